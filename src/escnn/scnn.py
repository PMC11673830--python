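"""Dual-scale sequential CNN for windows of consecutive sleep epochs.

Two parallel convolutional branches read the raw (window, epoch,
sample) tensor: a *small-scale* branch (kernel width fs/2 samples)
tuned to fast activity and a *large-scale* branch (kernel width 4*fs)
tuned to slow waves.  Both first-layer kernels have height 2 over the
epoch axis, so the features at window position j mix epoch j with its
successor and carry cross-epoch context.  Each branch continues with
max-pooling, two further width-wise convolutions, a
squeeze-and-excitation gate that reweights channels, and global average
pooling; the branch features are concatenated and a shared linear head
emits stage logits for every one of the L window positions.

Training minimises softmax cross-entropy averaged over all positions,
with Adam and early stopping on validation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .seqcodec import ProbTensor, SequenceTensor, encode_labels, encode_sequences
from .types import EpochedRecording, N_STAGES

__all__ = ["SCNNConfig", "SCNNClassifier", "build_scnn", "se_recalibrate",
           "forward", "train_scnn"]


@dataclass
class SCNNConfig:
    """Hyperparameters of the dual-scale sequential CNN.

    Kernel widths/strides default to fractions of the sampling rate:
    small branch width fs/2 stride fs/16, large branch width 4*fs
    stride fs/2.  ``n_filters`` is the first-layer filter count per
    branch; the two follow-up convolutions use twice that.
    """

    fs: float = 100.0
    n_stages: int = N_STAGES
    small_kernel_w: int | None = None
    large_kernel_w: int | None = None
    small_stride: int | None = None
    large_stride: int | None = None
    kernel_h: int = 2
    n_filters: int = 64
    conv_w: int = 8
    pool1: int = 8
    pool2: int = 4
    se_reduction: int = 16
    dropout: float = 0.0
    augment: bool = True
    lr: float = 2e-3
    batch_size: int = 32
    max_epochs: int = 25
    min_epochs: int = 8
    patience: int = 5
    balanced_classes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.small_kernel_w is None:
            self.small_kernel_w = max(int(self.fs // 2), 2)
        if self.large_kernel_w is None:
            self.large_kernel_w = int(self.fs * 4)
        if self.small_stride is None:
            self.small_stride = max(int(self.fs // 16), 1)
        if self.large_stride is None:
            self.large_stride = max(int(self.fs // 2), 1)
        if self.kernel_h < 1:
            raise ValueError("kernel_h must be >= 1")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")
        if (2 * self.n_filters) % self.se_reduction != 0:
            raise ValueError(
                f"branch feature count {2 * self.n_filters} must be "
                f"divisible by se_reduction {self.se_reduction}")


class _Branch:
    """One convolutional scale: EpochConv -> (pool, conv, relu) x2 -> SE -> GAP."""

    def __init__(self, cfg: SCNNConfig, kernel_w: int, stride: int, M: int,
                 rng: np.random.Generator):
        f1, f2 = cfg.n_filters, 2 * cfg.n_filters
        self.conv1 = nn.EpochConv(f1, kernel_w, stride, cfg.kernel_h, rng)
        w = self.conv1.out_width(M)
        self.relu1 = nn.ReLU()
        self.pool1 = nn.MaxPoolW(min(cfg.pool1, w))
        w = self.pool1.out_width(w)
        self.conv2 = nn.ConvW(f1, f2, min(cfg.conv_w, w), rng)
        w = self.conv2.out_width(w)
        self.relu2 = nn.ReLU()
        self.pool2 = nn.MaxPoolW(min(cfg.pool2, w))
        w = self.pool2.out_width(w)
        self.conv3 = nn.ConvW(f2, f2, min(cfg.conv_w, w), rng)
        w = self.conv3.out_width(w)
        self.relu3 = nn.ReLU()
        self.se = nn.SEBlock(f2, cfg.se_reduction, rng)
        self.gap = nn.GlobalAvgPoolW()
        self.layers = [self.conv1, self.relu1, self.pool1, self.conv2,
                       self.relu2, self.pool2, self.conv3, self.relu3,
                       self.se, self.gap]
        self.n_features = f2

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x                                  # (B, L, f2)

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class _SCNNNet:
    """Two branches + dropout + shared per-position classifier."""

    def __init__(self, cfg: SCNNConfig, M: int):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.M = M
        self.small = _Branch(cfg, cfg.small_kernel_w, cfg.small_stride, M, rng)
        self.large = _Branch(cfg, cfg.large_kernel_w, cfg.large_stride, M, rng)
        d = self.small.n_features + self.large.n_features
        self.dropout = nn.Dropout(cfg.dropout, np.random.default_rng(
            cfg.seed + 7919))
        self.head = nn.Dense(d, cfg.n_stages, rng, scale=0.01)

    def params(self):
        return self.small.params() + self.large.params() + self.head.params()

    def forward(self, x, train=False):
        fs_ = self.small.forward(x, train=train)
        fl_ = self.large.forward(x, train=train)
        feats = np.concatenate([fl_, fs_], axis=2)   # large first, then small
        feats = self.dropout.forward(feats, train=train)
        return self.head.forward(feats, train=train)

    def backward(self, dlogits):
        g = self.head.backward(dlogits)
        g = self.dropout.backward(g)
        nl = self.large.n_features
        self.large.backward(np.ascontiguousarray(g[:, :, :nl]))
        self.small.backward(np.ascontiguousarray(g[:, :, nl:]))

    def state(self):
        return [p.value.copy() for p in self.params()]

    def load_state(self, state):
        for p, v in zip(self.params(), state):
            p.value = v.copy()


class SCNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn style wrapper around the dual-scale sequential CNN.

    ``fit`` consumes a window tensor ``X`` of shape (n_windows, L, M)
    and per-position labels ``y`` of shape (n_windows, L);
    ``predict_proba`` returns (n_windows, L, n_stages) softmax
    probabilities.  If no validation set is passed, the last
    ``val_fraction`` of the windows is held out for early stopping.
    """

    def __init__(self, config: SCNNConfig | None = None,
                 val_fraction: float = 0.1, **overrides):
        self.config = config
        self.val_fraction = val_fraction
        self.overrides = overrides

    def _cfg(self) -> SCNNConfig:
        if self.config is not None:
            base = asdict(self.config)
            base.update(self.overrides)
            return SCNNConfig(**base)
        return SCNNConfig(**self.overrides)

    def _build(self, M: int) -> None:
        cfg = self._cfg()
        self.config_ = cfg
        self.net_ = _SCNNNet(cfg, M)
        self.classes_ = np.arange(cfg.n_stages)

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=nn.F32)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[0] < 1:
            raise ValueError("X must be a nonempty (n_windows, L, M) tensor")
        if y.shape != X.shape[:2]:
            raise ValueError(f"label shape {y.shape} != window shape "
                             f"{X.shape[:2]}")
        if not hasattr(self, "net_") or self.net_.M != X.shape[2]:
            self._build(X.shape[2])
        cfg = self.config_
        net = self.net_

        if validation_data is not None:
            Xtr, ytr = X, y
            Xva, yva = validation_data
            Xva = np.asarray(Xva, dtype=nn.F32)
            yva = np.asarray(yva)
        else:
            # every k-th window, so validation samples the whole night of
            # every subject and sees rare stages (a contiguous tail can
            # miss N1 entirely and let early stopping fire on a model
            # that has collapsed it)
            stride = max(int(round(1.0 / max(self.val_fraction, 1e-9))), 2)
            val_mask = np.zeros(X.shape[0], dtype=bool)
            val_mask[stride - 1::stride] = True
            if 0 < val_mask.sum() < X.shape[0]:
                Xtr, ytr = X[~val_mask], y[~val_mask]
                Xva, yva = X[val_mask], y[val_mask]
            else:
                Xtr, ytr, Xva, yva = X, y, X, y

        class_w = None
        if cfg.balanced_classes:
            counts = np.bincount(ytr.ravel(), minlength=cfg.n_stages)
            class_w = counts.sum() / np.maximum(counts, 1) / cfg.n_stages

        opt = nn.Adam(net.params(), lr=cfg.lr)
        shuffle_rng = np.random.default_rng(cfg.seed + 1)
        aug_rng = np.random.default_rng(cfg.seed + 2)
        history = []
        best_acc, best_state, since_best = -1.0, net.state(), 0

        for ep in range(cfg.max_epochs):
            order = shuffle_rng.permutation(Xtr.shape[0])
            losses, correct, seen = [], 0, 0
            for start in range(0, order.size, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb = Xtr[idx]
                if cfg.augment:
                    # circular time shift and sign flip leave the spectral
                    # content of each epoch unchanged but break the net's
                    # ability to memorize individual noise realizations
                    xb = np.roll(xb, int(aug_rng.integers(0, xb.shape[2])),
                                 axis=2)
                    if aug_rng.random() < 0.5:
                        xb = -xb
                logits = net.forward(xb, train=True)
                loss, dlogits = nn.softmax_xent(logits, ytr[idx], class_w)
                opt.zero_grad()
                net.backward(dlogits)
                opt.step()
                losses.append(loss)
                correct += int((logits.argmax(-1) == ytr[idx]).sum())
                seen += idx.size * logits.shape[1]
            val_acc = self._position_accuracy(Xva, yva)
            history.append({"epoch": ep, "loss": float(np.mean(losses)),
                            "train_acc": correct / seen, "val_acc": val_acc})
            if val_acc > best_acc + 1e-9:
                best_acc, best_state, since_best = val_acc, net.state(), 0
            else:
                since_best += 1
                if since_best >= cfg.patience and ep + 1 >= cfg.min_epochs:
                    break
            if val_acc >= 0.998:        # nothing left to improve on
                break
        net.load_state(best_state)
        self.history_ = history
        self.best_val_acc_ = best_acc
        return self

    def _position_accuracy(self, X, y) -> float:
        """Macro recall over the stages present in the validation set.

        Balanced scoring keeps early stopping honest on rare stages: a
        model that has collapsed N1 into N2 cannot reach a perfect
        validation score even though N1 epochs are few.
        """
        pred = self.predict_proba(X).argmax(-1)
        recalls = [float((pred[y == c] == c).mean())
                   for c in np.unique(y)]
        return float(np.mean(recalls))

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=nn.F32)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, L, M)")
        if X.shape[2] != self.net_.M:
            raise ValueError(f"epoch length {X.shape[2]} != model's "
                             f"{self.net_.M}")
        out = []
        bs = max(self.config_.batch_size, 1)
        for start in range(0, X.shape[0], bs):
            logits = self.net_.forward(X[start:start + bs], train=False)
            out.append(nn.softmax(logits.astype(np.float64)))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(-1)

    def save(self, path) -> None:
        """Single-file parameter archive (.npz) + JSON config sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        params = {f"p{i}": p.value for i, p in
                  enumerate(self.net_.params())}
        np.savez(path, M=np.array(self.net_.M), **params)
        path.with_suffix(".json").write_text(
            json.dumps(asdict(self.config_), indent=2))

    @classmethod
    def load(cls, path) -> "SCNNClassifier":
        import json
        from pathlib import Path

        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        cfg = SCNNConfig(**json.loads(
            path.with_suffix(".json").read_text()))
        arx = np.load(path)
        clf = cls(config=cfg)
        clf._build(int(arx["M"]))
        for i, p in enumerate(clf.net_.params()):
            p.value = arx[f"p{i}"].astype(nn.F32)
        return clf


# ---------------------------------------------------------------------------
# functional surface

def build_scnn(config: SCNNConfig, M: int | None = None) -> SCNNClassifier:
    """Instantiate an untrained classifier with seeded parameters."""
    clf = SCNNClassifier(config=config)
    clf._build(int(M if M is not None else config.fs * 30))
    return clf


def se_recalibrate(features: np.ndarray, weights: dict[str, np.ndarray],
                   ) -> np.ndarray:
    """Apply a squeeze-and-excitation gate to a (P, W, O) feature array.

    ``weights`` holds ``W1`` (O/r, O), ``b1``, ``W2`` (O, O/r), ``b2``.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 3:
        raise ValueError("features must be (P, W, O)")
    O = x.shape[2]
    W1, b1 = np.asarray(weights["W1"]), np.asarray(weights["b1"])
    W2, b2 = np.asarray(weights["W2"]), np.asarray(weights["b2"])
    if W1.shape[1] != O or W2.shape[0] != O:
        raise ValueError("SE weight shapes do not match feature channels")
    z = x.mean(axis=1)                       # squeeze over W
    a = np.maximum(z @ W1.T + b1, 0.0)
    gate = 1.0 / (1.0 + np.exp(-(a @ W2.T + b2)))
    return x * gate[:, None, :]


def forward(model: SCNNClassifier, seq: SequenceTensor) -> ProbTensor:
    """Run the network on an encoded night; softmax per position."""
    if seq.data.shape[2] != model.net_.M:
        raise ValueError(
            f"sequence epoch length {seq.data.shape[2]} does not match "
            f"model's {model.net_.M}")
    return ProbTensor(model.predict_proba(seq.data))


def train_scnn(model: SCNNClassifier, train: list[EpochedRecording],
               valid: list[EpochedRecording] | None = None,
               L: int = 10) -> SCNNClassifier:
    """Train on whole recordings (windows pooled across subjects).

    With ``valid=None`` the tail fraction of the pooled windows serves
    for early stopping.
    """
    if not train:
        raise ValueError("empty training set")
    fss = {r.fs for r in train}
    if len(fss) != 1:
        raise ValueError(f"recordings mix sampling rates: {sorted(fss)}")
    Xs, ys = [], []
    for rec in train:
        Xs.append(encode_sequences(rec, L).data)
        ys.append(encode_labels(rec.labels, L))
    X = np.concatenate(Xs, axis=0)
    y = np.concatenate(ys, axis=0)
    val = None
    if valid:
        Xv = np.concatenate([encode_sequences(r, L).data for r in valid])
        yv = np.concatenate([encode_labels(r.labels, L) for r in valid])
        val = (Xv, yv)
    return model.fit(X, y, validation_data=val)
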