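"""Reading, preprocessing and epoching of polysomnography EEG.

EDF/EDF+ files are read through :mod:`mne`.  A deliberately minimal
16-bit EDF/EDF+ *writer* is included so synthetic fixtures can be
round-tripped through the real reader; it supports exactly what the
fixtures need (one data channel, optional stage annotations) and is not
a general-purpose exporter.

Preprocessing follows the common clinical recipe for sleep EEG: an
optional 50/60 Hz notch, a 0.3--35 Hz zero-phase bandpass, and
whole-recording z-normalisation so every night enters the classifier
with zero mean and unit variance.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import (
    DEFAULT_EPOCH_LEN_S,
    EpochedRecording,
    INT_TO_STAGE,
    RawRecording,
    StageLabels,
    UNSCORED,
)

__all__ = [
    "read_psg",
    "read_hypnogram",
    "map_stages",
    "preprocess",
    "epoch_and_align",
    "trim_wake",
    "write_edf",
    "save_epoched",
    "load_epoched",
]

# ---------------------------------------------------------------------------
# reading

_CSV_TOKEN_MAP = {
    "W": "Wake", "1": "S1", "2": "S2", "3": "S3", "4": "S4", "R": "REM",
    "N1": "N1", "N2": "N2", "N3": "N3", "M": "MOVEMENT", "?": "UNKNOWN",
}

_EDF_ANNOT_MAP = {
    "Sleep stage W": "Wake",
    "Sleep stage 1": "S1",
    "Sleep stage 2": "S2",
    "Sleep stage 3": "S3",
    "Sleep stage 4": "S4",
    "Sleep stage R": "REM",
    "Sleep stage N1": "N1",
    "Sleep stage N2": "N2",
    "Sleep stage N3": "N3",
    "Sleep stage ?": "UNKNOWN",
    "Sleep stage M": "MOVEMENT",
    "Movement time": "MOVEMENT",
}


def read_psg(path, channel: str) -> RawRecording:
    """Read one EEG channel from an EDF/EDF+ file, in microvolts."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(
            f"channel {channel!r} not in {path.name}; "
            f"available channels: {raw.ch_names}"
        )
    raw.pick([channel]).load_data(verbose="error")
    samples = raw.get_data()[0] * 1e6  # volts -> microvolts
    return RawRecording(
        samples=samples,
        fs=float(raw.info["sfreq"]),
        channel=channel,
        subject_id=path.stem,
    )


def read_hypnogram(path, dialect: str = "csv",
                   epoch_len_s: float = DEFAULT_EPOCH_LEN_S) -> StageLabels:
    """Parse a hypnogram into one label per 30 s epoch.

    R&K tokens (S1--S4) are preserved verbatim; use :func:`map_stages`
    to convert to AASM.  ``dialect`` is ``"csv"`` (header ``epoch,stage``)
    or ``"edfplus_annotations"``.
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, dtype=str)
        if "stage" not in df.columns:
            raise ValueError(f"{path.name}: expected a 'stage' column")
        tokens = []
        for raw_tok in df["stage"].astype(str).str.strip():
            if raw_tok not in _CSV_TOKEN_MAP:
                raise ValueError(f"unknown stage token {raw_tok!r} in {path.name}")
            tokens.append(_CSV_TOKEN_MAP[raw_tok])
        return StageLabels(np.array(tokens, dtype=object), epoch_len_s=epoch_len_s)

    if dialect == "edfplus_annotations":
        import mne

        ann = mne.read_annotations(str(path))
        order = np.argsort(ann.onset, kind="stable")
        tokens: list[str] = []
        prev_end = None
        for i in order:
            desc = str(ann.description[i])
            if desc not in _EDF_ANNOT_MAP:
                raise ValueError(f"unknown stage annotation {desc!r}")
            onset, dur = float(ann.onset[i]), float(ann.duration[i])
            if prev_end is not None and onset < prev_end - 1e-6:
                raise ValueError(
                    f"overlapping annotations at onset {onset} s "
                    f"(previous block ends at {prev_end} s)"
                )
            for t, name in ((dur, "duration"), (onset, "onset")):
                if abs(t / epoch_len_s - round(t / epoch_len_s)) > 1e-6:
                    raise ValueError(
                        f"annotation {name} {t} s is not a multiple of "
                        f"{epoch_len_s} s"
                    )
            if prev_end is not None and onset > prev_end + 1e-6:
                tokens.extend(["UNKNOWN"] * int(round((onset - prev_end) / epoch_len_s)))
            tokens.extend([_EDF_ANNOT_MAP[desc]] * int(round(dur / epoch_len_s)))
            prev_end = onset + dur
        if not tokens:
            raise ValueError(f"no stage annotations found in {path.name}")
        return StageLabels(np.array(tokens, dtype=object), epoch_len_s=epoch_len_s)

    raise ValueError(f"unknown hypnogram dialect {dialect!r}")


_RK_TO_AASM = {
    "Wake": "Wake", "S1": "N1", "S2": "N2", "S3": "N3", "S4": "N3",
    "REM": "REM", "N1": "N1", "N2": "N2", "N3": "N3",
    "MOVEMENT": UNSCORED, "UNKNOWN": UNSCORED,
}


def map_stages(labels: StageLabels, scheme: str = "rk_to_aasm") -> StageLabels:
    """Convert R&K tokens to the AASM five-stage scheme.

    S3 and S4 merge into N3; movement time and unknown epochs become
    ``UNSCORED``.  ``scheme="identity"`` returns the labels untouched.
    """
    if scheme == "identity":
        return StageLabels(labels.stages.copy(), epoch_len_s=labels.epoch_len_s)
    if scheme != "rk_to_aasm":
        raise ValueError(f"unknown scheme {scheme!r}")
    mapped = np.array([_RK_TO_AASM[s] for s in labels.stages], dtype=object)
    return StageLabels(mapped, epoch_len_s=labels.epoch_len_s)


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(rec: RawRecording, notch_hz=50, band=(0.3, 35.0),
               normalize: bool = True) -> RawRecording:
    """Notch + zero-phase bandpass + whole-recording z-normalisation.

    ``notch_hz`` is 50, 60 or None.  Filters are applied forward and
    backward (zero phase) so stage boundaries are not smeared by group
    delay.  Set ``normalize=False`` to inspect the filtered signal before
    the z-scoring step.
    """
    nyq = rec.fs / 2.0
    low, high = float(band[0]), float(band[1])
    if not (0 < low < high):
        raise ValueError(f"invalid band {band}")
    if high >= nyq:
        raise ValueError(f"band high {high} Hz must be below Nyquist {nyq} Hz")

    x = rec.samples.astype(float)
    if notch_hz not in (None, "none"):
        notch_hz = float(notch_hz)
        if notch_hz not in (50.0, 60.0):
            raise ValueError("notch frequency must be 50, 60 or None")
        if notch_hz >= nyq * 0.999:
            # e.g. 50 Hz mains on a 100 Hz recording: the notch target sits
            # at Nyquist and the 35 Hz low-pass already removes it.
            warnings.warn(
                f"notch {notch_hz} Hz at/above Nyquist {nyq} Hz; skipped",
                RuntimeWarning,
            )
        else:
            b, a = sps.iirnotch(notch_hz, Q=30.0, fs=rec.fs)
            x = sps.filtfilt(b, a, x)

    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    x = sps.sosfiltfilt(sos, x)

    if normalize:
        sd = x.std()
        if sd < 1e-12:
            raise ValueError("signal is constant after filtering; cannot z-normalize")
        x = (x - x.mean()) / sd
    return RawRecording(samples=x, fs=rec.fs, channel=rec.channel,
                        subject_id=rec.subject_id)


def epoch_and_align(rec: RawRecording, labels: StageLabels,
                    epoch_len_s: float | None = None) -> EpochedRecording:
    """Cut the recording into scored epochs aligned with the hypnogram.

    Trailing partial epochs are discarded; epochs labelled ``UNSCORED``
    are dropped from both the signal and the labels.
    """
    if epoch_len_s is None:
        epoch_len_s = labels.epoch_len_s
    m = int(round(epoch_len_s * rec.fs))
    p_signal = rec.samples.size // m
    if p_signal < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s is shorter than one "
            f"{epoch_len_s} s epoch"
        )
    p = min(p_signal, len(labels))
    X = rec.samples[: p * m].reshape(p, m)
    toks = labels.stages[:p]
    keep = np.array([t != UNSCORED for t in toks], dtype=bool)
    if not keep.any():
        raise ValueError("no scored epochs remain after dropping UNSCORED")
    kept = StageLabels(toks[keep], epoch_len_s=epoch_len_s)
    kept.codes()  # validates AASM-only labels
    return EpochedRecording(X=X[keep], labels=kept, fs=rec.fs,
                            subject_id=rec.subject_id)


def trim_wake(rec: EpochedRecording, keep_min: float) -> EpochedRecording:
    """Trim long pre/post-sleep Wake, keeping ``keep_min`` minutes.

    Wake epochs further than ``keep_min`` minutes before the first /
    after the last non-Wake epoch are dropped.  A night with no sleep
    at all is returned unchanged.
    """
    toks = rec.labels.stages
    non_wake = np.flatnonzero(toks != "Wake")
    if non_wake.size == 0:
        return rec
    k = int(round(keep_min * 60.0 / rec.labels.epoch_len_s))
    lo = max(int(non_wake[0]) - k, 0)
    hi = min(int(non_wake[-1]) + k, len(toks) - 1)
    sel = slice(lo, hi + 1)
    return EpochedRecording(
        X=rec.X[sel],
        labels=StageLabels(toks[sel], epoch_len_s=rec.labels.epoch_len_s),
        fs=rec.fs, subject_id=rec.subject_id, meta=dict(rec.meta))


# ---------------------------------------------------------------------------
# minimal EDF writer (synthetic fixtures only)

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def write_edf(path, channels: dict[str, np.ndarray], fs: float,
              annotations: list[tuple[float, float, str]] | None = None) -> None:
    """Write a small 16-bit EDF (or EDF+C when annotations are given).

    ``channels`` maps label -> microvolt signal; all signals share ``fs``
    and the sampling rate must be an integer (one-second data records).
    ``annotations`` is a list of (onset_s, duration_s, text).
    """
    path = Path(path)
    fs_i = int(round(fs))
    if abs(fs - fs_i) > 1e-9:
        raise ValueError("writer supports integer sampling rates only")
    sigs = {k: np.asarray(v, dtype=float).ravel() for k, v in channels.items()}
    n = min(s.size for s in sigs.values())
    n_rec = n // fs_i
    if n_rec < 1:
        raise ValueError("need at least one second of signal")

    labels = list(sigs)
    is_plus = annotations is not None
    ns = len(labels) + (1 if is_plus else 0)
    annot_spr = 60  # 120 bytes of TAL space per record

    digmin, digmax = -32768, 32767
    phys = {}
    for k in labels:
        lo, hi = float(sigs[k].min()), float(sigs[k].max())
        if hi - lo < 1e-9:
            lo, hi = lo - 1.0, hi + 1.0
        phys[k] = (lo, hi)

    now = _dt.datetime(2000, 1, 1, 0, 0, 0)
    hdr = b""
    hdr += _pad("0", 8)
    hdr += _pad("X X X X" if is_plus else "synthetic", 80)
    hdr += _pad("Startdate 01-JAN-2000 X X X" if is_plus else "synthetic", 80)
    hdr += _pad(now.strftime("%d.%m.%y"), 8)
    hdr += _pad(now.strftime("%H.%M.%S"), 8)
    hdr += _pad(str(256 * (ns + 1)), 8)
    hdr += _pad("EDF+C" if is_plus else "", 44)
    hdr += _pad(str(n_rec), 8)
    hdr += _pad("1", 8)
    hdr += _pad(str(ns), 4)

    def field(values, width):
        return b"".join(_pad(v, width) for v in values)

    all_labels = labels + (["EDF Annotations"] if is_plus else [])
    hdr += field(all_labels, 16)
    hdr += field([""] * ns, 80)                                   # transducer
    hdr += field(["uV"] * len(labels) + ([""] if is_plus else []), 8)
    hdr += field([f"{phys[k][0]:.8g}"[:8] for k in labels]
                 + (["-1"] if is_plus else []), 8)                # phys min
    hdr += field([f"{phys[k][1]:.8g}"[:8] for k in labels]
                 + (["1"] if is_plus else []), 8)                 # phys max
    hdr += field([str(digmin)] * ns, 8)
    hdr += field([str(digmax)] * ns, 8)
    hdr += field([""] * ns, 80)                                   # prefilter
    hdr += field([str(fs_i)] * len(labels)
                 + ([str(annot_spr)] if is_plus else []), 8)
    hdr += field([""] * ns, 32)

    # TALs per record: a timekeeping TAL, plus any annotation starting
    # in that record.
    tal_by_rec: dict[int, bytes] = {}
    if is_plus:
        for onset, dur, text in annotations:
            r = int(onset)  # records are 1 s long
            if r >= n_rec:
                continue
            tal = f"+{onset:g}\x15{dur:g}\x14{text}\x14\x00".encode("ascii")
            tal_by_rec[r] = tal_by_rec.get(r, b"") + tal

    dig = {}
    for k in labels:
        lo, hi = phys[k]
        scale = (digmax - digmin) / (hi - lo)
        d = np.round((sigs[k][: n_rec * fs_i] - lo) * scale + digmin)
        dig[k] = np.clip(d, digmin, digmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for k in labels:
                fh.write(dig[k][r * fs_i: (r + 1) * fs_i].tobytes())
            if is_plus:
                tal = f"+{r}\x14\x14\x00".encode("ascii") + tal_by_rec.get(r, b"")
                if len(tal) > 2 * annot_spr:
                    raise ValueError("too many annotations in one record")
                fh.write(tal.ljust(2 * annot_spr, b"\x00"))


# ---------------------------------------------------------------------------
# HDF5 persistence of epoched recordings

def save_epoched(rec: EpochedRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=rec.X.astype(np.float32))
        f.create_dataset("labels", data=rec.stage_codes())
        f.attrs["fs"] = rec.fs
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["epoch_len_s"] = rec.labels.epoch_len_s


def load_epoched(path) -> EpochedRecording:
    with h5py.File(path, "r") as f:
        X = f["X"][()]
        codes = f["labels"][()]
        fs = float(f.attrs["fs"])
        sid = str(f.attrs.get("subject_id", ""))
        elen = float(f.attrs.get("epoch_len_s", DEFAULT_EPOCH_LEN_S))
    toks = np.array([INT_TO_STAGE[int(c)] for c in codes], dtype=object)
    return EpochedRecording(X=X, labels=StageLabels(toks, epoch_len_s=elen),
                            fs=fs, subject_id=sid)
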