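"""EDF round trips, hypnogram parsing, filtering and epoching."""

import numpy as np
import pytest

from escnn.edf_io import (epoch_and_align, map_stages, preprocess,
                          read_hypnogram, read_psg, save_epoched,
                          load_epoched, write_edf)
from escnn.synth import write_edf_fixture
from escnn.types import RawRecording, StageLabels, UNSCORED


@pytest.fixture(scope="module")
def fixture_edf(tmp_path_factory):
    rng = np.random.default_rng(7)
    fs = 100
    x = rng.standard_normal(fs * 120) * 20.0       # 2 minutes, ~uV scale
    path = tmp_path_factory.mktemp("edf") / "night.edf"
    write_edf(path, {"Fpz-Cz": x}, fs=fs)
    return path, x, fs


class TestReadPsg:
    def test_round_trip_within_quantization(self, fixture_edf):
        path, x, fs = fixture_edf
        rec = read_psg(path, "Fpz-Cz")
        assert rec.fs == fs
        assert rec.samples.size == x.size
        # 16-bit quantization over the physical range
        step = (x.max() - x.min()) / 65535
        assert np.abs(rec.samples - x).max() < 2 * step

    def test_missing_channel_lists_available(self, fixture_edf):
        path, *_ = fixture_edf
        with pytest.raises(ValueError, match="Fpz-Cz"):
            read_psg(path, "EMG")

    def test_second_channel_selected(self, tmp_path):
        fs = 100
        a = np.full(fs * 30, 10.0)
        b = np.linspace(-50, 50, fs * 30)
        path = tmp_path / "two.edf"
        write_edf(path, {"ch-A": a, "ch-B": b}, fs=fs)
        rec = read_psg(path, "ch-B")
        assert np.corrcoef(rec.samples, b)[0, 1] > 0.9999

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_psg(tmp_path / "nope.edf", "Fpz-Cz")


class TestHypnogram:
    def test_csv_tokens_preserved_for_remap(self, tmp_path):
        p = tmp_path / "hyp.csv"
        p.write_text("epoch,stage\n0,W\n1,1\n2,2\n3,3\n4,4\n5,R\n")
        labels = read_hypnogram(p, "csv")
        assert list(labels.stages) == ["Wake", "S1", "S2", "S3", "S4", "REM"]

    def test_csv_unknown_token_rejected(self, tmp_path):
        p = tmp_path / "hyp.csv"
        p.write_text("epoch,stage\n0,W\n1,Z\n")
        with pytest.raises(ValueError, match="'Z'"):
            read_hypnogram(p, "csv")

    def test_edfplus_duration_expanded(self, tmp_path, one_night):
        path = tmp_path / "annotated.edf"
        write_edf_fixture(one_night, path, with_annotations=True)
        labels = read_hypnogram(path, "edfplus_annotations")
        expected = one_night.labels.stages
        # fixture writer maps AASM tokens verbatim
        assert list(labels.stages[: len(expected)]) == list(expected)

    def test_non_multiple_duration_rejected(self, tmp_path):
        path = tmp_path / "bad.edf"
        write_edf(path, {"C3": np.zeros(100 * 90)}, fs=100,
                  annotations=[(0.0, 45.0, "Sleep stage W")])
        with pytest.raises(ValueError, match="multiple"):
            read_hypnogram(path, "edfplus_annotations")


class TestMapStages:
    def test_rk_merge_rule(self):
        labels = StageLabels(np.array(
            ["Wake", "S1", "S2", "S3", "S4", "REM"], dtype=object))
        out = map_stages(labels, "rk_to_aasm")
        assert list(out.stages) == ["Wake", "N1", "N2", "N3", "N3", "REM"]

    def test_identity(self):
        labels = StageLabels(np.array(["S3", "REM"], dtype=object))
        assert list(map_stages(labels, "identity").stages) == ["S3", "REM"]

    def test_movement_and_unknown_become_unscored(self):
        labels = StageLabels(np.array(["MOVEMENT", "UNKNOWN"], dtype=object))
        out = map_stages(labels)
        assert list(out.stages) == [UNSCORED, UNSCORED]


class TestPreprocess:
    def test_notch_attenuates_mains(self):
        fs = 200.0
        t = np.arange(int(fs * 60)) / fs
        x = np.sin(2 * np.pi * 50.0 * t)
        rec = RawRecording(x, fs=fs)
        out = preprocess(rec, notch_hz=50, band=(0.3, 70.0), normalize=False)
        atten_db = 20 * np.log10(np.sqrt(np.mean(x ** 2))
                                 / np.sqrt(np.mean(out.samples ** 2)))
        assert atten_db >= 20.0

    def test_z_normalization_exact(self, rng):
        rec = RawRecording(rng.standard_normal(100 * 120) * 13 + 4, fs=100.0)
        out = preprocess(rec, notch_hz=None, band=(0.3, 35.0))
        assert abs(out.samples.mean()) < 1e-6
        assert abs(out.samples.std() - 1.0) < 1e-6

    def test_z_normalization_idempotent(self, rng):
        rec = RawRecording(rng.standard_normal(100 * 60), fs=100.0)
        once = preprocess(rec, notch_hz=None, band=(0.3, 35.0))
        x = once.samples
        again = (x - x.mean()) / x.std()
        np.testing.assert_allclose(x, again, atol=1e-12)

    def test_passband_fidelity(self):
        fs = 100.0
        t = np.arange(int(fs * 60)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        out = preprocess(RawRecording(x, fs=fs), notch_hz=None,
                         band=(0.3, 35.0), normalize=False)
        assert np.corrcoef(x, out.samples)[0, 1] > 0.99

    def test_band_above_nyquist_rejected(self):
        rec = RawRecording(np.zeros(1000) + np.arange(1000.0), fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess(rec, notch_hz=None, band=(0.3, 60.0))


class TestEpochAndAlign:
    def test_floor_arithmetic(self, rng):
        rec = RawRecording(rng.standard_normal(9500), fs=100.0)
        labels = StageLabels(np.array(["Wake", "N2", "N3"], dtype=object))
        out = epoch_and_align(rec, labels, epoch_len_s=30)
        assert out.X.shape == (3, 3000)

    def test_unscored_rows_dropped(self, rng):
        rec = RawRecording(rng.standard_normal(9000), fs=100.0)
        labels = StageLabels(np.array(["Wake", UNSCORED, "N2"], dtype=object))
        out = epoch_and_align(rec, labels, epoch_len_s=30)
        assert out.n_epochs == 2
        assert list(out.labels.stages) == ["Wake", "N2"]
        np.testing.assert_array_equal(
            out.X, rec.samples[:9000].reshape(3, 3000)[[0, 2]].astype(
                np.float32))

    def test_signal_shorter_than_epoch_rejected(self, rng):
        rec = RawRecording(rng.standard_normal(1000), fs=100.0)
        labels = StageLabels(np.array(["Wake"], dtype=object))
        with pytest.raises(ValueError, match="shorter"):
            epoch_and_align(rec, labels, epoch_len_s=30)

    def test_all_unscored_rejected(self, rng):
        rec = RawRecording(rng.standard_normal(6000), fs=100.0)
        labels = StageLabels(np.array([UNSCORED, UNSCORED], dtype=object))
        with pytest.raises(ValueError, match="scored"):
            epoch_and_align(rec, labels, epoch_len_s=30)

    def test_rows_always_match_labels(self, one_night):
        assert one_night.X.shape[0] == len(one_night.labels)


class TestHdf5:
    def test_round_trip(self, tmp_path, one_night):
        p = tmp_path / "rec.h5"
        save_epoched(one_night, p)
        back = load_epoched(p)
        np.testing.assert_allclose(back.X, one_night.X, atol=1e-6)
        assert list(back.labels.stages) == list(one_night.labels.stages)
        assert back.fs == one_night.fs
        assert back.subject_id == one_night.subject_id
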