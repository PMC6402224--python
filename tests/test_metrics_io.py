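"""Metrics, CSV and WFDB format-212 I/O, and CLI smoke tests."""

import numpy as np
import pytest
from click.testing import CliRunner

import ufirecg as u
from ufirecg.cli import main


class TestRMSE:
    def test_identical_is_zero(self):
        x = np.arange(10.0)
        assert u.rmse(x, x) == 0.0

    def test_constant_offset(self):
        x = np.arange(10.0)
        assert u.rmse(x + 0.3, x) == pytest.approx(0.3)

    def test_gaussian_error_recovers_sigma(self):
        rng = np.random.default_rng(1)
        e = rng.normal(0, 0.7, 100_000)
        se = 0.7 * np.sqrt(0.5 / e.size)
        assert abs(u.rmse(e, np.zeros_like(e)) - 0.7) < 3 * se

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            u.rmse(np.ones(3), np.ones(4))


class TestBoxplot:
    def test_small_worked_case(self):
        s = u.boxplot_stats([1, 2, 3, 4, 5])
        assert (s.median, s.q1, s.q3) == (3.0, 2.0, 4.0)
        assert s.n_outliers == 0

    def test_all_equal(self):
        s = u.boxplot_stats([2.0] * 8)
        assert s.iqr == 0.0 and s.n_outliers == 0
        assert s.whisker_low == s.whisker_high == 2.0

    def test_extreme_value_is_outlier(self):
        base = np.array([1, 2, 3, 4, 5], dtype=float)
        s = u.boxplot_stats(np.append(base, 3 + 10 * 2.0))  # 10 x IQR above the median
        assert s.n_outliers == 1
        assert s.whisker_high <= 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            u.boxplot_stats([])


class TestCSVSignal:
    def test_round_trip(self, tmp_path):
        sig = u.ECGSignal(np.random.default_rng(0).normal(size=257), 360.0, "rt")
        path = tmp_path / "sig.csv"
        u.write_csv_signal(sig, path)
        back = u.read_csv_signal(path)
        np.testing.assert_array_equal(back.samples, sig.samples)
        assert back.fs == 360.0

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            u.read_csv_signal(path, fs=360.0)

    def test_header_only(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text("sample\n")
        with pytest.raises(ValueError, match="no samples"):
            u.read_csv_signal(path, fs=360.0)

    def test_non_numeric_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample\n1.0\nbogus\n2.0\n")
        with pytest.raises(ValueError, match="line 3"):
            u.read_csv_signal(path, fs=360.0)


class TestWFDB212:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        adc = rng.integers(-2048, 2048, size=1001)
        mv = (adc - 0.0) / 200.0
        rec = tmp_path / "rt01"
        u.write_wfdb(rec, mv, fs=360.0, gains=(200.0,), baselines=(0,))
        back = u.read_wfdb(rec, channel="MLII")
        np.testing.assert_array_equal(np.round(back.samples * 200.0), adc)
        assert back.fs == 360.0

    def test_two_channel_selection(self, tmp_path):
        t = np.arange(600) / 360.0
        ch0 = np.sin(2 * np.pi * 1.2 * t)
        ch1 = np.cos(2 * np.pi * 1.2 * t)
        rec = tmp_path / "rt02"
        u.write_wfdb(rec, np.vstack([ch0, ch1]), fs=360.0,
                     gains=(200.0, 200.0), baselines=(1024, 1024),
                     channel_names=("MLII", "V1"))
        mlii = u.read_wfdb(rec, channel="MLII")
        v1 = u.read_wfdb(rec, channel="V1")
        assert np.abs(mlii.samples - ch0).max() < 1 / 200.0  # quantisation only
        assert np.abs(v1.samples - ch1).max() < 1 / 200.0

    def test_missing_lead_lists_available(self, tmp_path):
        rec = tmp_path / "rt03"
        u.write_wfdb(rec, np.zeros(10), fs=360.0, gains=(200.0,), baselines=(0,))
        with pytest.raises(ValueError, match="MLII"):
            u.read_wfdb(rec, channel="V5")

    def test_unsupported_format_rejected(self, tmp_path):
        rec = tmp_path / "rt04"
        u.write_wfdb(rec, np.zeros(10), fs=360.0, gains=(200.0,), baselines=(0,))
        hea = rec.with_suffix(".hea")
        hea.write_text(hea.read_text().replace(" 212 ", " 16 "))
        with pytest.raises(ValueError, match="format"):
            u.read_wfdb(rec, channel="MLII")

    def test_truncated_dat_rejected(self, tmp_path):
        rec = tmp_path / "rt05"
        u.write_wfdb(rec, np.zeros(100), fs=360.0, gains=(200.0,), baselines=(0,))
        dat = rec.parent / "rt05.dat"
        dat.write_bytes(dat.read_bytes()[:30])
        with pytest.raises(ValueError, match="truncated"):
            u.read_wfdb(rec, channel="MLII")


class TestCLI:
    def test_simulate_then_features(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "rec"
        r = runner.invoke(main, ["simulate", "--beats", "3", "--snr-db", "30",
                                 "--seed", "1", "-o", str(out)])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "rec.noisy.csv").exists()
        feat = tmp_path / "features.csv"
        r = runner.invoke(main, ["features", "-i", str(tmp_path / "rec.noisy.csv"),
                                 "--beat-length", "300", "-o", str(feat)])
        assert r.exit_code == 0, r.output
        import pandas as pd

        df = pd.read_csv(feat)
        assert len(df) == 3 and "P_amp" in df.columns

    def test_evaluate_prints_all_methods(self):
        r = CliRunner().invoke(main, ["evaluate", "--beats", "3", "--snr-db", "30"])
        assert r.exit_code == 0, r.output
        for name in ("adaptive_smoother", "ufir_filter", "ufir_predictor", "linear_predictor"):
            assert name in r.output

    def test_predict_lp(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "rec"
        runner.invoke(main, ["simulate", "--beats", "2", "--snr-db", "25",
                             "--seed", "2", "-o", str(out)])
        res = tmp_path / "lp.csv"
        r = runner.invoke(main, ["predict-lp", "-i", str(tmp_path / "rec.noisy.csv"),
                                 "-o", str(res)])
        assert r.exit_code == 0, r.output
        assert "delta" in r.output and res.exists()
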