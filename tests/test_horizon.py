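"""QRS window detection, residual MSV, optimal-horizon estimation, profiles."""

import numpy as np
import pytest

import ufirecg as u
from ufirecg.horizon import three_part_estimate

from conftest import quadratic_beat


def synthetic_beats(n_beats, snr_db, seed):
    rec = u.generate(u.SyntheticParams(n_beats=n_beats, snr_db=snr_db, seed=seed))
    return rec, [u.ECGSignal(rec.noisy.samples[a:b], 360.0) for a, b in rec.beat_bounds]


class TestDetectQRSWindow:
    def test_centering_arithmetic(self):
        x = np.zeros(300)
        x[150] = 1.0
        x[140] = -0.3
        x[160] = -0.3
        w = u.detect_qrs_window(u.ECGSignal(x, 360.0), 60)
        assert (w.q_int, w.s_int) == (120, 180)
        assert (w.q, w.r, w.s) == (140, 150, 160)

    def test_ground_truth_troughs(self, clean_beat, clean_record, interval):
        w = u.detect_qrs_window(clean_beat, interval)
        t = clean_record.truth[0].fiducials
        assert w.r == t.r_index
        assert w.q == t.q_index
        assert w.s == t.s_index

    def test_monotone_segment_flagged(self):
        # strictly rising into R then falling: argmin hits the window boundary
        x = np.concatenate([np.linspace(-1, 1, 150), np.linspace(1, -1, 150)])
        w = u.detect_qrs_window(u.ECGSignal(x, 360.0), 60)
        assert w.q_at_boundary and w.s_at_boundary
        assert w.q == w.q_int and w.s == w.s_int

    def test_flat_beat_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            u.detect_qrs_window(u.ECGSignal(np.zeros(100), 360.0), 20)


class TestResidualMSV:
    def test_noiseless_polynomial_is_exact(self):
        beat = quadratic_beat()
        w = u.BeatWindows(q_int=120, q=140, r=150, s=160, s_int=180, t_end=299, interval=60)
        for N in (5, 11, 21, 41):
            assert u.residual_msv(beat, w, 2, N) < 1e-12

    def test_deterministic(self, noisy_record_35db, interval):
        a, b = noisy_record_35db.beat_bounds[0]
        beat = u.ECGSignal(noisy_record_35db.noisy.samples[a:b], 360.0)
        w = u.detect_qrs_window(beat, interval)
        assert u.residual_msv(beat, w, 2, 21) == u.residual_msv(beat, w, 2, 21)

    def test_matches_monte_carlo_expectation(self):
        """Polynomial + AWGN: the single-draw MSV lies within three standard
        deviations of the Monte-Carlo expectation over noise draws."""
        base = quadratic_beat()
        w = u.BeatWindows(q_int=120, q=140, r=150, s=160, s_int=180, t_end=299, interval=60)
        sigma = 0.05
        rng = np.random.default_rng(7)
        draws = np.array([
            u.residual_msv(
                u.ECGSignal(base.samples + rng.normal(0, sigma, 300), 360.0), w, 2, 9
            )
            for _ in range(200)
        ])
        single = u.residual_msv(
            u.ECGSignal(base.samples + rng.normal(0, sigma, 300), 360.0), w, 2, 9
        )
        assert abs(single - draws.mean()) < 3 * draws.std()

    def test_invalid_horizon(self):
        beat = quadratic_beat()
        w = u.BeatWindows(q_int=120, q=140, r=150, s=160, s_int=180, t_end=299, interval=60)
        with pytest.raises(ValueError, match="horizon"):
            u.residual_msv(beat, w, 2, 2)


class TestEstimateNopt:
    def test_zero_noise_tie_breaks_to_smallest_horizon(self):
        beats = [quadratic_beat(coeffs=(0.2 + 0.01 * k, -0.003, 1e-5)) for k in range(3)]
        # polynomial beats have a flat (zero) MSV curve; the window detector
        # needs a peak, so pass explicit windows via a monkey-ish tiny grid
        n_opt, curve = u.estimate_nopt(
            [_with_peak(b) for b in beats], degree=2, interval=60,
            n_grid=np.arange(3, 20, 2),
        )
        assert n_opt == 3 + 1
        assert np.all(curve.v_avg < 1e-10)

    def test_order_invariance(self, interval):
        _, beats = synthetic_beats(20, 20.0, 3)
        n1, c1 = u.estimate_nopt(beats, degree=2, interval=interval)
        n2, c2 = u.estimate_nopt(beats[::-1], degree=2, interval=interval)
        assert n1 == n2
        np.testing.assert_allclose(c1.v_avg, c2.v_avg, rtol=1e-12)

    def test_nopt_nondecreasing_in_noise(self, interval):
        votes = 0
        for seed in (1, 2, 3):
            ns = []
            for snr in (30.0, 20.0, 10.0):
                _, beats = synthetic_beats(30, snr, seed)
                ns.append(u.estimate_nopt(beats, degree=2, interval=interval)[0])
            votes += all(a <= b for a, b in zip(ns, ns[1:]))
        assert votes >= 2  # majority over seeds

    def test_degenerate_grid_rejected(self, interval):
        _, beats = synthetic_beats(2, 20.0, 0)
        with pytest.raises(ValueError, match="grid"):
            u.estimate_nopt(beats, degree=2, interval=interval, n_grid=np.arange(3, 10, 2))


def _with_peak(beat):
    """Add a narrow spike so R detection succeeds without changing the
    polynomial character away from the protected window."""
    x = beat.samples.copy()
    x[150] += 5.0
    return u.ECGSignal(x, beat.fs)


class TestBuildProfile:
    def windows(self, q, s, q_int=None, s_int=None):
        return u.BeatWindows(
            q_int=q_int if q_int is not None else q - 18,
            q=q, r=(q + s) // 2, s=s,
            s_int=s_int if s_int is not None else s + 18,
            t_end=299, interval=72,
        )

    def test_degenerate_equal_horizons(self):
        prof = u.build_profile(self.windows(140, 160), 3, 3, 300)
        assert np.all(prof.n_apt == 3)

    def test_exact_descent(self):
        w = self.windows(140, 160)  # q - q_int = 18 = n_opt - n_min
        prof = u.build_profile(w, 21, 3, 300)
        np.testing.assert_array_equal(prof.n_apt[122:141], np.arange(21, 2, -1))
        assert np.all(prof.n_apt[:122] == 21)
        assert np.all(prof.n_apt[140:161] == 3)

    def test_one_step_property_with_narrow_window(self):
        w = self.windows(140, 160, q_int=130, s_int=170)  # window < ramp
        prof = u.build_profile(w, 21, 3, 300)
        assert np.abs(np.diff(prof.n_apt)).max() <= 1
        assert prof.n_apt.min() == 3 and prof.n_apt.max() == 21

    def test_bounds_validation(self):
        with pytest.raises(ValueError, match="n_opt"):
            u.build_profile(self.windows(140, 160), 3, 5, 300)
        with pytest.raises(ValueError, match="beat_length"):
            u.build_profile(self.windows(140, 160), 21, 3, 100)
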