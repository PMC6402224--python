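# ufirecg

Adaptive-horizon **unbiased FIR (UFIR) smoothing** for single-lead ECG
denoising and morphological feature extraction.

ECG interpretation rests on a handful of morphological features — the
amplitudes and durations of the P wave, QRS complex and T wave, and the ST
slope — which must be measured from noisy recordings.  The classic signal
chain for this uses one-step linear prediction, but prediction is the
*least* accurate member of the estimation family: if no future values are
needed, smoothing with a small lag removes strictly more noise.  This
package implements that idea for practitioners working with MIT-BIH-style
recordings (360 Hz, MLII lead) or synthetic beats.

## The estimator

Measurements are modelled as `s_n = x_n + v_n` with `v_n` zero-mean noise
of unknown statistics.  On a horizon of `N` samples the degree-`l` p-shift
UFIR estimator forms

    x̂_{n|n-p} = Σ_{i=p}^{N-1+p} h_li(N, p) · s_{n-i},

where the gains `h` are the unique FIR weights satisfying the unbiasedness
(polynomial-reproduction) constraints

    Σ_i h_li(N, p) = 1,   Σ_i h_li(N, p) · i^u = 0   (1 ≤ u ≤ l),

obtained from the normal system of the N×(l+1) Vandermonde matrix,
`h = V (VᵀV)⁻¹ e₁`.  No noise statistics enter.  `p < 0` gives smoothing
with lag `q = −p` (the central choice `p = −(N−1)/2` is exactly the
Savitzky–Golay smoother), `p = 0` causal filtering, `p > 0` prediction.

Two horizons matter on a heartbeat: an optimal `N_opt` for the slow P/T
segments — estimated from the knee of the mean-square residual curve
`V(N) = E{(s_n − x̂_n)²}` averaged over beats — and the minimal
`N_min = l + 1` (exact interpolation, zero bias) across the fast QRS
excursion.  The adaptive smoother splits each beat into five parts:
`N_opt` on the outer slow parts, `N_min` on `[Q, S]`, and one-step ramps
between them inside a window centred on the R peak.  The denoised beat
then feeds a fiducial extractor: R/Q/S from extrema, QRS suppression by
linear bridging, P/T peaks, wave onsets/offsets from first-difference
extrema, amplitudes relative to the baseline at the P-wave offset, and the
ST angle `θ = arccos(a·b/|a||b|)` from a unit temporal step at S.

An order-2 linear predictor (Yule–Walker coefficients by the correlation
method) is included as the standard comparator, and a Fourier-series
synthetic ECG generator provides beats with known fiducial ground truth at
any SNR.

## Worked example

```sh
$ ufirecg evaluate --beats 20 --snr-db 35 --seed 1
 adaptive_smoother  RMSE = 0.00542 mV
       ufir_filter  RMSE = 0.03423 mV
    ufir_predictor  RMSE = 0.05649 mV
  linear_predictor  RMSE = 0.01600 mV
```

Twenty synthetic beats are generated at 35 dB input SNR and denoised four
ways; RMSE is measured against the known clean signal.  The adaptive
smoother (`N_opt = 21`, `l = 2`) is ~6× more accurate than the causal
UFIR filter, ~10× more accurate than the one-step UFIR predictor, and ~3×
more accurate than the q = 2 linear predictor at these conditions.

The same pipeline from Python:

```python
import ufirecg as u

rec = u.generate(u.SyntheticParams(n_beats=100, snr_db=20.0, seed=1))
beats = [u.ECGSignal(rec.noisy.samples[a:b], 360.0) for a, b in rec.beat_bounds]
n_opt, curve = u.estimate_nopt(beats, degree=2)   # -> 24 at these conditions
_, denoised = u.denoise_record(rec.noisy, rec.beat_bounds, n_opt=n_opt)
feats = u.extract_features(
    u.ECGSignal(denoised.estimates[:300], 360.0), u.default_interval(360.0)
)
print(feats.p_amp, feats.qrs_dur, feats.st_angle_deg)
```

Other CLI subcommands: `simulate`, `optimize-horizon`, `denoise`,
`features`, `predict-lp`.  WFDB format-212 records (MIT-BIH layout) are
read with `u.read_wfdb(path, channel="MLII")`; no database download is
needed for any test.

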