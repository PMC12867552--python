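# rnb — Rhythms and Background

`rnb` separates the rhythmic and the scale-free ("arrhythmic") parts of
electrophysiological time series *at the signal level*. Spectral
parameterization tools (FOOOF, IRASA) split a power spectrum into a
`1/f^β` background and oscillatory peaks, but they cannot hand back a
time series; instantaneous phase, amplitude and phase–amplitude coupling
(PAC) estimates therefore stay contaminated by the background. `rnb`
performs the separation on wavelet coefficients and synthesizes a purely
rhythmic time series that downstream event detectors and coupling
analyses can consume. It is written for sleep electrophysiologists
(EEG/iEEG) but applies to any recording dominated by power-law
background activity.

## The method

Each fixed-length epoch `s(t)` is expanded on an orthonormal fractional
spline wavelet basis (regularity order `α`, dyadic scales `j = 1..J`,
low-frequency residue `s_r`):

    s(t) = s_r(t) + Σ_j Σ_k w_{j,k} ψ^{(α)}_{j,k}(t)

1. **Scaling exponent.** With `D_j = log2(mean_k w_{j,k}²)`, the
   wavelet-domain exponent `β*` is the weighted least-squares slope of
   `D_j` on `j` over scales `[j1, j2]` with weights `n_j = 2⁻ʲN` (the
   coefficient counts). Under the orthonormal normalization this slope
   equals the Fourier exponent of a `1/f^β` process.
2. **Denoising.** Coefficients are soft-shrunk,
   `S(w) = w·max(1 − λ/|w|, 0)`, with the universal threshold
   `λ = σ√(2 ln N)` and `σ = median|w_{1,·}|/0.6745` estimated from the
   finest scale; the threshold is applied in the expansion-coefficient
   convention of the timescale family, so its effective weight falls as
   `2^{(1−j)/2}` toward coarser scales.
3. **Background removal and synthesis.** The shrunken coefficients are
   rescaled by `2^{−jβ*/2}` (flattening the scale-free trend) and the
   rhythmic series `s_R(t)` is synthesized on the order-`α₀` basis
   (`α₀ = 4`), omitting the residue. A shrinkage-only reconstruction
   (`s_denoised`, no rescale) is kept for amplitude readouts in input
   units.

On top of the core pipeline the package provides ensemble
"spectroscopy" (per-epoch `β*` distributions plus averaged rhythmic
Fourier spectra), sleep slow-wave and theta-burst detectors,
slow/fast-switcher classification by transition frequency
`f_tr = 1/(2τ)`, mean-corrected PAC, event-locked Morse-wavelet
scalograms, and the synthetic-data generators (scale-free backgrounds,
a Jansen–Rit-type neural mass alpha model, tapered sinusoid bursts)
used to validate recovery of oscillation amplitudes and exponents.

## Worked example

```python
import numpy as np
from rnb import OscillationSpec, compose_epoch, extract_rhythmic, gen_scale_free
from rnb.spectroscopy import band_peak_amplitude, periodogram

fs = 256.0
bg = gen_scale_free(beta=2.2, n=2048, fs=fs, seed=0)      # 8 s, unit variance
osc = OscillationSpec("neural_mass", frequency=10.5,
                      amplitude_level=0.7, readout_band=(9, 12))
epoch = compose_epoch(bg, [osc], fs, seed=1)              # 4 s alpha burst at 2-6 s

r = extract_rhythmic(epoch, fs)
print(f"beta* = {r.beta_star:.2f}")
print(f"retained coefficients: {100 * r.retained_fraction:.1f}%")
print(f"alpha readout = {band_peak_amplitude(r.s_denoised, fs, (9, 12)):.2f}")

f, p = periodogram(r.s_denoised, fs)
ff, pp = f[f > 1], p[f > 1]
print(f"rhythmic spectral peak at {ff[np.argmax(pp)]:.1f} Hz")
```

prints

```
beta* = 2.66
retained coefficients: 26.8%
alpha readout = 0.68
rhythmic spectral peak at 10.1 Hz
```

The epoch's raw spectrum is dominated by the `1/f^2.2` decay; after
extraction roughly a quarter of the wavelet coefficients survive
shrinkage and the rhythmic readout returns the injected oscillation:
its band-peak power (0.68, against a calibrated level of 0.7) and its
frequency (10.1 Hz, against a simulated 10.5 Hz alpha at finite-epoch
resolution). The exponent estimate (2.66 for a simulated 2.2
background) shows the known upward bias that a loud oscillation
exerts on the weighted scaling fit — see `docs/methods.md` for the
size of this coupling and when it matters.

A command-line surface wraps the same pipeline:

```bash
rnb simulate --beta 2.1 --n-epochs 300 --out epochs.npz --seed 1
rnb rnb epochs.npz --format npz --out rhythmic.npz --beta-table beta.tsv
rnb spectroscopy rhythmic.npz --prefix nrem3
rnb events recording.csv --fs 200 --region-band 0.5 2.5 --out events.tsv
rnb recover --design single_alpha --seed 7 --out-prefix recovery
```

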