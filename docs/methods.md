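# Methods

This note records the model assumptions, the numerical choices, and the
limits of what the synthetic validation shows. It documents decisions;
every number quoted as an outcome is computed by the test suite or by
`scripts/acceptance.py`, not asserted here.

## Signal model

An epoch is modeled as a scale-free background plus transient
oscillations. In the Fourier domain the background contributes
`c/f^β`; in the wavelet domain it makes the per-scale coefficient
power grow geometrically, `E[w²_j] ∝ 2^{jβ}` under L2 (orthonormal)
atom normalization. Oscillations occupy one or two adjacent scales at
specific times. The pipeline assumes a *single* power law per epoch: no
spectral knees, no time-varying exponent within an epoch, single
channel. Epochs are treated as independent.

## Wavelet transform

Analysis and synthesis use orthonormal fractional spline wavelets
realized in the frequency domain on the DFT grid (periodic boundary).
The fractional B-spline autocorrelation is evaluated exactly through
Hurwitz zeta functions, so arbitrary fractional orders are available
and the filter bank is paraunitary to machine precision (round-trip
error ~1e−14, exact energy accounting — both under test). Inputs are
mean-removed and symmetrically zero-padded to the next power of two;
the pad region is excluded from event analyses.

Normalization matters twice and the two uses differ deliberately:

- **Exponent estimation** is calibrated against L2-normalized
  coefficients, where the weighted log2-power slope equals the Fourier
  exponent directly (verified unbiased within 0.02 on synthetic
  `1/f^β` epochs across β ∈ [1, 2.5]).
- **Shrinkage** applies the universal threshold in the
  expansion-coefficient convention of the timescale family, whose
  atoms carry a `1/2^j` prefactor. In L2 units that is a per-scale
  threshold `2^{(1−j)/2}·λ`: the finest-scale noise floor is removed
  aggressively while coarse-scale oscillatory coefficients keep their
  amplitude. A single uniform L2 threshold was tried first and rejected
  because it eats 10–50 % of a low-amplitude oscillation's power in
  flat-background conditions, making recovered amplitudes strongly
  background-dependent.

## Parameters

| parameter | default | meaning / why |
|---|---|---|
| `j1, j2` | 1, 9 | scale range of the β* fit; fine scales carry most coefficients (weights `n_j = 2⁻ʲN`), the coarse end is limited by epoch duration |
| `J` | 8 | deepest scale synthesized; scale 9 enters only the fit |
| `a0` | 4 | base analysis order; smooth enough for oscillatory content |
| `alpha0` | 4 | synthesis order: compromise between spectral resolution (spindles) and temporal sharpness (slow waves) |
| `adaptive_alpha` | on | second analysis pass at `α = a0 + β*/2`; pass 1 (order `a0`) supplies the β* that makes the adapted order computable |
| λ | `σ√(2 ln N)` | universal threshold; `N` is the padded sample count; `σ` from the finest scale of the pass that is actually shrunk |

Adapted orders are quantized to 0.01 for the filter-bank cache; the
effect on coefficients is far below the stochastic variability between
epochs.

## Two reconstructions

`s_R` (shrink → rescale by `2^{−jβ*/2}` → synthesize without residue)
is *whitened*: its scale-free trend is flat, which is what event
detection and PAC need. Because the whitening gain is scale-dependent,
`s_R`'s spectral amplitudes are not in input units; amplitude readouts
("maximal rhythmic amplitude") therefore come from `s_denoised`, the
shrinkage-only reconstruction, which stays on the input scale. This is
the package's resolution of the proportionality constant left free in
the rescale definition.

## Synthetic data: what it emulates, what it does not

- **Backgrounds**: FFT-shaped white noise with `1/f^β` power and random
  phases, standardized per epoch, `β ~ N(target, 0.1)`. Circularly
  stationary by construction (no edge bias) — real recordings are not.
- **Alpha bursts**: a classical two-population + pyramidal neural mass
  model (canonical parameter set: gains 3.25/22 mV, rate constants
  100/50 s⁻¹, connectivity 135·{1, 0.8, 0.25, 0.25}, sigmoid
  v0 = 6 mV, e0 = 2.5 s⁻¹, r = 0.56 mV⁻¹, uniform 120–320 pulses/s
  drive), integrated by fixed-step Euler–Maruyama at ≤ 1/1024 s with a
  deterministic settled-state pre-roll. Produces a noisy ~10 Hz
  oscillation with realistic bandwidth.
- **Delta/alpha pairs** (dual design): Tukey(0.5)-tapered sinusoid
  bursts, since the neural mass model is alpha-specific.
- **Calibration**: each burst is scaled so its oscillation-alone
  Hann-periodogram band peak equals its amplitude level; levels and
  readouts then share a scale and ideal recovery has slope 1. The 15
  levels span one decade linearly (0.1–1.0 in PSD units of a
  unit-variance background), placing burst amplitudes at roughly
  0.3–1× the background's standard deviation.

What passing the recovery tests shows: the pipeline returns oscillation
amplitudes on the calibrated scale with near-unity slope across
background regimes, and its exponent estimates track the realized
background exponent on oscillation-free epochs with residual SD ≈ 0.04.
What it does not show: behavior under spectral knees, multifractal
backgrounds, nonstationary β within an epoch, or measurement artifacts
— none of which the generators produce.

### Known coupling between components

A calibrated oscillation whose band-peak PSD matches the level scale
carries several times the background's power at its wavelet scale. The
`n_j`-weighted log-power fit responds: β* is inflated by ~0.1–0.4
depending on level and background (largest for sigma-band bursts, whose
scale combines low background power with high fit leverage). This
coupling is intrinsic to a weighted least-squares scaling fit confronted
with loud narrowband transients; it is measured by the acceptance suite
rather than hidden, and it means per-epoch β* from rhythm-rich epochs
should be interpreted with care. Delta-range bursts perturb β* far
less.

## Event layer

Band filters are zero-phase 4th-order Butterworth responses applied as
the squared magnitude on the DFT grid (periodic boundary, after linear
detrending). The time-domain forward–backward realization was rejected:
its reflection-padding transients extend ~2 s at 0.5 Hz high-pass edges
and generate spurious slow half-waves at epoch boundaries.

Slow-wave candidates are successive zero-crossing half-wave pairs with
both durations in 125–1000 ms; the half-wave with lower mean gamma
(30–80 Hz) envelope power is the downstate. Detection criteria are
amplitude-free, hence scale-invariant; a band-relevance guard (the
filtered trace must retain ≥ 10 % of the signal RMS) keeps stop-band
residue from producing events. Region-adaptive detection conjoins the
canonical delta pass with a locally dominant band pass; hyper-peak
coincidence within 250 ms counts as the same event (the conjunction
tolerance is a package choice). Switcher classes come from a
2-component EM Gaussian mixture on `f_tr` (5 k-means-seeded restarts,
tol 1e−6, seeded); the threshold is the equal-posterior crossing
between the component means, with the lower-mean component labeled
slow. Theta bursts require an envelope peak ≥ +3 SD with start/stop at
the flanking +1 SD crossings and a 0.4–1 s duration; the baseline is
the ensemble mean/SD of the theta envelope across the recording's
epochs, not the event window. PAC is the mean-corrected mixed moment
`|⟨A e^{iφ}⟩ − ⟨A⟩⟨e^{iφ}⟩|`; it vanishes exactly for constant
amplitude and equals 1/2 for `A = 1 + cos φ` — both closed forms are
tested. Scalograms use the analytic Morse wavelet (time-bandwidth 20,
shape 3), peak-normalized so a unit sinusoid at a filter's center
frequency reads ~1.

## Degenerate inputs and tie rules

All-zero epochs return a zero rhythmic series with β* = 0 and retained
fraction 0. All-zero wavelet scales yield a −∞ log-power sentinel with
a warning and are invalid inside the fit range. β* outside [0, 4]
triggers a warning, not an error. Spectral peak detection requires
strict inequality against both neighbors (plateaus are not peaks) and
a prominence floor relative to the in-band median, with a tiny
absolute guard for numerically sparse spectra. Identical transition
frequencies across all events short-circuit the mixture fit into a
flagged single class.

## Limitations

- The β*-oscillation coupling above: exponents from epochs with strong
  rhythms are biased upward.
- Whitened (`s_R`) amplitudes are not in input units; use
  `s_denoised`-based readouts for amplitudes.
- Periodic boundary conditions trade reflection transients for wrap
  transients; both matter only near epoch edges, and event analyses
  should discard pad regions.
- The sleep-event layer is validated on constructed fixtures and
  synthetic couplings, not on annotated recordings; detector
  thresholds mirror published conventions rather than re-derived
  optima.
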