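"""Synthetic-data generators and the amplitude/beta recovery experiments.

The generators emulate the study conditions the method is validated
against: scale-free ``1/f^beta`` backgrounds (spectrally shaped white
noise with random Fourier phases, per-epoch ``beta ~ N(target, 0.1)``),
transient alpha oscillations from a phenomenological neural mass model,
and generic tapered sinusoid bursts for multi-oscillation designs.

Amplitude calibration
---------------------
Oscillation amplitude levels are expressed on the scale of the band-peak
PSD readout of the oscillation alone: each generated waveform is rescaled
so that its own Hann-periodogram peak inside its readout band equals its
level.  Readouts and levels therefore share one scale and perfect
recovery corresponds to a regression slope of one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from rnb.core import RnBConfig, extract_rhythmic
from rnb.spectroscopy import band_peak_amplitude


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# generators


def gen_scale_free(beta: float, n: int, fs: float, seed) -> np.ndarray:
    """Scale-free background: white noise shaped to a ``1/f^beta`` power
    law with random Fourier phases; zero mean, unit variance.

    ``n`` must be a power of two so epochs feed the dyadic transform
    without padding.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"epoch length {n} is not a power of two")
    rng = _as_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


@dataclass
class NeuralMassParams:
    """Canonical parameter set of the two-population (excitatory,
    inhibitory) + pyramidal phenomenological neural mass model.

    Average synaptic gains ``A`` (excitatory) and ``B`` (inhibitory) in
    mV, lumped rate constants ``a``, ``b`` in 1/s, connectivity constants
    ``C1..C4`` proportional to ``C = 135``, and the population sigmoid
    (``v0`` mV, ``e0`` 1/s, ``r`` 1/mV).  The pyramidal population is
    driven by a nonspecific input ``p(t)`` drawn uniformly in
    ``[p_min, p_max]`` pulses/s at every integration step.
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 100.0
    b: float = 50.0
    C: float = 135.0
    v0: float = 6.0
    e0: float = 2.5
    r: float = 0.56
    p_min: float = 120.0
    p_max: float = 320.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("rate constants must be > 0")

    @property
    def C1(self) -> float:
        return self.C

    @property
    def C2(self) -> float:
        return 0.8 * self.C

    @property
    def C3(self) -> float:
        return 0.25 * self.C

    @property
    def C4(self) -> float:
        return 0.25 * self.C


class IntegrationError(RuntimeError):
    pass


def _neural_mass_batch(
    duration_s: float, fs: float, params: NeuralMassParams, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Integrate ``n`` independent realizations; returns (n, samples).

    Fixed-step Euler–Maruyama on an oversampled grid (step <= 1/1024 s,
    always <= 1/fs); the stochastic drive is redrawn every step.
    """
    n_out = int(round(duration_s * fs))
    if n_out < fs:
        raise ValueError("neural mass simulation needs at least 1 s of samples")
    over = max(1, int(np.ceil(1024.0 / fs)))
    dt = 1.0 / (fs * over)
    p = params

    def sigm(v):
        return 2.0 * p.e0 / (1.0 + np.exp(p.r * (p.v0 - v)))

    y = np.zeros((6, n))
    out = np.empty((n, n_out))
    drive_lo, drive_hi = p.p_min, p.p_max
    # deterministic pre-roll with the mean drive: start the oscillation
    # from the model's settled state instead of an unphysical step at y=0
    mean_drive = np.full(n, 0.5 * (drive_lo + drive_hi))
    for _ in range(int(round(1.5 / dt))):
        y0, y1, y2, y3, y4, y5 = y
        dy3 = p.A * p.a * sigm(y1 - y2) - 2.0 * p.a * y3 - p.a**2 * y0
        dy4 = p.A * p.a * (mean_drive + p.C2 * sigm(p.C1 * y0)) - 2.0 * p.a * y4 - p.a**2 * y1
        dy5 = p.B * p.b * p.C4 * sigm(p.C3 * y0) - 2.0 * p.b * y5 - p.b**2 * y2
        y = y + dt * np.array([y3, y4, y5, dy3, dy4, dy5])
    for i in range(n_out * over):
        y0, y1, y2, y3, y4, y5 = y
        drive = rng.uniform(drive_lo, drive_hi, size=n) if drive_hi > drive_lo else np.full(n, drive_lo)
        dy3 = p.A * p.a * sigm(y1 - y2) - 2.0 * p.a * y3 - p.a**2 * y0
        dy4 = p.A * p.a * (drive + p.C2 * sigm(p.C1 * y0)) - 2.0 * p.a * y4 - p.a**2 * y1
        dy5 = p.B * p.b * p.C4 * sigm(p.C3 * y0) - 2.0 * p.b * y5 - p.b**2 * y2
        y = y + dt * np.array([y3, y4, y5, dy3, dy4, dy5])
        if i % over == over - 1:
            k = i // over
            if not np.all(np.isfinite(y)):
                raise IntegrationError(
                    f"neural mass trajectory diverged at t={k / fs:.3f}s (step {dt:.2e}s)"
                )
            out[:, k] = y[1] - y[2]
    return out - out.mean(axis=1, keepdims=True)


def gen_neural_mass(
    duration_s: float, fs: float, params: NeuralMassParams | None = None, seed=None
) -> np.ndarray:
    """One realization of the neural-mass alpha oscillation (pyramidal
    population potential, mean-removed)."""
    return _neural_mass_batch(duration_s, fs, params or NeuralMassParams(), _as_rng(seed), 1)[0]


# ---------------------------------------------------------------------------
# epoch composition


@dataclass
class OscillationSpec:
    """A transient oscillation to superimpose on a background epoch."""

    generator: str = "neural_mass"        # "neural_mass" | "sinusoid_burst"
    frequency: float = 10.5
    amplitude_level: float = 1.0
    onset_s: float = 2.0
    duration_s: float = 4.0
    readout_band: tuple[float, float] | None = None

    def band(self) -> tuple[float, float]:
        if self.readout_band is not None:
            return self.readout_band
        return (self.frequency - 1.5, self.frequency + 1.5)

    def __post_init__(self) -> None:
        if self.amplitude_level <= 0:
            raise ValueError("amplitude_level must be > 0")


@dataclass
class SimulationSpec:
    """Design of one simulated condition ensemble."""

    beta_mean: float = 2.11
    beta_sd: float = 0.1
    n_epochs_total: int = 300
    n_with_osc: int = 200
    n_analyzed: int = 60
    epoch_s: float = 8.0
    fs: float = 256.0
    oscillations: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_analyzed > self.n_epochs_total or self.n_with_osc > self.n_epochs_total:
            raise ValueError("analyzed/oscillation counts cannot exceed the total epochs")


def _render_burst(
    spec: OscillationSpec, fs: float, rng: np.random.Generator, params: NeuralMassParams | None
) -> np.ndarray:
    n_burst = int(round(spec.duration_s * fs))
    if spec.generator == "neural_mass":
        return _neural_mass_batch(spec.duration_s, fs, params or NeuralMassParams(), rng, 1)[0]
    if spec.generator == "sinusoid_burst":
        from scipy.signal import windows

        t = np.arange(n_burst) / fs
        return np.sin(2.0 * np.pi * spec.frequency * t) * windows.tukey(n_burst, alpha=0.5)
    raise ValueError(f"unknown generator {spec.generator!r}")


def _place_and_calibrate(
    burst: np.ndarray, spec: OscillationSpec, n: int, fs: float
) -> np.ndarray:
    start = int(round(spec.onset_s * fs))
    if start + burst.size > n:
        raise ValueError("oscillation window does not fit in the epoch")
    placed = np.zeros(n)
    placed[start : start + burst.size] = burst
    p0 = band_peak_amplitude(placed, fs, spec.band())
    return placed * np.sqrt(spec.amplitude_level / p0)


def oscillation_waveform(
    spec: OscillationSpec, n: int, fs: float, seed=None, params: NeuralMassParams | None = None
) -> np.ndarray:
    """Render one oscillation into a length-``n`` epoch-aligned array,
    calibrated so its band-peak PSD readout equals its amplitude level."""
    rng = _as_rng(seed)
    return _place_and_calibrate(_render_burst(spec, fs, rng, params), spec, n, fs)


def compose_epoch(
    background: np.ndarray,
    oscillations: list[OscillationSpec],
    fs: float,
    seed=None,
    params: NeuralMassParams | None = None,
) -> np.ndarray:
    """Additively superimpose calibrated oscillations on a background."""
    rng = _as_rng(seed)
    epoch = np.asarray(background, dtype=float).copy()
    bands = []
    for spec in oscillations:
        lo, hi = spec.band()
        for plo, phi in bands:
            if lo < phi and plo < hi:
                warnings.warn(
                    f"oscillations overlap in band [{max(lo, plo)}, {min(hi, phi)}] Hz",
                    RuntimeWarning,
                )
        bands.append((lo, hi))
        epoch += oscillation_waveform(spec, epoch.size, fs, rng, params)
    return epoch


# ---------------------------------------------------------------------------
# recovery experiments

#: Background target exponents of the single-oscillation design.
SINGLE_DESIGN_BETAS = (1.69, 2.11, 2.49)
#: The 15 amplitude levels, linearly spanning one decade (arbitrary units).
DEFAULT_LEVELS = tuple(np.linspace(0.1, 1.0, 15))
ALPHA_BAND = (9.0, 12.0)
DUAL_DELTA_BAND = (2.0, 4.0)
DUAL_ALPHA_BAND = (12.0, 14.0)
#: Fixed alpha level of the dual design (mid-range).
DUAL_ALPHA_LEVEL = 0.55


def _simulate_condition(
    beta_target: float,
    oscillations: list[OscillationSpec],
    rng: np.random.Generator,
    *,
    n_total: int,
    n_osc: int,
    n_analyzed: int,
    n_samples: int,
    fs: float,
    background_scale: float,
    config: RnBConfig,
    bands: dict[str, tuple[float, float]],
) -> list[dict]:
    """Generate and analyze one (background, level) cell.

    Oscillation membership and the analyzed subset are drawn over the full
    ensemble; only analyzed epochs are materialized.
    """
    osc_flags = np.zeros(n_total, dtype=bool)
    osc_flags[rng.choice(n_total, size=n_osc, replace=False)] = True
    analyzed = rng.choice(n_total, size=n_analyzed, replace=False)
    n_osc_analyzed = int(osc_flags[analyzed].sum())

    # neural-mass realizations for all oscillation-bearing epochs of the
    # cell are integrated in one vectorized batch
    batches: dict[int, np.ndarray] = {}
    cursor = dict.fromkeys(range(len(oscillations)), 0)
    for i, spec in enumerate(oscillations):
        if spec.generator == "neural_mass" and n_osc_analyzed:
            batches[i] = _neural_mass_batch(
                spec.duration_s, fs, NeuralMassParams(), rng, n_osc_analyzed
            )

    rows = []
    for idx in analyzed:
        beta_i = rng.normal(beta_target, 0.1)
        epoch = background_scale * gen_scale_free(max(beta_i, 0.0), n_samples, fs, rng)
        has_osc = bool(osc_flags[idx])
        if has_osc:
            for i, spec in enumerate(oscillations):
                if i in batches:
                    burst = batches[i][cursor[i]]
                    cursor[i] += 1
                else:
                    burst = _render_burst(spec, fs, rng, None)
                epoch = epoch + _place_and_calibrate(burst, spec, n_samples, fs)
        r = extract_rhythmic(epoch, fs, config)
        row = {
            "beta_target": beta_target,
            "beta_sim": beta_i,
            "has_osc": has_osc,
            "beta_hat": r.beta_star,
        }
        for name, band in bands.items():
            row[f"amp_{name}"] = band_peak_amplitude(r.s_denoised, fs, band)
        rows.append(row)
    return rows


def _ols(table: pd.DataFrame, formula: str):
    import statsmodels.formula.api as smf

    return smf.ols(formula, data=table).fit()


def _reg_rows(model, label: str) -> list[dict]:
    rows = []
    for name in model.params.index:
        rows.append(
            {
                "model": label,
                "term": name,
                "slope": float(model.params[name]),
                "t": float(model.tvalues[name]),
                "p": float(model.pvalues[name]),
                "r2": float(model.rsquared),
            }
        )
    return rows


def run_recovery_experiment(
    design: str = "single_alpha",
    seed: int = 0,
    *,
    n_epochs_total: int = 300,
    n_with_osc: int = 200,
    n_analyzed: int = 60,
    levels=None,
    backgrounds=None,
    background_scale: float = 1.0,
    fs: float = 256.0,
    epoch_s: float = 8.0,
    config: RnBConfig | None = None,
) -> dict:
    """Run an amplitude/beta recovery experiment and fit its regressions.

    ``single_alpha``: a 4-s neural-mass alpha burst (10.5 Hz) at 15
    calibrated levels within three scale-free background regimes.
    ``dual_delta_alpha``: a 3 Hz delta burst varied over 15 levels
    concurrent with a fixed 13 Hz alpha burst (both tapered sinusoids).

    Analyzed epochs that carry no oscillation enter the regressions with
    level 0.  Returns ``{"epochs": per-epoch table, "regressions":
    regression table, "per_condition": per-background slope table}``.
    """
    rng = np.random.default_rng(seed)
    config = config or RnBConfig()
    n_samples = int(round(epoch_s * fs))
    levels = list(DEFAULT_LEVELS if levels is None else levels)

    rows = []
    if design == "single_alpha":
        bgs = list(SINGLE_DESIGN_BETAS if backgrounds is None else backgrounds)
        bands = {"alpha": ALPHA_BAND}
        for beta_t in bgs:
            for level in levels:
                osc = OscillationSpec(
                    generator="neural_mass",
                    frequency=10.5,
                    amplitude_level=level,
                    readout_band=ALPHA_BAND,
                )
                for row in _simulate_condition(
                    beta_t, [osc], rng,
                    n_total=n_epochs_total, n_osc=n_with_osc, n_analyzed=n_analyzed,
                    n_samples=n_samples, fs=fs, background_scale=background_scale,
                    config=config, bands=bands,
                ):
                    row["level"] = level if row["has_osc"] else 0.0
                    rows.append(row)
    elif design == "dual_delta_alpha":
        bgs = list((2.11,) if backgrounds is None else backgrounds)
        bands = {"delta": DUAL_DELTA_BAND, "alpha": DUAL_ALPHA_BAND}
        for beta_t in bgs:
            for level in levels:
                oscs = [
                    OscillationSpec(
                        generator="sinusoid_burst", frequency=3.0,
                        amplitude_level=level, readout_band=DUAL_DELTA_BAND,
                    ),
                    OscillationSpec(
                        generator="sinusoid_burst", frequency=13.0,
                        amplitude_level=DUAL_ALPHA_LEVEL, readout_band=DUAL_ALPHA_BAND,
                    ),
                ]
                for row in _simulate_condition(
                    beta_t, oscs, rng,
                    n_total=n_epochs_total, n_osc=n_with_osc, n_analyzed=n_analyzed,
                    n_samples=n_samples, fs=fs, background_scale=background_scale,
                    config=config, bands=bands,
                ):
                    row["level"] = level if row["has_osc"] else 0.0
                    rows.append(row)
    else:
        raise ValueError(f"unknown design {design!r}")

    table = pd.DataFrame(rows)
    reg_rows: list[dict] = []
    per_condition = []

    if design == "single_alpha":
        table["bg_c"] = table["beta_target"] - np.mean(sorted(set(table["beta_target"])))
        m_amp = _ols(table, "amp_alpha ~ level + bg_c + level:bg_c")
        reg_rows += _reg_rows(m_amp, "amp~level+bg+level:bg")
        for beta_t, sub in table.groupby("beta_target"):
            m = _ols(sub, "amp_alpha ~ level")
            per_condition.append(
                {"beta_target": beta_t, "slope": float(m.params["level"]), "r2": float(m.rsquared)}
            )
        reg_rows += _reg_rows(_ols(table, "beta_hat ~ level"), "beta~level")
        reg_rows += _reg_rows(_ols(table, "beta_hat ~ beta_target"), "beta~background")
        reg_rows += _reg_rows(_ols(table, "beta_hat ~ beta_sim"), "beta~background_realized")
    else:
        reg_rows += _reg_rows(_ols(table, "amp_delta ~ level"), "delta_amp~delta_level")
        # cross-talk is defined on epochs that actually carry the fixed
        # alpha oscillation; control epochs carry neither oscillation and
        # would fake a positive slope through their empty sigma band
        osc = table[table["has_osc"]]
        reg_rows += _reg_rows(_ols(osc, "amp_alpha ~ level"), "alpha_amp~delta_level")
        reg_rows += _reg_rows(_ols(table, "beta_hat ~ level"), "beta~delta_level")

    return {
        "epochs": table,
        "regressions": pd.DataFrame(reg_rows),
        "per_condition": pd.DataFrame(per_condition),
    }


def _coef(res: dict, model: str, term: str, what: str = "slope") -> float:
    r = res["regressions"]
    return float(r[(r.model == model) & (r.term == term)].iloc[0][what])


def recovery_summary(single: dict, dual: dict) -> dict:
    """Headline quantities of the two recovery experiments.

    single-oscillation design: the amplitude-on-level main-effect slope
    and model R^2, the minimum per-background-condition slope, and the
    variance in beta* explained by amplitude level vs background
    condition.  dual design: the delta recovery slope and R^2, and the
    alpha-readout cross-talk slope.
    """
    return {
        "amp_slope": _coef(single, "amp~level+bg+level:bg", "level"),
        "amp_r2": _coef(single, "amp~level+bg+level:bg", "level", "r2"),
        "min_condition_slope": float(single["per_condition"]["slope"].min()),
        "beta_on_level_r2": _coef(single, "beta~level", "level", "r2"),
        "beta_on_background_r2": _coef(single, "beta~background", "beta_target", "r2"),
        "delta_slope": _coef(dual, "delta_amp~delta_level", "level"),
        "delta_r2": _coef(dual, "delta_amp~delta_level", "level", "r2"),
        "alpha_crosstalk_slope": _coef(dual, "alpha_amp~delta_level", "level"),
    }
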