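"""Orthonormal fractional spline wavelet filter banks and the dyadic
timescale transform.

The analysis/synthesis pair is realized in the frequency domain on the DFT
grid with periodic boundary conditions.  Working with frequency-sampled
filters permits *fractional* regularity orders ``alpha`` (the smoothness of
the spline basis, which may be adapted to the scale-free exponent of the
data) while retaining exact perfect reconstruction: no filter truncation is
involved.

Construction
------------
The symmetric fractional B-spline of degree ``alpha`` has Fourier transform
``B(w) = |sin(w/2) / (w/2)|^(alpha+1)``.  Orthonormalizing by the spline
autocorrelation ``A(w) = sum_n |B(w + 2 pi n)|^2`` yields the scaling
function ``phi = B / sqrt(A)`` and the conjugate-mirror filter pair

    H(w) = sqrt(2) |cos(w/2)|^(alpha+1) sqrt(A(w) / A(2w))
    G(w) = exp(-i w) H(w + pi)

The autocorrelation is evaluated exactly through the Hurwitz zeta function
(every aliased term shares the same ``|sin|`` factor), so the filter bank is
paraunitary to machine precision and the discrete transform is orthonormal:
wavelet atoms are L2-normalized and energy is conserved across scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import zeta as _hurwitz_zeta


class LengthError(ValueError):
    """Raised for epoch lengths the dyadic transform cannot handle."""


class ScaleError(ValueError):
    """Raised when the requested number of scales exceeds the dyadic depth."""


class DataError(ValueError):
    """Raised for non-finite input samples."""


def _spline_autocorrelation(q: np.ndarray, order: float) -> np.ndarray:
    """Autocorrelation ``A(w)`` of the fractional B-spline, ``q = w / 2pi``.

    Uses ``A(w) = |sinc(q)|^s + |2 sin(pi q)|^s (2 pi)^-s
    [zeta(s, 1+q) + zeta(s, 1-q)]`` with ``s = 2 alpha + 2``; the first term
    is the ``n = 0`` alias, the zeta terms sum the rest exactly.
    """
    s = 2.0 * order + 2.0
    q = np.asarray(q, dtype=float)
    main = np.abs(np.sinc(q)) ** s
    tail = (np.abs(2.0 * np.sin(np.pi * q)) ** s / (2.0 * np.pi) ** s) * (
        _hurwitz_zeta(s, 1.0 + q) + _hurwitz_zeta(s, 1.0 - q)
    )
    return main + tail


def _filters(order: float, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Low/high-pass filter spectra sampled on the length-``m`` DFT grid."""
    k = np.arange(m)
    q = k / m                      # w / 2pi in [0, 1)
    q2 = (2 * k % m) / m           # frac(2q), the decimated grid
    a_w = _spline_autocorrelation(q, order)
    a_2w = _spline_autocorrelation(q2, order)
    low = np.sqrt(2.0) * np.abs(np.cos(np.pi * q)) ** (order + 1.0) * np.sqrt(a_w / a_2w)
    # conjugate mirror: G(w) = e^{-iw} H(w + pi)
    high = np.exp(-2j * np.pi * q) * np.roll(low, -(m // 2))
    return low.astype(complex), high


@dataclass
class WaveletBasis:
    """Frequency-sampled orthonormal fractional spline wavelet basis.

    Parameters
    ----------
    alpha : float
        Regularity (smoothness) order of the spline family; fractional
        values are allowed, ``alpha = 0`` gives the least regular member.
    N : int
        Epoch length in samples; must be a power of two.
    """

    alpha: float
    N: int
    _levels: dict = field(default_factory=dict, repr=False)
    _f0: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"wavelet order alpha must be >= 0, got {self.alpha}")
        n = int(self.N)
        if n < 2 or (n & (n - 1)) != 0:
            raise LengthError(
                f"epoch length {self.N} is not a power of two; detrend and "
                "symmetrically zero-pad epochs to the next power of two "
                "(see rnb.core.pad_to_pow2) before analysis"
            )
        self.N = n

    @property
    def max_scale(self) -> int:
        """Deepest admissible scale, ``log2(N) - 1``."""
        return int(np.log2(self.N)) - 1

    def filters(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Analysis/synthesis filter spectra for decomposition level ``j``."""
        if j not in self._levels:
            self._levels[j] = _filters(self.alpha, self.N >> (j - 1))
        return self._levels[j]

    def atom(self, j: int, k: int) -> np.ndarray:
        """Explicit time-domain sample of the (j, k) wavelet atom."""
        coeffs = [np.zeros(self.N >> jj) for jj in range(1, j + 1)]
        coeffs[j - 1][k] = 1.0
        dec = TimescaleDecomposition(
            coefficients=coeffs, residue=np.zeros(self.N >> j), N=self.N, fs=1.0, alpha=self.alpha
        )
        return synthesize(dec, self, include_residue=False)

    @property
    def f0(self) -> float:
        """Characteristic mother-wavelet frequency (fraction of fs).

        Defined from the spectral peak of the scale-1 atom so that scale
        ``j`` is centered on ``f_j = 2**(-j) * f0 * fs``.  Computed
        numerically once per basis.
        """
        if self._f0 is None:
            # a deeper atom samples the mother wavelet's spectrum finely;
            # dyadic self-similarity then rescales its peak to scale 1
            j = min(3, self.max_scale)
            atom = self.atom(j, (self.N >> j) // 2)
            spec = np.abs(np.fft.rfft(atom))
            nu_peak = np.argmax(spec) / self.N
            self._f0 = (2.0**j) * nu_peak
        return self._f0


@dataclass
class TimescaleDecomposition:
    """Dyadic wavelet coefficients plus the low-frequency residue.

    ``coefficients[j-1]`` holds the ``n_j = 2**-j * N`` scale-``j`` values
    ``w_{j,k}``; ``residue`` is the coarse approximation complementing the
    wavelet scales (length ``2**-J * N``).
    """

    coefficients: list[np.ndarray]
    residue: np.ndarray
    N: int
    fs: float
    alpha: float

    @property
    def J(self) -> int:
        return len(self.coefficients)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.size for c in self.coefficients])

    def scale_frequencies(self, f0: float) -> np.ndarray:
        """Center frequency ``f_j = 2**(-j) * f0 * fs`` of each scale, Hz."""
        j = np.arange(1, self.J + 1)
        return (2.0 ** (-j.astype(float))) * f0 * self.fs

    def copy(self) -> "TimescaleDecomposition":
        return TimescaleDecomposition(
            coefficients=[c.copy() for c in self.coefficients],
            residue=self.residue.copy(),
            N=self.N,
            fs=self.fs,
            alpha=self.alpha,
        )

    def truncated(self, J: int) -> "TimescaleDecomposition":
        """Keep scales ``1..J`` only; the dropped coarse content is zeroed."""
        if J > self.J:
            raise ScaleError(f"cannot truncate to J={J}: only {self.J} scales present")
        return TimescaleDecomposition(
            coefficients=[c.copy() for c in self.coefficients[:J]],
            residue=np.zeros(self.N >> J),
            N=self.N,
            fs=self.fs,
            alpha=self.alpha,
        )

    def energy(self, include_residue: bool = True) -> float:
        e = sum(float(np.sum(c**2)) for c in self.coefficients)
        if include_residue:
            e += float(np.sum(self.residue**2))
        return e


def build_basis(alpha: float, N: int) -> WaveletBasis:
    """Construct the orthonormal fractional spline basis of order ``alpha``
    for epochs of (power-of-two) length ``N``."""
    return WaveletBasis(alpha=float(alpha), N=int(N))


def analyze(
    signal: np.ndarray, basis: WaveletBasis, J: int, fs: float = 1.0
) -> TimescaleDecomposition:
    """Decompose ``signal`` onto scales ``1..J`` of ``basis``.

    Each level halves the approximation: the scale-``j`` detail holds
    ``n_j = 2**-j * N`` coefficients, and the final approximation is
    returned as the residue.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size != basis.N:
        raise LengthError(f"signal length {x.size} does not match basis N={basis.N}")
    if not np.all(np.isfinite(x)):
        raise DataError("signal contains NaN or Inf samples")
    if J > basis.max_scale:
        raise ScaleError(f"J={J} exceeds max scale log2(N)-1 = {basis.max_scale}")
    if J < 1:
        raise ScaleError("J must be >= 1")

    details: list[np.ndarray] = []
    c_hat = np.fft.fft(x)
    for j in range(1, J + 1):
        m = c_hat.size
        low, high = basis.filters(j)
        half = m // 2
        y_low = c_hat * np.conj(low)
        y_high = c_hat * np.conj(high)
        # decimation by 2 in the frequency domain
        c_hat = 0.5 * (y_low[:half] + y_low[half:])
        d_hat = 0.5 * (y_high[:half] + y_high[half:])
        details.append(np.fft.ifft(d_hat).real)
    residue = np.fft.ifft(c_hat).real
    return TimescaleDecomposition(
        coefficients=details, residue=residue, N=basis.N, fs=fs, alpha=basis.alpha
    )


def synthesize(
    decomp: TimescaleDecomposition, basis: WaveletBasis, include_residue: bool = True
) -> np.ndarray:
    """Invert the timescale transform.

    With unmodified coefficients and ``include_residue=True`` this
    reproduces the analyzed signal exactly (perfect reconstruction); with
    ``include_residue=False`` the coarse approximation is omitted, as in
    rhythmic synthesis.
    """
    if decomp.N != basis.N:
        raise LengthError(
            f"decomposition N={decomp.N} does not match basis N={basis.N}"
        )
    J = decomp.J
    if include_residue:
        c_hat = np.fft.fft(np.asarray(decomp.residue, dtype=float))
    else:
        c_hat = np.zeros(decomp.N >> J, dtype=complex)
    for j in range(J, 0, -1):
        if decomp.coefficients[j - 1].size != decomp.N >> j:
            raise LengthError(
                f"scale {j} holds {decomp.coefficients[j - 1].size} coefficients, "
                f"expected {decomp.N >> j}"
            )
        d_hat = np.fft.fft(np.asarray(decomp.coefficients[j - 1], dtype=float))
        low, high = basis.filters(j)
        up_c = np.concatenate([c_hat, c_hat])
        up_d = np.concatenate([d_hat, d_hat])
        c_hat = up_c * low + up_d * high
    return np.fft.ifft(c_hat).real


def scale_log_power(decomp: TimescaleDecomposition) -> np.ndarray:
    """Average log2 power per scale, ``D_j = log2(mean_k w_{j,k}^2)``.

    All-zero scales return ``-inf`` (flagged with a warning) so that the
    caller can exclude them from scaling fits.
    """
    import warnings

    out = np.empty(decomp.J)
    for j, c in enumerate(decomp.coefficients, start=1):
        p = float(np.mean(c**2))
        if p == 0.0:
            warnings.warn(f"scale {j} has zero power; D_j set to -inf", RuntimeWarning)
            out[j - 1] = -np.inf
        else:
            out[j - 1] = np.log2(p)
    return out
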