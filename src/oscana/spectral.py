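"""Segment-averaged spectra, coherence with analytic confidence limit,
Morlet-wavelet power, and frequency-band summaries.

The coherence estimator follows the classic segment-averaging scheme:
both series are standardized, split into M disjoint segments of length L
(remainder dropped), per-segment auto/cross spectra are averaged, and
magnitude-squared coherence |Sxy|^2/(Sxx*Syy) is formed on the averages.
The significance threshold at level ``alpha`` for M averaged segments is
the analytic limit ``1 - (1-alpha)**(1/(M-1))``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumEstimate",
    "CoherenceResult",
    "BandSummary",
    "BAND_PROFILES",
    "standardize",
    "segment_spectra",
    "coherence",
    "coherence_confidence_limit",
    "wavelet_power",
    "band_summary",
    "band_power",
]

#: Band definitions per species profile (Hz, inclusive edges).  Profile
#: selection is mandatory wherever bands are implied: human and mouse
#: theta differ and must never be mixed silently.
BAND_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "human": {
        "theta": (4.0, 8.0),
        "gamma": (30.0, 100.0),
        "low_gamma": (30.0, 70.0),
        "high_gamma": (70.0, 100.0),
    },
    "mouse": {
        "theta": (7.0, 12.0),
        "gamma": (30.0, 100.0),
        "low_gamma": (30.0, 70.0),
        "high_gamma": (70.0, 100.0),
    },
}


@dataclass
class SpectrumEstimate:
    """Segment-averaged auto/cross spectral densities."""

    freqs: np.ndarray
    Sxx: np.ndarray
    Syy: np.ndarray
    Sxy: np.ndarray
    M: int
    L: int
    remainder: int  # samples dropped from the tail


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coherence: np.ndarray
    M: int
    alpha: float
    conf_limit: float


@dataclass
class BandSummary:
    band: tuple[float, float]
    mean_value: float
    peak_freq: float
    peak_value: float


def standardize(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-SD copy of a series; error on zero variance."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize expects a 1-D series of length >= 2")
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant (zero-variance) series")
    return (x - x.mean()) / sd


def _segment_tapers(L: int, taper: str) -> np.ndarray:
    """Return tapers as a (n_tapers, L) stack (one row unless multitaper)."""
    if taper == "boxcar":
        return np.ones((1, L))
    if taper == "hann":
        return sps.windows.hann(L, sym=False)[None, :]
    if taper == "multitaper":
        nw = 3.0
        k = int(2 * nw - 1)
        return sps.windows.dpss(L, nw, Kmax=k)
    raise ValueError(f"unknown taper {taper!r}; use boxcar, hann or multitaper")


def segment_spectra(
    x: np.ndarray,
    y: np.ndarray,
    L: int,
    fs: float = 1.0,
    taper: str = "hann",
    pre_standardize: bool = True,
) -> SpectrumEstimate:
    """Average per-segment auto/cross spectra over M = floor(N/L) disjoint
    segments; the remainder is dropped and logged.

    Densities use the usual one-sided Welch scaling, so ``sum(Sxx)*df``
    recovers the (windowed) signal variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    n = x.size
    L = int(L)
    if L < 2:
        raise ValueError(f"segment length L must be >= 2, got {L}")
    if n < L:
        raise ValueError(f"series length {n} shorter than segment length {L}")
    if pre_standardize:
        x = standardize(x)
        y = standardize(y)

    m = n // L
    remainder = n - m * L
    if remainder:
        logger.info("segment_spectra: dropping %d remainder samples", remainder)

    xs = x[: m * L].reshape(m, L)
    ys = y[: m * L].reshape(m, L)

    tapers = _segment_tapers(L, taper)
    # scale so Sxx integrates to (windowed) variance: 1/(fs * sum(w^2))
    scales = 1.0 / (fs * (tapers**2).sum(axis=1))

    freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    sxx = np.zeros(freqs.size)
    syy = np.zeros(freqs.size)
    sxy = np.zeros(freqs.size, dtype=complex)
    for w, sc in zip(tapers, scales):
        fx = np.fft.rfft(xs * w[None, :], axis=1)
        fy = np.fft.rfft(ys * w[None, :], axis=1)
        sxx += sc * (np.abs(fx) ** 2).mean(axis=0)
        syy += sc * (np.abs(fy) ** 2).mean(axis=0)
        sxy += sc * (fx * np.conj(fy)).mean(axis=0)
    k = tapers.shape[0]
    sxx /= k
    syy /= k
    sxy /= k
    # one-sided doubling (except DC and Nyquist)
    dbl = np.full(freqs.size, 2.0)
    dbl[0] = 1.0
    if L % 2 == 0:
        dbl[-1] = 1.0
    return SpectrumEstimate(
        freqs=freqs, Sxx=sxx * dbl, Syy=syy * dbl, Sxy=sxy * dbl,
        M=m, L=L, remainder=remainder,
    )


def coherence_confidence_limit(M: int, alpha: float = 0.99) -> float:
    """Analytic coherence significance threshold 1 - (1-alpha)^(1/(M-1))."""
    if M < 2:
        raise ValueError(f"confidence limit needs M >= 2 segments, got {M}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return 1.0 - (1.0 - alpha) ** (1.0 / (M - 1))


def coherence(
    x: np.ndarray,
    y: np.ndarray,
    L: int,
    fs: float = 1.0,
    alpha: float = 0.99,
    taper: str = "hann",
) -> CoherenceResult:
    """Magnitude-squared coherence on segment-averaged spectra.

    Requires M >= 2 segments so the confidence limit is finite.
    """
    est = segment_spectra(x, y, L, fs=fs, taper=taper)
    if est.M < 2:
        raise ValueError(
            f"coherence needs at least 2 segments (got M={est.M}); "
            "shorten L or provide more data"
        )
    denom = est.Sxx * est.Syy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(est.Sxy) ** 2 / denom
    coh = np.where(denom > 0, coh, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    return CoherenceResult(
        freqs=est.freqs,
        coherence=coh,
        M=est.M,
        alpha=alpha,
        conf_limit=coherence_confidence_limit(est.M, alpha),
    )


# ---------------------------------------------------------------------------
# Morlet wavelet power
# ---------------------------------------------------------------------------

def _morlet(fs: float, freq: float, n_cycles: float,
            normalization: str) -> np.ndarray:
    """Complex Morlet wavelet at ``freq`` Hz.

    Gaussian envelope with sigma_t = n_cycles/(2*pi*freq), truncated at
    +/- 5 sigma.  ``normalization='energy'`` gives unit L2 norm;
    ``'amplitude'`` calibrates so |W|^2 of a sinusoid of amplitude a at
    the center frequency equals its mean power a^2/2.
    """
    sigma_t = n_cycles / (2.0 * math.pi * freq)
    half = int(math.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-(t**2) / (2.0 * sigma_t**2))
    w = env * np.exp(2j * math.pi * freq * t)
    if normalization == "energy":
        return w / np.sqrt((np.abs(w) ** 2).sum())
    if normalization == "amplitude":
        return w * (math.sqrt(2.0) / env.sum())
    raise ValueError(f"unknown normalization {normalization!r}")


def wavelet_power(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    n_cycles: float = 3.0,
    power_exponent: int = 1,
    normalization: str = "energy",
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged Morlet-wavelet magnitude per center frequency.

    Default grid is 1..100 Hz in 1 Hz steps.  ``power_exponent=1``
    averages the plain magnitude of the transform; ``2`` averages the
    squared magnitude.  Edge samples within one wavelet half-length of
    either end are excluded from the time average.

    Returns ``(freqs, power)``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("wavelet_power expects a 1-D series")
    if freqs is None:
        freqs = np.arange(1.0, 101.0)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("wavelet center frequencies must be positive")
    if power_exponent not in (1, 2):
        raise ValueError("power_exponent must be 1 or 2")

    longest = _morlet(fs, freqs.min(), n_cycles, normalization).size
    if x.size <= longest:
        raise ValueError(
            f"series of {x.size} samples is shorter than the longest wavelet; "
            f"need more than {longest} samples for a minimum frequency of "
            f"{freqs.min():g} Hz"
        )

    out = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        w = _morlet(fs, f, n_cycles, normalization)
        half = w.size // 2
        conv = sps.fftconvolve(x.astype(complex), w, mode="same")
        valid = np.abs(conv[half : x.size - half])
        out[i] = (valid**power_exponent).mean()
    return freqs, out


def band_summary(
    freqs: np.ndarray, values: np.ndarray, band: tuple[float, float]
) -> BandSummary:
    """Mean over in-band bins (inclusive edges) plus the argmax peak."""
    freqs = np.asarray(freqs, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"band low must be below high, got {band}")
    if lo < freqs.min() - 1e-9 or hi > freqs.max() + 1e-9:
        raise ValueError(f"band {band} outside spectrum range "
                         f"[{freqs.min():g}, {freqs.max():g}]")
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no frequency bins")
    fb = freqs[mask]
    vb = values[mask]
    ipk = int(np.argmax(vb))
    return BandSummary(
        band=(float(lo), float(hi)),
        mean_value=float(vb.mean()),
        peak_freq=float(fb[ipk]),
        peak_value=float(vb[ipk]),
    )


def band_power(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    nperseg: int | None = None,
    taper: str = "boxcar",
) -> float:
    """Total power of ``x`` inside ``band`` (Hz), by integrating the
    one-sided segment-averaged PSD over the band.

    A pure in-band sinusoid of amplitude a returns ~a^2/2; out-of-band
    content contributes only leakage.  The series is mean-centered but
    not variance-normalized (this is a power, not a shape, measure).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("band_power expects a 1-D series of length >= 4")
    lo, hi = band
    if not 0 <= lo < hi:
        raise ValueError(f"invalid band {band}")
    if hi > fs / 2:
        raise ValueError(f"band {band} exceeds the Nyquist frequency {fs / 2:g}")
    if nperseg is None:
        nperseg = x.size
    xc = x - x.mean()
    est = segment_spectra(xc, xc, nperseg, fs=fs, taper=taper,
                          pre_standardize=False)
    df = est.freqs[1] - est.freqs[0]
    mask = (est.freqs >= lo) & (est.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} resolves to no bins at df={df:g} Hz")
    return float(est.Sxx[mask].sum() * df)
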