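"""Synthetic signal generators with known ground truth.

Every generator is seed-deterministic and parameterized by a small spec
dataclass whose invariants are checked eagerly.  The generators provide:

* paired-region oscillation signals with prescribed theta/gamma content,
  tunable inter-region coherence, and theta-phase -> gamma-amplitude
  coupling of known depth,
* multichannel EEG switching between a few quasi-stable topographies,
  with the true state sequence returned for recovery tests,
* stimulus-locked epochs with a known injected response,
* two-group score samples, optionally moment-matched exactly.

Ground truth is constructed analytically (e.g. the theta phase used for
the coupling envelope is the exact generating phase), so estimators can
be validated against closed forms without circularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .recording import EpochSet, Recording

__all__ = [
    "CouplingSpec",
    "MicrostateSpec",
    "GroupSpec",
    "ResponseSpec",
    "gen_coupled_pair",
    "gen_microstate_eeg",
    "gen_group_scores",
    "gen_evoked_epochs",
    "random_topographies",
    "write_labels",
    "read_labels",
    "write_group_scores",
]


class SpecError(ValueError):
    """A generator spec violates one of its invariants."""


# ---------------------------------------------------------------------------
# coupled oscillation pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingSpec:
    """Parameters for a theta/gamma coupled region pair.

    ``coupling_depth`` d sets the gamma envelope to
    ``gamma_amp * (1 + d*cos(phase_theta))``; ``coherence_mix`` w is the
    fraction of the theta-band source shared between the two regions.
    """

    theta_freq: float = 10.0
    gamma_freq: float = 70.0
    theta_amp: float = 1.0
    gamma_amp: float = 0.5
    coupling_depth: float = 0.5
    coherence_mix: float = 0.5
    noise_sd: float = 0.1
    fs: float = 1000.0
    duration: float = 60.0
    seed: int = 0
    #: optional shared fraction for an additional gamma-band background
    #: source present in both regions (None = no gamma background); lets
    #: studies plant inter-region gamma coherence independently of w.
    gamma_coherence_mix: float | None = None
    gamma_bg_amp: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_depth <= 1.0:
            raise SpecError(
                f"coupling_depth must lie in [0, 1], got {self.coupling_depth}"
            )
        if not 0.0 <= self.coherence_mix <= 1.0:
            raise SpecError(
                f"coherence_mix must lie in [0, 1], got {self.coherence_mix}"
            )
        if not self.fs > 2.0 * self.gamma_freq:
            raise SpecError(
                f"fs must exceed 2*gamma_freq ({2 * self.gamma_freq} Hz), got {self.fs}"
            )
        if self.theta_freq <= 0 or self.gamma_freq <= self.theta_freq:
            raise SpecError("need 0 < theta_freq < gamma_freq")
        if self.noise_sd < 0:
            raise SpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.gamma_coherence_mix is not None and not (
            0.0 <= self.gamma_coherence_mix <= 1.0
        ):
            raise SpecError(
                f"gamma_coherence_mix must lie in [0, 1], got "
                f"{self.gamma_coherence_mix}"
            )
        n = self.duration * self.fs
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise SpecError(
                f"duration*fs must be a positive integer, got {n}"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                      center: float, rel_bw: float = 0.25) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited around ``center`` Hz."""
    lo = max(center * (1 - rel_bw), 0.1)
    hi = min(center * (1 + rel_bw), 0.49 * fs)
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    # match the power of a unit cosine (variance 1/2) so mixing weights
    # trade shared against independent content without changing band power
    return x / (sd * math.sqrt(2.0)) if sd > 0 else x


def gen_coupled_pair(spec: CouplingSpec) -> tuple[Recording, Recording]:
    """Generate a (region_A, region_B) pair with known coupling structure.

    Region A carries the theta oscillation; region B carries gamma whose
    instantaneous amplitude follows ``gamma_amp*(1 + d*cos(theta_phase))``
    plus its own theta-band component.  The theta-band component of each
    region mixes a shared deterministic source (weight ``sqrt(w)``) with
    independent narrowband noise (weight ``sqrt(1-w)``), which makes the
    inter-region coherence at ``theta_freq`` monotone in w.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    phase_theta = 2.0 * math.pi * spec.theta_freq * t

    shared = np.cos(phase_theta)
    w_sh = math.sqrt(spec.coherence_mix)
    w_ind = math.sqrt(1.0 - spec.coherence_mix)

    theta_a = spec.theta_amp * (
        w_sh * shared
        + w_ind * _narrowband_noise(rng, n, spec.fs, spec.theta_freq)
    )
    theta_b = spec.theta_amp * (
        w_sh * shared
        + w_ind * _narrowband_noise(rng, n, spec.fs, spec.theta_freq)
    )

    envelope = spec.gamma_amp * (1.0 + spec.coupling_depth * np.cos(phase_theta))
    gamma_b = envelope * np.cos(2.0 * math.pi * spec.gamma_freq * t)

    a = theta_a + spec.noise_sd * rng.standard_normal(n)
    b = theta_b + gamma_b + spec.noise_sd * rng.standard_normal(n)

    if spec.gamma_coherence_mix is not None:
        wg_sh = math.sqrt(spec.gamma_coherence_mix)
        wg_ind = math.sqrt(1.0 - spec.gamma_coherence_mix)
        shared_g = _narrowband_noise(rng, n, spec.fs, spec.gamma_freq)
        a = a + spec.gamma_bg_amp * (
            wg_sh * shared_g
            + wg_ind * _narrowband_noise(rng, n, spec.fs, spec.gamma_freq)
        )
        b = b + spec.gamma_bg_amp * (
            wg_sh * shared_g
            + wg_ind * _narrowband_noise(rng, n, spec.fs, spec.gamma_freq)
        )

    rec_a = Recording(a[None, :], spec.fs, ["region_A"], units="a.u.")
    rec_b = Recording(b[None, :], spec.fs, ["region_B"], units="a.u.")
    return rec_a, rec_b


# ---------------------------------------------------------------------------
# microstate-style EEG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrostateSpec:
    """Parameters for quasi-stable topography switching EEG.

    Topographies are re-centered (zero mean across channels) and
    unit-normalized on construction; dwell times are geometric with mean
    ``mean_dwell`` ms (memoryless switching).  ``snr`` is the ratio of
    the typical signal-vector norm to the noise-vector norm; ``inf`` is
    allowed and produces noiseless data.
    """

    n_channels: int
    topographies: np.ndarray  # (k, n_channels)
    mean_dwell: float = 100.0  # ms
    fs: float = 250.0
    duration: float = 20.0
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        topo = np.atleast_2d(np.asarray(self.topographies, dtype=float))
        if topo.shape[1] != self.n_channels:
            raise SpecError(
                f"topographies have {topo.shape[1]} channels, spec says {self.n_channels}"
            )
        if topo.shape[0] < 1:
            raise SpecError("need at least one topography")
        topo = topo - topo.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(topo, axis=1)
        if np.any(norms < 1e-12):
            raise SpecError("topography degenerate (zero after mean removal)")
        topo = topo / norms[:, None]
        # pairwise collinearity check on the normalized maps
        k = topo.shape[0]
        for i in range(k):
            for j in range(i + 1, k):
                if abs(float(topo[i] @ topo[j])) > 0.999:
                    raise SpecError(f"topographies {i} and {j} are collinear")
        object.__setattr__(self, "topographies", topo)
        if not self.mean_dwell > 0:
            raise SpecError(f"mean_dwell must be > 0, got {self.mean_dwell}")
        if not (self.snr > 0):
            raise SpecError(f"snr must be > 0, got {self.snr}")
        if self.fs <= 0 or self.duration <= 0:
            raise SpecError("fs and duration must be positive")

    @property
    def k(self) -> int:
        return self.topographies.shape[0]

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def random_topographies(n_channels: int, k: int, seed: int = 0) -> np.ndarray:
    """k mutually orthogonal zero-mean unit-norm channel maps."""
    if k > n_channels - 1:
        raise SpecError(
            f"cannot fit {k} orthogonal zero-mean maps in {n_channels} channels"
        )
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n_channels, k + 1))
    raw[:, 0] = 1.0  # force the mean direction into the basis, then drop it
    q, _ = np.linalg.qr(raw)
    topo = q[:, 1 : k + 1].T
    return topo / np.linalg.norm(topo, axis=1)[:, None]


def gen_microstate_eeg(spec: MicrostateSpec) -> tuple[Recording, np.ndarray]:
    """Generate switching-topography EEG and its true label sequence.

    Each dwell run takes a random polarity; within a run the per-sample
    amplitude is uniform in [0.75, 1.25] so the signal never vanishes.
    Channel noise is white Gaussian with SD ``1/(snr*sqrt(n_channels))``,
    i.e. the expected noise-vector norm is ``1/snr`` relative to the
    unit-norm topography scale.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    k = spec.k

    mean_samples = max(spec.mean_dwell / 1000.0 * spec.fs, 1.0)
    p_switch = 1.0 / mean_samples

    labels = np.empty(n, dtype=int)
    data = np.zeros((spec.n_channels, n))
    pos = 0
    state = int(rng.integers(k))
    while pos < n:
        run = int(rng.geometric(p_switch))
        run = min(run, n - pos)
        sign = -1.0 if rng.random() < 0.5 else 1.0
        amps = sign * rng.uniform(0.75, 1.25, size=run)
        labels[pos : pos + run] = state
        data[:, pos : pos + run] = spec.topographies[state][:, None] * amps[None, :]
        pos += run
        if k > 1:
            nxt = int(rng.integers(k - 1))
            state = nxt if nxt < state else nxt + 1
        # k == 1: stay

    if np.isfinite(spec.snr):
        noise_sd = 1.0 / (spec.snr * math.sqrt(spec.n_channels))
        data = data + noise_sd * rng.standard_normal(data.shape)

    rec = Recording(data, spec.fs, units="a.u.")
    return rec, labels


# ---------------------------------------------------------------------------
# two-group scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Two-group Gaussian score samples, optionally exactly moment-matched."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    moment_match: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sd1 > 0 and self.sd2 > 0):
            raise SpecError("sd1 and sd2 must be > 0")
        if self.n1 < 2 or self.n2 < 2:
            raise SpecError("group sizes must be >= 2")


def _match_moments(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    s = x.std(ddof=1)
    if s == 0:
        raise SpecError("cannot moment-match a zero-variance sample")
    return mean + sd * (x - x.mean()) / s


def gen_group_scores(spec: GroupSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two score samples.

    With ``moment_match`` the samples are affinely rescaled so the sample
    mean and sample SD (ddof=1, the convention of printed "mean +/- SD"
    tables) equal the requested values exactly.
    """
    rng = np.random.default_rng(spec.seed)
    g1 = spec.mean1 + spec.sd1 * rng.standard_normal(spec.n1)
    g2 = spec.mean2 + spec.sd2 * rng.standard_normal(spec.n2)
    if spec.moment_match:
        g1 = _match_moments(g1, spec.mean1, spec.sd1)
        g2 = _match_moments(g2, spec.mean2, spec.sd2)
    return g1, g2


# ---------------------------------------------------------------------------
# evoked epochs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseSpec:
    """Injected post-stimulus response: a decaying oscillation.

    For t > 0 the response on channel c is
    ``amplitude * weights[c] * exp(-t/decay) * sin(2*pi*freq*t)``.
    """

    amplitude: float = 1.0
    freq: float = 8.0
    decay: float = 0.3  # s
    noise_sd: float = 0.0
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.decay <= 0 or self.freq <= 0:
            raise SpecError("freq and decay must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")


def gen_evoked_epochs(
    n_epochs: int,
    pre: float,
    post: float,
    fs: float,
    response_spec: ResponseSpec,
    seed: int = 0,
    n_channels: int = 16,
    analysis_window: tuple[float, float] | None = (-0.25, 2.0),
) -> EpochSet:
    """Epochs around a stimulus at t=0 with a known injected response.

    ``analysis_window`` guards the epoch span: generation fails if the
    epoch cannot cover it (pass ``None`` to disable the check).
    """
    if n_epochs < 1:
        raise SpecError("need at least one epoch")
    if pre < 0 or post <= 0:
        raise SpecError("need pre >= 0 and post > 0")
    if analysis_window is not None:
        lo, hi = analysis_window
        if -pre > lo + 1e-12 or post < hi - 1e-12:
            raise SpecError(
                f"epoch span [-{pre}, {post}] s cannot cover the analysis "
                f"window [{lo}, {hi}] s"
            )
    rng = np.random.default_rng(seed)
    # ceil so the epoch covers at least [-pre, post] despite fs rounding
    n_pre = int(math.ceil(pre * fs - 1e-9))
    n_post = int(math.ceil(post * fs - 1e-9))
    times = np.arange(-n_pre, n_post + 1) / fs

    weights = response_spec.weights
    if weights is None:
        weights = np.ones(n_channels)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n_channels,):
        raise SpecError(f"weights must have shape ({n_channels},)")

    resp_t = np.where(
        times > 0,
        response_spec.amplitude
        * np.exp(-np.clip(times, 0, None) / response_spec.decay)
        * np.sin(2.0 * math.pi * response_spec.freq * times),
        0.0,
    )
    base = weights[:, None] * resp_t[None, :]
    data = np.broadcast_to(base, (n_epochs, n_channels, times.size)).copy()
    if response_spec.noise_sd > 0:
        data += response_spec.noise_sd * rng.standard_normal(data.shape)
    labels = [f"ch{i:02d}" for i in range(n_channels)]
    return EpochSet(data=data, times=times, fs=fs, channel_labels=labels)


# ---------------------------------------------------------------------------
# text I/O for ground truth
# ---------------------------------------------------------------------------

def write_labels(labels: np.ndarray, path: str | Path) -> None:
    np.savetxt(Path(path), np.asarray(labels, dtype=int), fmt="%d")


def read_labels(path: str | Path) -> np.ndarray:
    return np.loadtxt(Path(path), dtype=int, ndmin=1)


def write_group_scores(
    g1: np.ndarray, g2: np.ndarray, path: str | Path,
    names: tuple[str, str] = ("group1", "group2"),
) -> None:
    """Two-column CSV (group, value)."""
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["group", "value"])
        for v in np.asarray(g1, dtype=float):
            wr.writerow([names[0], repr(float(v))])
        for v in np.asarray(g2, dtype=float):
            wr.writerow([names[1], repr(float(v))])
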