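"""Stimulus-locked global mean field power (GMFP) over an electrode
subset, and baseline-normalized band-power condition ratios.

GMFP at each time point is the root-mean-square deviation of the evoked
potential from the subset mean (the Lehmann-Skrandies field-power form):

    GMFP(t) = sqrt( (1/K) * sum_k (v_k(t) - vbar(t))^2 )

computed on the across-epoch average restricted to the electrode subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import spectral
from .recording import EpochSet

__all__ = [
    "GMFPTrace",
    "BandRatio",
    "default_frontal_subset",
    "gmfp",
    "band_power",
    "condition_ratio",
]


@dataclass
class GMFPTrace:
    time: np.ndarray            # s relative to the stimulus
    values: np.ndarray          # field power, >= 0
    electrode_subset: list[str]
    window: tuple[float, float] = (-0.25, 2.0)


@dataclass
class BandRatio:
    numerator_condition: str
    denominator_condition: str
    band: tuple[float, float]
    ratio: float


def default_frontal_subset() -> list[str]:
    """The default 16-label frontal electrode list (10-10 names).

    Shipped as package data; this is configuration, not a claim about
    any particular montage.
    """
    raw = json.loads(
        resources.files("oscana.data").joinpath("frontal_subset.json").read_text()
    )
    return list(raw["electrodes"])


def gmfp(
    epochs: EpochSet,
    electrode_subset: list[str] | None = None,
    window: tuple[float, float] = (-0.25, 2.0),
) -> GMFPTrace:
    """GMFP of the evoked (epoch-average) response on an electrode subset,
    restricted to ``window`` seconds around the stimulus (inclusive)."""
    if electrode_subset is None:
        electrode_subset = list(epochs.channel_labels)
    missing = [e for e in electrode_subset if e not in epochs.channel_labels]
    if missing:
        raise ValueError(f"electrodes missing from the epochs: {missing}")
    lo, hi = window
    if lo < epochs.times[0] - 1e-9 or hi > epochs.times[-1] + 1e-9:
        raise ValueError(
            f"window {window} outside epoch span "
            f"[{epochs.times[0]:g}, {epochs.times[-1]:g}] s"
        )
    idx = [epochs.channel_labels.index(e) for e in electrode_subset]
    evoked = epochs.average()[idx]
    tmask = (epochs.times >= lo - 1e-12) & (epochs.times <= hi + 1e-12)
    sub = evoked[:, tmask]
    centered = sub - sub.mean(axis=0, keepdims=True)
    values = np.sqrt((centered**2).mean(axis=0))
    return GMFPTrace(
        time=epochs.times[tmask].copy(),
        values=values,
        electrode_subset=list(electrode_subset),
        window=(float(lo), float(hi)),
    )


def band_power(
    series: np.ndarray,
    fs: float,
    band: tuple[float, float],
    interval: tuple[float, float] | None = None,
    times: np.ndarray | None = None,
) -> float:
    """Mean band power of a series over a time interval.

    ``interval`` (s) requires a matching ``times`` axis; the series is
    cropped before the spectral estimate.  Delegates the estimate to
    :func:`oscana.spectral.band_power` (integrated one-sided PSD), so a
    pure in-band sinusoid of amplitude a yields ~a^2/2.
    """
    series = np.asarray(series, dtype=float)
    if interval is not None:
        if times is None:
            raise ValueError("interval cropping needs a times axis")
        times = np.asarray(times, dtype=float)
        if times.shape != series.shape:
            raise ValueError("times must match the series shape")
        lo, hi = interval
        if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
            raise ValueError(f"interval {interval} outside the data span")
        mask = (times >= lo - 1e-12) & (times <= hi + 1e-12)
        series = series[mask]
    return spectral.band_power(series, fs, band)


def condition_ratio(
    cond_power: float,
    baseline_power: float,
    other_cond_power: float,
    other_baseline_power: float,
    band: tuple[float, float] = (0.0, 0.0),
    conditions: tuple[str, str] = ("cond", "other"),
) -> BandRatio:
    """Baseline-normalized contrast (cond/baseline) / (other/other_baseline)."""
    powers = (cond_power, baseline_power, other_cond_power, other_baseline_power)
    if any(not p > 0 for p in powers):
        raise ValueError(f"all powers must be positive, got {powers}")
    ratio = (cond_power / baseline_power) / (other_cond_power / other_baseline_power)
    return BandRatio(
        numerator_condition=conditions[0],
        denominator_condition=conditions[1],
        band=tuple(band),
        ratio=float(ratio),
    )
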