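"""Resting-state EEG microstate pipeline.

Global field power (GFP), GFP-peak picking, polarity-invariant modified
k-means clustering of peak topographies into k=4 prototype classes,
back-fitting of prototypes to the full record, and per-class duration /
occurrence / coverage statistics.

All spatial operations are polarity-invariant (a map and its negation
belong to the same class) and presuppose the average reference, which is
applied internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .recording import Recording

__all__ = [
    "MicrostateModel",
    "MicrostateStats",
    "average_reference",
    "gfp",
    "find_gfp_peaks",
    "cluster_topographies",
    "assign_canonical_labels",
    "backfit",
    "microstate_stats",
    "segment",
]

CLASS_NAMES = ("A", "B", "C", "D")


@dataclass
class MicrostateModel:
    """Fitted prototypes plus the back-fitted labeling of the record."""

    prototypes: np.ndarray  # (k, n_channels), unit norm, zero mean
    labels: np.ndarray      # per-sample class indices
    gev: float              # global explained variance in [0, 1]
    class_names: list[str] = field(default_factory=lambda: list(CLASS_NAMES))
    gev_trajectory: np.ndarray | None = None


@dataclass
class MicrostateStats:
    """Per-class temporal statistics.

    duration: mean run length in ms (nan for classes that never occur);
    occurrence: runs per second; coverage: fraction of samples.
    """

    duration_ms: dict[str, float]
    occurrence_per_s: dict[str, float]
    coverage: dict[str, float]


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean at every sample."""
    data = np.asarray(data, dtype=float)
    return data - data.mean(axis=0, keepdims=True)


def gfp(eeg: Recording) -> np.ndarray:
    """Global field power: per-sample SD across channels (average
    reference applied first, so this is the RMS of the referenced map)."""
    if eeg.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    ref = average_reference(eeg.data)
    return np.sqrt((ref**2).mean(axis=0))


def find_gfp_peaks(gfp_series: np.ndarray, min_separation: int = 0) -> np.ndarray:
    """Strict local maxima of the GFP series, greedily thinned so that no
    two kept peaks are closer than ``min_separation`` samples (highest
    peaks kept first).  Returns ascending sample indices (may be empty).
    """
    g = np.asarray(gfp_series, dtype=float)
    if g.size < 3:
        raise ValueError("peak picking needs a series of length >= 3")
    cand = np.flatnonzero((g[1:-1] > g[:-2]) & (g[1:-1] > g[2:])) + 1
    if cand.size == 0 or min_separation <= 1:
        return cand
    order = cand[np.argsort(g[cand])[::-1]]
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - k) >= min_separation for k in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=int)


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def _gev(maps: np.ndarray, prototypes: np.ndarray, labels: np.ndarray) -> float:
    """Global explained variance of ``maps`` under a sign-invariant
    assignment: sum of squared projections over total squared norm."""
    proj = np.einsum("nc,nc->n", maps, prototypes[labels])
    total = (maps**2).sum()
    return float((proj**2).sum() / total) if total > 0 else 0.0


def cluster_topographies(
    peak_maps: np.ndarray,
    k: int = 4,
    n_restarts: int = 100,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Polarity-invariant modified k-means on GFP-peak topographies.

    Assigns each map to the prototype with maximal absolute dot product
    and updates each prototype to the dominant eigenvector of its
    cluster's scatter matrix, which maximizes explained variance under
    sign invariance.  Best of ``n_restarts`` by global explained
    variance (GEV); convergence when GEV improves by less than ``tol``.

    Returns ``(prototypes, gev_trajectory)`` where the trajectory is the
    per-iteration GEV of the winning restart (non-decreasing).
    """
    maps = np.atleast_2d(np.asarray(peak_maps, dtype=float))
    n_maps, n_ch = maps.shape
    if n_maps < k:
        raise ValueError(f"need at least k={k} maps, got {n_maps}")
    maps = average_reference(maps.T).T  # zero-mean each map across channels
    rng = np.random.default_rng(seed)

    best_protos = None
    best_traj: list[float] = []
    best_gev = -np.inf
    for _ in range(max(n_restarts, 1)):
        protos = _normalize_maps(maps[rng.choice(n_maps, k, replace=False)].copy())
        traj: list[float] = []
        prev = -np.inf
        for _it in range(max_iter):
            corr = maps @ protos.T
            labels = np.argmax(np.abs(corr), axis=1)
            for j in range(k):
                sel = maps[labels == j]
                if sel.shape[0] == 0:
                    # re-seed empty cluster with the worst-explained map
                    resid = (maps**2).sum(axis=1) - np.take_along_axis(
                        corr**2, labels[:, None], axis=1
                    )[:, 0]
                    protos[j] = _normalize_maps(
                        maps[int(np.argmax(resid))][None, :]
                    )[0]
                    continue
                scatter = sel.T @ sel
                _, vecs = np.linalg.eigh(scatter)
                protos[j] = vecs[:, -1]
            protos = _normalize_maps(protos)
            corr = maps @ protos.T
            labels = np.argmax(np.abs(corr), axis=1)
            cur = _gev(maps, protos, labels)
            traj.append(cur)
            if cur - prev < tol:
                break
            prev = cur
        if traj and traj[-1] > best_gev:
            best_gev = traj[-1]
            best_protos = protos.copy()
            best_traj = traj
    assert best_protos is not None
    return best_protos, np.asarray(best_traj)


def _load_templates() -> tuple[list[str], np.ndarray, list[str]]:
    raw = json.loads(
        resources.files("oscana.data").joinpath("templates_1020.json").read_text()
    )
    names = list(raw["class_names"])
    chans = list(raw["channel_labels"])
    maps = _normalize_maps(np.asarray(raw["maps"], dtype=float))
    return names, maps, chans


def assign_canonical_labels(
    prototypes: np.ndarray,
    channel_labels: list[str] | None = None,
) -> list[str]:
    """Label prototypes A-D by absolute spatial correlation with the
    canonical template maps shipped as package data (19-channel 10-20
    montage).  The templates are idealized configuration data, not a
    claim about any particular study's montage.

    If ``channel_labels`` do not cover the template montage the
    prototypes cannot be matched and a ``ValueError`` is raised; callers
    may then fall back to positional names (``segment`` does this).
    """
    from scipy.optimize import linear_sum_assignment

    names, tmpl, tmpl_chans = _load_templates()
    prototypes = np.atleast_2d(np.asarray(prototypes, dtype=float))
    if channel_labels is None or set(tmpl_chans) - set(channel_labels):
        raise ValueError(
            "canonical labeling needs the 10-20 template channels "
            f"{tmpl_chans}; pass matching channel_labels or use positional "
            "class names"
        )
    idx = [channel_labels.index(c) for c in tmpl_chans]
    sub = _normalize_maps(prototypes[:, idx])
    cost = -np.abs(sub @ tmpl.T)
    rows, cols = linear_sum_assignment(cost)
    out = [""] * prototypes.shape[0]
    for r, c in zip(rows, cols):
        out[r] = names[c]
    return out


def backfit(
    eeg: Recording,
    prototypes: np.ndarray,
    smooth_window: int = 0,
) -> np.ndarray:
    """Label every sample by maximal absolute spatial correlation with a
    prototype.  ``smooth_window`` > 1 applies a majority filter of that
    width (off by default)."""
    prototypes = np.atleast_2d(np.asarray(prototypes, dtype=float))
    if prototypes.shape[1] != eeg.n_channels:
        raise ValueError(
            f"prototypes have {prototypes.shape[1]} channels, "
            f"recording has {eeg.n_channels}"
        )
    ref = average_reference(eeg.data)
    corr = np.abs(prototypes @ ref)  # (k, n_samples); norms don't affect argmax
    labels = np.argmax(corr, axis=0)
    if smooth_window > 1:
        k = prototypes.shape[0]
        half = smooth_window // 2
        onehot = np.zeros((k, labels.size))
        onehot[labels, np.arange(labels.size)] = 1.0
        kernel = np.ones(2 * half + 1)
        votes = np.stack([np.convolve(onehot[j], kernel, mode="same")
                          for j in range(k)])
        labels = np.argmax(votes, axis=0)
    return labels


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (values, lengths)."""
    labels = np.asarray(labels)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return labels[starts], ends - starts


def microstate_stats(
    labels: np.ndarray,
    fs: float,
    class_names: list[str] | None = None,
) -> MicrostateStats:
    """Mean run duration (ms), occurrence (runs/s) and coverage per class."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    classes = np.unique(labels)
    if class_names is None:
        class_names = [str(c) for c in classes]
        lookup = {c: str(c) for c in classes}
    else:
        lookup = {i: nm for i, nm in enumerate(class_names)}
    vals, lens = _runs(labels)
    total_s = labels.size / fs
    duration, occurrence, coverage = {}, {}, {}
    for cls, name in lookup.items():
        sel = vals == cls
        n_runs = int(sel.sum())
        n_samp = int(lens[sel].sum())
        duration[name] = (
            float(lens[sel].mean() * 1000.0 / fs) if n_runs else float("nan")
        )
        occurrence[name] = n_runs / total_s
        coverage[name] = n_samp / labels.size
    return MicrostateStats(duration, occurrence, coverage)


def segment(
    eeg: Recording,
    k: int = 4,
    n_restarts: int = 100,
    seed: int | None = None,
    min_peak_separation: int = 0,
    smooth_window: int = 0,
    label_by_templates: bool = False,
) -> tuple[MicrostateModel, MicrostateStats]:
    """Full pipeline: GFP -> peaks -> clustering -> back-fitting -> stats."""
    g = gfp(eeg)
    peaks = find_gfp_peaks(g, min_peak_separation)
    if peaks.size < k:
        raise ValueError(f"only {peaks.size} GFP peaks found; need >= k={k}")
    maps = average_reference(eeg.data)[:, peaks].T
    protos, traj = cluster_topographies(maps, k=k, n_restarts=n_restarts, seed=seed)
    if label_by_templates:
        names = assign_canonical_labels(protos, eeg.channel_labels)
    else:
        names = [CLASS_NAMES[i] if i < len(CLASS_NAMES) else f"C{i}"
                 for i in range(k)]
    labels = backfit(eeg, protos, smooth_window=smooth_window)
    ref = average_reference(eeg.data)
    model = MicrostateModel(
        prototypes=protos,
        labels=labels,
        gev=_gev(ref.T, protos, labels),
        class_names=names,
        gev_trajectory=traj,
    )
    stats = microstate_stats(labels, eeg.fs, class_names=names)
    return model, stats
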