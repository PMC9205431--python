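"""Excitation/inhibition balance statistics and critical-temperature
extraction.

A signed coupling matrix assigns each connection an excitatory (+) or
inhibitory (-) role. The E/I ratio of a region is the ratio of positive to
negative couplings on its row — either as a count of edges (the default,
matching the worked convention "45 positive and 34 negative edges give
45/34 = 1.32") or as a ratio of summed weights. A ratio of 1 indicates
perfect balance; values above 1 a shift toward excitation.

Group comparisons quantify a balance shift between two cohorts via
``delta = 1 - ratio_A / ratio_B`` per region (positive when group B is
more excitatory), the cross-group R^2, and a two-sided paired t test
across regions.

The critical temperature of a network is the temperature at the peak of
the susceptibility curve from a Monte Carlo temperature scan — the point
of maximal magnetization fluctuations, interpreted as the system's
tolerance to injected randomness before order is lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FlatCurveError, NoInhibitionError, ShapeError
from .ising_sim import ThermoCurve
from .pmem_inference import _coerce_J

__all__ = [
    "EiResult",
    "GroupComparison",
    "ei_ratio",
    "group_delta",
    "critical_temperature",
]


@dataclass
class EiResult:
    """Per-region and global excitation/inhibition ratios."""

    per_region: np.ndarray
    global_ratio: float
    mode: str  # count | weight
    region_labels: list[str] = field(default_factory=list)


@dataclass
class GroupComparison:
    """Region-wise comparison of mean E/I ratios between two groups."""

    mean_a: np.ndarray
    mean_b: np.ndarray
    delta_per_roi: np.ndarray
    mean_delta: float
    r_squared: float
    paired_t: float
    paired_t_p: float


def _ratio(pos: np.ndarray, neg: np.ndarray, mode: str, what: str, on_empty: str) -> float:
    if mode == "count":
        num, den = float(pos.size), float(neg.size)
    elif mode == "weight":
        num, den = float(pos.sum()), float(-neg.sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if den == 0:
        if on_empty == "nan":
            return float("nan")
        raise NoInhibitionError(f"{what}: no negative edges, E/I ratio undefined")
    return num / den


def ei_ratio(J, mode: str = "count", on_empty: str = "raise") -> EiResult:
    """E/I ratio per region (its off-diagonal row) and globally (each edge
    counted once via the upper triangle). Exact zeros are excluded from both
    numerator and denominator.

    A region without negative edges has no defined ratio: by default that
    raises :class:`NoInhibitionError`; ``on_empty="nan"`` records NaN
    instead, for cohort aggregation where such regions are treated as
    missing for that subject.
    """
    Jm = _coerce_J(J)
    labels = list(J.region_labels) if hasattr(J, "region_labels") else []
    N = Jm.shape[0]
    per = np.empty(N)
    for i in range(N):
        row = np.delete(Jm[i], i)
        per[i] = _ratio(row[row > 0], row[row < 0], mode, f"region {i}", on_empty)
    iu = np.triu_indices(N, k=1)
    edges = Jm[iu]
    glob = _ratio(edges[edges > 0], edges[edges < 0], mode, "global", on_empty)
    return EiResult(per, glob, mode, labels)


def cohort_ei_means(couplings, mode: str = "count") -> np.ndarray:
    """Group-mean E/I ratio per region: subject-level ratios averaged across
    subjects (not edge-pooled), regions with an undefined subject ratio
    treated as missing for that subject."""
    ratios = np.array([ei_ratio(J, mode, on_empty="nan").per_region for J in couplings])
    return np.nanmean(ratios, axis=0)


def group_delta(ratios_a: np.ndarray, ratios_b: np.ndarray) -> GroupComparison:
    """Compare per-region mean E/I ratios of two matched groups.

    ``delta = 1 - ratio_A / ratio_B`` per region; also reports the mean
    delta, the squared Pearson correlation of the cross-group scatter, and
    a two-sided paired t test across regions (no multiplicity correction).
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError(f"ratio vectors must be 1-D and matched, got {a.shape} vs {b.shape}")
    delta = 1.0 - a / b
    if a.std() == 0 or b.std() == 0:
        r2 = 1.0 if np.array_equal(a, b) else 0.0
    else:
        r2 = float(stats.pearsonr(a, b)[0] ** 2)
    if np.array_equal(a, b):
        t_stat, p = 0.0, 1.0  # ttest_rel is 0/0 for identical samples
    else:
        t_stat, p = stats.ttest_rel(a, b)
    return GroupComparison(a, b, delta, float(delta.mean()), r2, float(t_stat), float(p))


def critical_temperature(curve: ThermoCurve) -> float:
    """Temperature ``T = 1/beta`` at the global susceptibility maximum.

    Exact ties are broken toward the higher temperature. A constant curve
    raises :class:`FlatCurveError`.
    """
    if curve.betas.size < 3:
        raise ShapeError("need at least 3 beta points")
    chi = curve.chi
    if np.ptp(chi) == 0:
        raise FlatCurveError("susceptibility curve is constant")
    peak = chi.max()
    candidates = np.flatnonzero(chi == peak)
    beta_star = curve.betas[candidates].min()  # smallest beta = highest T
    return float(1.0 / beta_star)
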