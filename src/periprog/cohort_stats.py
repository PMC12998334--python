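"""Cohort-level hypothesis tests and the migration-distance ratio.

Thin, pinned-convention wrappers around the classical nonparametric tests
used throughout the organoid cohort analyses: Fisher's exact test on 2x2
engraftment tables, the Mann-Whitney U test with an explicit exact/approximate
dispatch rule, Kruskal-Wallis with Holm-adjusted pairwise post hocs, BH/Holm
p-value adjustment, and the ratio of late- to early-window migration distance
from time-lapse organoid tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FisherResult",
    "MannWhitneyResult",
    "KruskalHolmResult",
    "MigrationTrack",
    "fisher_exact_2x2",
    "mann_whitney",
    "kruskal_wallis_holm",
    "adjust_pvalues",
    "migration_ratio",
]


@dataclass(frozen=True)
class FisherResult:
    p: float
    odds_ratio: float


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" | "asymptotic"


@dataclass(frozen=True)
class KruskalHolmResult:
    h: float
    p: float
    pairwise: pd.DataFrame = field(repr=False)


@dataclass
class MigrationTrack:
    """Centroid track of one organoid sampled every ~2 h over ~96 h."""

    organoid_id: str
    condition: str
    t: np.ndarray  # hours
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher's exact test on a 2x2 table (rows = groups).

    The two-sided p-value follows the probability-mass criterion: the sum of
    hypergeometric probabilities of all tables with the observed margins whose
    probability does not exceed that of the observed table. The odds ratio is
    the sample odds ratio a*d / (b*c), reported as inf when b*c == 0 and the
    numerator is positive.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("table entries must be nonnegative")
    if t.sum() == 0:
        raise ValueError("table grand total is zero")
    res = _st.fisher_exact(t, alternative="two-sided")
    a, b = t[0]
    c, d = t[1]
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(p=float(res.pvalue), odds_ratio=float(odds))


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(x, y, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with explicit branch selection.

    mode="auto" uses the exact null distribution when both groups have at
    most 25 observations and the pooled data contain no ties; otherwise the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction is used. U is reported for the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both groups; p = 1")
        return MannWhitneyResult(u=x.size * y.size / 2.0, p=1.0, method="degenerate")
    if mode == "auto":
        exact = x.size <= 25 and y.size <= 25 and not _has_ties(x, y)
    else:
        exact = mode == "exact"
    method = "exact" if exact else "asymptotic"
    res = _st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), p=float(min(res.pvalue, 1.0)), method=method)


def kruskal_wallis_holm(groups: dict[str, list | np.ndarray]) -> KruskalHolmResult:
    """Kruskal-Wallis H (tie-corrected) plus Holm-adjusted pairwise post hocs.

    Pairwise comparisons are two-sided Mann-Whitney tests over all group
    pairs, adjusted with Holm's step-down procedure.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
    vals = list(arrays.values())
    pooled = np.concatenate(vals)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = _st.kruskal(*vals)
    names = list(arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            mw = mann_whitney(arrays[names[i]], arrays[names[j]])
            rows.append((names[i], names[j], mw.u, mw.p))
    pw = pd.DataFrame(rows, columns=["group_a", "group_b", "u", "p"])
    pw["p_holm"] = adjust_pvalues(pw["p"].to_numpy(), method="holm")
    return KruskalHolmResult(h=float(h), p=float(p), pairwise=pw)


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg ("bh") or Holm ("holm") adjustment, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "holm": "holm"}.get(method.lower())
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def _window_distance(track: MigrationTrack, lo: float, hi: float) -> float:
    sel = (track.t >= lo) & (track.t <= hi)
    if sel.sum() < 2:
        raise ValueError(f"window [{lo}, {hi}] h has fewer than 2 samples")
    dx = np.diff(track.x[sel])
    dy = np.diff(track.y[sel])
    return float(np.hypot(dx, dy).sum())


def migration_ratio(track: MigrationTrack,
                    early: tuple[float, float] = (0.0, 24.0),
                    late: tuple[float, float] = (72.0, 96.0)) -> float:
    """Ratio r of migration distance in the late window to the early window.

    Distance is the summed Euclidean step length between consecutive centroid
    samples inside each window. A zero early-window distance yields NaN with a
    warning (ratio undefined).
    """
    d_early = _window_distance(track, *early)
    d_late = _window_distance(track, *late)
    if d_early == 0.0:
        warnings.warn(f"track {track.organoid_id}: zero early-window distance; r undefined")
        return float("nan")
    return d_late / d_early
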