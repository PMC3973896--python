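"""Subpopulation structure of cell-mechanics and flow-cytometry data.

Covers quadrant gating of two-channel cytometry events, univariate
Gaussian-mixture fits with BIC model selection, peak counting on the
fitted density, band fractions (the mechanics interval attributed to
mesenchymal-stem-like cells) and the group-comparison statistics
(Shapiro-Wilk normality, one-way ANOVA, Tukey HSD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multicomp import pairwise_tukeyhsd

QUADRANTS = ("++", "+-", "-+", "--")


@dataclass
class GateSpec:
    """Log-scale gating thresholds per channel; values strictly above a
    threshold are marker-positive, ties count as negative."""

    sca1_threshold: float
    cd44_threshold: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sca1_threshold) and np.isfinite(self.cd44_threshold)):
            raise ValueError("thresholds must be finite")


def derive_gates_from_control(control: pd.DataFrame, percentile: float = 99.5,
                              sca1_col: str = "log_sca1",
                              cd44_col: str = "log_cd44") -> GateSpec:
    """Per-channel threshold at the given percentile of negative-control
    intensities (events above it are called positive)."""
    if len(control) == 0:
        raise ValueError("empty control event table")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    return GateSpec(
        sca1_threshold=float(np.percentile(control[sca1_col], percentile)),
        cd44_threshold=float(np.percentile(control[cd44_col], percentile)),
    )


@dataclass
class QuadrantResult:
    """Quadrant fractions and counts; a partition of all events."""

    fractions: dict[str, float]
    counts: dict[str, int]
    n: int

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if self.n and abs(total - 1.0) > 1e-9:
            raise ValueError("quadrant fractions must sum to 1")


def quadrant_gate(events: pd.DataFrame, gates: GateSpec,
                  sca1_col: str = "log_sca1",
                  cd44_col: str = "log_cd44") -> QuadrantResult:
    """Assign every event to exactly one Sca-1/CD44 quadrant."""
    sca1 = events[sca1_col].to_numpy() > gates.sca1_threshold
    cd44 = events[cd44_col].to_numpy() > gates.cd44_threshold
    n = len(events)
    counts = {
        "++": int(np.sum(sca1 & cd44)),
        "+-": int(np.sum(sca1 & ~cd44)),
        "-+": int(np.sum(~sca1 & cd44)),
        "--": int(np.sum(~sca1 & ~cd44)),
    }
    fractions = {q: (c / n if n else 0.0) for q, c in counts.items()}
    return QuadrantResult(fractions=fractions, counts=counts, n=n)


# ---------------------------------------------------------------------------
# Gaussian mixtures
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """BIC-selected univariate Gaussian mixture.

    Components are sorted by mean; ``bic`` maps each candidate k to its
    score.  ``data_min``/``data_max`` record the fitted data range used
    as the default peak-counting grid.
    """

    property_name: str
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    bic: dict[int, float]
    log_likelihood: float
    data_min: float
    data_max: float
    n: int

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-6:
            raise ValueError("component weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("component sds must be positive")

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        comp = self.weights * stats.norm.pdf(x, self.means, self.sds)
        return comp.sum(axis=-1)


def fit_mixture(values, k_max: int = 6, restarts: int = 20, seed: int = 0,
                variance_floor_factor: float = 1e-3,
                property_name: str = "") -> MixtureFit:
    """EM-fit Gaussian mixtures for k = 1..k_max and select k by BIC.

    Each candidate k is fitted with ``restarts`` initializations;
    component variances are floored at ``variance_floor_factor`` times
    the data variance so duplicated points cannot collapse a
    component.  Deterministic for a given seed.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError(f"need at least 10 values to fit a mixture (got {len(x)})")
    data_var = float(np.var(x))
    floor = max(variance_floor_factor * data_var, 1e-12)
    X = x.reshape(-1, 1)
    k_cap = min(k_max, len(np.unique(x)))
    bics: dict[int, float] = {}
    best: GaussianMixture | None = None
    best_bic = np.inf
    for k in range(1, k_cap + 1):
        gm = GaussianMixture(n_components=k, n_init=restarts, reg_covar=floor,
                             random_state=seed)
        gm.fit(X)
        bics[k] = float(gm.bic(X))
        if bics[k] < best_bic:
            best, best_bic = gm, bics[k]
    order = np.argsort(best.means_[:, 0])
    return MixtureFit(
        property_name=property_name,
        k=best.n_components,
        weights=best.weights_[order],
        means=best.means_[order, 0],
        sds=np.sqrt(best.covariances_[order, 0, 0]),
        bic=bics,
        log_likelihood=float(best.score(X) * len(x)),
        data_min=float(x.min()),
        data_max=float(x.max()),
        n=len(x),
    )


@dataclass
class PeakCount:
    count: int
    locations: np.ndarray
    heights: np.ndarray


def count_peaks(fit: MixtureFit, grid_step: float = 1.0,
                merge_tol: float = 25.0,
                grid_range: tuple[float, float] | None = None) -> PeakCount:
    """Count modes of the fitted mixture density.

    The density is evaluated on a regular grid over the data range
    (default) and strict local maxima are collected; maxima closer
    than ``merge_tol`` are merged, keeping the higher one.
    """
    lo, hi = grid_range if grid_range is not None else (fit.data_min, fit.data_max)
    if hi <= lo:
        raise ValueError("empty peak-counting range")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    dens = fit.pdf(grid)
    is_max = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    locs = grid[1:-1][is_max]
    heights = dens[1:-1][is_max]
    merged: list[tuple[float, float]] = []
    for x, h in zip(locs, heights):
        if merged and x - merged[-1][0] < merge_tol:
            if h > merged[-1][1]:
                merged[-1] = (x, h)
        else:
            merged.append((x, h))
    return PeakCount(count=len(merged),
                     locations=np.array([m[0] for m in merged]),
                     heights=np.array([m[1] for m in merged]))


def band_fraction(values, band: tuple[float, float]) -> float:
    """Fraction of finite values inside the closed interval ``band``."""
    lo, hi = band
    if not lo < hi:
        raise ValueError("band lower bound must be below upper bound")
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return 0.0
    return float(np.mean((x >= lo) & (x <= hi)))


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Normality, omnibus and pairwise statistics for one property."""

    property_name: str
    shapiro: dict[str, tuple[float, float]]
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame
    alpha: float = 0.05
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = bool(self.anova_p < self.alpha)


def compare_groups(table: pd.DataFrame, value_col: str,
                   group_col: str = "group", alpha: float = 0.05) -> GroupComparison:
    """Shapiro-Wilk per group, one-way ANOVA and Tukey HSD pairwise.

    Rows with non-finite values are dropped.  Requires at least two
    groups with at least three observations each.
    """
    data = table[[group_col, value_col]].dropna()
    groups = {g: sub[value_col].to_numpy() for g, sub in data.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    if any(len(v) < 3 for v in groups.values()):
        raise ValueError("each group needs at least 3 observations")
    shapiro = {g: tuple(map(float, stats.shapiro(v))) for g, v in groups.items()}
    f_stat, p = stats.f_oneway(*groups.values())
    tk = pairwise_tukeyhsd(data[value_col].to_numpy(),
                           data[group_col].to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return GroupComparison(property_name=value_col, shapiro=shapiro,
                           anova_f=float(f_stat), anova_p=float(p),
                           tukey=tukey, alpha=alpha)
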