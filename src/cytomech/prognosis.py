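"""Tumor prognosis indicators and their correlation with cell mechanics.

Indicators: tumor volume by the modified ellipsoid formula
``TV = L * W^2`` (caliper length and width, mm), excised tumor weight
TW (g) and the body-weight gain ratio ``BWG = (w_t - w_0) / w_0``.
Also included are two simple assay quantities: the microvascular area
fraction of a binary vessel mask and the percentage wound closure of a
scratch assay.  Correlations are Pearson, classified by magnitude:
low (|r| <= 0.25), fair (<= 0.5), moderate (<= 0.75), high (> 0.75).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CM_COLUMNS = {"CS": "cs_pa", "TS": "ts_pa", "AF": "af_nn"}
INDICATOR_COLUMNS = {"TV": "tv_mm3", "TW": "tw_g", "BWG": "bwg"}

#: Upper bounds of the |r| strength classes (boundary values belong to
#: the lower class).
STRENGTH_BOUNDS = ((0.25, "low"), (0.5, "fair"), (0.75, "moderate"), (1.0, "high"))


def tumor_volume(length_mm, width_mm):
    """Modified ellipsoid tumor volume ``L * W^2`` (mm^3).

    Inputs are canonicalized so the length is the larger of the two
    caliper diameters; the result is therefore invariant to swapped
    arguments.  Negative dimensions are an error.
    """
    length = np.asarray(length_mm, dtype=float)
    width = np.asarray(width_mm, dtype=float)
    if np.any(length < 0) or np.any(width < 0):
        raise ValueError("tumor dimensions must be non-negative")
    lo = np.minimum(length, width)
    hi = np.maximum(length, width)
    out = hi * lo**2
    return float(out) if out.ndim == 0 else out


def bwg(weights_g, w0_g: float | None = None):
    """Body-weight gain ratio series ``(w_t - w_0) / w_0``.

    ``w_0`` defaults to the first entry of the series.
    """
    w = np.asarray(weights_g, dtype=float)
    if w0_g is None:
        if len(w) == 0:
            raise ValueError("empty weight series")
        w0_g = float(w[0])
    if not w0_g > 0:
        raise ValueError("original body weight must be positive")
    return (w - w0_g) / w0_g


def strength_class(r: float) -> str:
    """Association strength of a Pearson coefficient by magnitude."""
    if not np.isfinite(r):
        return "not_computed"
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise ValueError("correlation coefficient outside [-1, 1]")
    for bound, name in STRENGTH_BOUNDS:
        if a <= bound + 1e-12:
            return name
    return "high"


def correlate(table: pd.DataFrame,
              cm_cols: dict[str, str] = CM_COLUMNS,
              indicator_cols: dict[str, str] = INDICATOR_COLUMNS) -> pd.DataFrame:
    """Pairwise Pearson correlation of mechanics versus indicators.

    Complete-case per pair (rows with NaN in either variable dropped).
    Returns one row per (mechanics, indicator) pair with columns
    ``cm, indicator, r, p, n, strength``; pairs with fewer than three
    complete cases are flagged ``not_computed``.
    """
    rows = []
    for cm_name, cm_col in cm_cols.items():
        for ind_name, ind_col in indicator_cols.items():
            sub = table[[cm_col, ind_col]].dropna()
            n = len(sub)
            if n < 3 or sub[cm_col].nunique() < 2 or sub[ind_col].nunique() < 2:
                rows.append(dict(cm=cm_name, indicator=ind_name,
                                 r=float("nan"), p=float("nan"), n=n,
                                 strength="not_computed"))
                continue
            r, p = stats.pearsonr(sub[cm_col], sub[ind_col])
            rows.append(dict(cm=cm_name, indicator=ind_name, r=float(r),
                             p=float(p), n=n, strength=strength_class(r)))
    return pd.DataFrame(rows)


def mvd_fraction(vessel_mask) -> float:
    """Microvascular density as the vascular area fraction: vessel
    pixels over total tissue pixels of a binary mask."""
    mask = np.asarray(vessel_mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    if mask.dtype != bool:
        vals = np.unique(mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    return float(mask.mean())


def wound_closure(widths_t, widths_0) -> float:
    """Percentage wound closure from repeated width measurements.

    ``100 * (1 - mean(widths_t) / mean(widths_0))``; by convention the
    initial wound is measured at several points (four by default in
    the assay).  Negative values mean the wound widened and are
    returned as-is.
    """
    wt = np.asarray(widths_t, dtype=float)
    w0 = np.asarray(widths_0, dtype=float)
    if wt.size == 0 or w0.size == 0:
        raise ValueError("need at least one width per time point")
    m0 = float(np.mean(w0))
    if m0 <= 0:
        raise ValueError("initial wound width must be positive")
    return 100.0 * (1.0 - float(np.mean(wt)) / m0)


def indicator_table(records: pd.DataFrame, indicators: pd.DataFrame | None = None,
                    reference_day: int = 14) -> pd.DataFrame:
    """Recompute TV and BWG from per-animal time series.

    ``records`` is the long-format cohort table (``animal_id, group,
    day, weight_g, length_mm, width_mm``).  TV is evaluated at the
    reference (excision) day, BWG at the final recorded day.  If an
    ``indicators`` table is given (e.g. the generator's output with
    per-animal mean mechanics and TW), its mechanics/TW columns are
    joined onto the recomputed values.
    """
    rows = []
    for animal, sub in records.sort_values("day").groupby("animal_id"):
        ref = sub[sub.day == reference_day]
        if len(ref) == 0:
            raise ValueError(f"animal {animal} has no day-{reference_day} record")
        tv = tumor_volume(float(ref.length_mm.iloc[0]), float(ref.width_mm.iloc[0]))
        gain = bwg(sub.weight_g.to_numpy())[-1]
        rows.append(dict(animal_id=animal, group=sub.group.iloc[0],
                         tv_mm3=tv, bwg=gain))
    out = pd.DataFrame(rows)
    if indicators is not None:
        keep = [c for c in indicators.columns
                if c in ("animal_id", "cs_pa", "ts_pa", "af_nn", "tw_g")]
        out = out.merge(indicators[keep], on="animal_id", how="left")
    return out
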