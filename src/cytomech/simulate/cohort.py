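"""Synthetic animal cohorts with a target mechanics-prognosis
correlation structure.

Per-animal vectors of (mean CS, mean TS, mean AF, TV, TW, BWG) are
drawn through a Gaussian copula: correlated standard normals with the
target correlation are pushed through the normal CDF and mapped to the
per-group marginal distributions by inverse transform.  Tumor
length/width and body-weight time series are then laid down so that
the indicator recomputed from the series (volume at the excision day,
weight-gain ratio at study end) reproduces the drawn value exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .. import params
from .specs import CohortSpec


def _marginal_ppf(kind: str, mean: float, sd: float, u: np.ndarray) -> np.ndarray:
    if kind == "normal":
        return stats.norm.ppf(u, loc=mean, scale=sd)
    if kind == "lognormal":
        # match the requested mean/sd via log-normal moments
        cv2 = (sd / mean) ** 2
        sigma2 = math.log1p(cv2)
        mu = math.log(mean) - sigma2 / 2.0
        return np.exp(stats.norm.ppf(u, loc=mu, scale=math.sqrt(sigma2)))
    raise ValueError(f"unknown marginal kind: {kind}")


def gaussian_copula_sample(correlation: np.ndarray, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Uniform(0,1) samples with the given Gaussian-copula correlation."""
    eigval, eigvec = np.linalg.eigh(correlation)
    if eigval.min() < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semidefinite "
            f"(minimum eigenvalue {float(eigval.min()):.4g})")
    factor = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    z = rng.standard_normal((n, correlation.shape[0])) @ factor.T
    return stats.norm.cdf(z)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-animal records and the indicator/mechanics table.

    Returns
    -------
    records : long-format frame with columns ``animal_id, group, day,
        weight_g, length_mm, width_mm`` (tumor dimensions are 0 while
        no palpable tumor is present).
    indicators : one row per animal: ``animal_id, group, cs_pa, ts_pa,
        af_nn, tv_mm3, tw_g, bwg`` where ``tv_mm3`` is the volume at
        the excision day and ``bwg`` the weight-gain ratio at study
        end.
    """
    rng = np.random.default_rng(spec.seed)
    names = params.COHORT_VARIABLES
    ind_rows = []
    rec_rows = []
    for group in sorted(spec.group_sizes):
        n = spec.group_sizes[group]
        u = gaussian_copula_sample(spec.correlation, n, rng)
        draws = {name: _marginal_ppf(*spec.marginals[group][name], u[:, i])
                 for i, name in enumerate(names)}
        # mechanics cannot be negative; clip pathological tail draws
        for name in ("CS", "TS", "AF", "TW"):
            draws[name] = np.clip(draws[name], 1e-6, None)
        draws["BWG"] = np.clip(draws["BWG"], -0.99, None)

        aspect = rng.uniform(1.1, 1.5, size=n)  # length/width ratio
        w0 = rng.normal(*spec.initial_body_weight_g, size=n)
        growth = (np.log(draws["TV"] / spec.initial_volume_mm3)
                  / max(spec.excision_day, 1))

        for i in range(n):
            animal = f"{group}-{i:03d}"
            ind_rows.append(dict(
                animal_id=animal, group=group,
                cs_pa=draws["CS"][i], ts_pa=draws["TS"][i], af_nn=draws["AF"][i],
                tv_mm3=draws["TV"][i], tw_g=draws["TW"][i], bwg=draws["BWG"][i],
            ))
            final_day = spec.days[-1]
            for day in spec.days:
                if day <= spec.excision_day:
                    tv = draws["TV"][i] * math.exp(growth[i] * (day - spec.excision_day))
                elif group == "Rec" and day >= spec.regrowth_day:
                    tv = spec.initial_volume_mm3 * math.exp(
                        growth[i] * (day - spec.regrowth_day))
                else:
                    tv = 0.0
                if tv > 0:
                    width = (tv / aspect[i]) ** (1.0 / 3.0)
                    length = aspect[i] * width
                else:
                    width = length = 0.0
                weight = w0[i] * (1.0 + draws["BWG"][i] * day / final_day)
                rec_rows.append(dict(animal_id=animal, group=group, day=int(day),
                                     weight_g=weight, length_mm=length,
                                     width_mm=width))
    records = pd.DataFrame(rec_rows)
    indicators = pd.DataFrame(ind_rows)
    return records, indicators
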