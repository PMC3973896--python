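"""Synthetic per-cell mechanics populations and flow-cytometry events."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .specs import FlowSpec, PopulationSpec

_MAX_REDRAWS = 1000

#: Properties generated per cell and their output column names.
CM_COLUMNS = {"CS": "cs_pa", "TS": "ts_pa", "AF": "af_nn"}


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray,
                      sd: np.ndarray) -> np.ndarray:
    """Positive normal draws by redraw (rejection); the study mixtures
    put negligible mass below zero except for the broad stromal
    component, so rejection is cheap."""
    x = rng.normal(mean, sd)
    for _ in range(_MAX_REDRAWS):
        bad = x <= 0
        if not bad.any():
            return x
        if np.all(sd[bad] == 0):
            raise ValueError("component with non-positive mean and zero sd")
        x[bad] = rng.normal(mean[bad], sd[bad])
    raise ValueError("positivity truncation failed; check component parameters")


def generate_cm_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a per-cell mechanics table from the subgroup mixture.

    Each cell is assigned a true subgroup from ``spec.proportions``,
    then its CS/TS/AF values are drawn from that subgroup's normal
    components (independently per property, truncated to positive
    values when ``truncate_positive``).

    Returns a frame with columns ``cell_id, group, truth_subgroup,
    cs_pa, ts_pa, af_nn``.
    """
    rng = np.random.default_rng(spec.seed)
    subgroups = sorted(spec.proportions)
    probs = np.array([spec.proportions[s] for s in subgroups], dtype=float)
    probs = probs / probs.sum()
    labels = rng.choice(len(subgroups), size=spec.n, p=probs)

    out = pd.DataFrame({
        "cell_id": [f"{spec.group}-{i:04d}" for i in range(spec.n)],
        "group": spec.group,
        "truth_subgroup": [subgroups[i] for i in labels],
    })
    any_props = next(iter(spec.components.values()))
    for prop in any_props:
        means = np.array([spec.components[subgroups[i]][prop][0] for i in labels])
        sds = np.array([spec.component_sd(subgroups[i], prop) for i in labels])
        if np.any(sds < 0):
            raise ValueError("negative component sd")
        if spec.truncate_positive:
            vals = _truncated_normal(rng, means, sds)
        else:
            vals = rng.normal(means, sds)
        out[CM_COLUMNS.get(prop, prop.lower())] = vals
    return out


def generate_flow_events(spec: FlowSpec) -> pd.DataFrame:
    """Draw a two-channel event table with known quadrant labels.

    Quadrant keys are ``"<sca1><cd44>"`` signs.  Channel intensities
    are log10-scale normals centered at ``log_positive`` /
    ``log_negative`` per marker status; tails may cross the generating
    threshold, as in real cytometry, so gating recovers the generating
    proportions only up to that leakage.

    Returns columns ``event_id, truth_quadrant, log_sca1, log_cd44``.
    """
    rng = np.random.default_rng(spec.seed)
    quads = sorted(spec.proportions)
    probs = np.array([spec.proportions[q] for q in quads], dtype=float)
    probs = probs / probs.sum()
    labels = rng.choice(len(quads), size=spec.n_events, p=probs)
    quad = np.array(quads, dtype=object)[labels]

    sca1_pos = np.array([q[0] == "+" for q in quad])
    cd44_pos = np.array([q[1] == "+" for q in quad])
    loc = {True: spec.log_positive, False: spec.log_negative}
    log_sca1 = rng.normal(np.where(sca1_pos, loc[True], loc[False]), spec.log_sd)
    log_cd44 = rng.normal(np.where(cd44_pos, loc[True], loc[False]), spec.log_sd)

    return pd.DataFrame({
        "event_id": np.arange(spec.n_events),
        "truth_quadrant": quad,
        "log_sca1": log_sca1,
        "log_cd44": log_cd44,
    })
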