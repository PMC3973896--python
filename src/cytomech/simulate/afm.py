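"""Synthetic AFM force-volume maps with known point moduli."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..afm import ForceCurve, TipModel, pyramid_force
from .specs import AfmSpec


@dataclass
class ForceVolumeData:
    """A grid of simulated approach curves plus the generating truth."""

    curves: dict[tuple[int, int], ForceCurve]
    truth_field_pa: np.ndarray
    truth_contact_um: np.ndarray
    spec: AfmSpec

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (row, col, z_um, f_nn, segment)."""
        parts = []
        for (r, c), curve in sorted(self.curves.items()):
            parts.append(pd.DataFrame({
                "row": r, "col": c,
                "z_um": curve.z_um, "f_nn": curve.f_nn,
                "segment": curve.segment,
            }))
        return pd.concat(parts, ignore_index=True)


def generate_afm_map(spec: AfmSpec) -> ForceVolumeData:
    """Simulate one force-volume map over the spec's stiffness field.

    Each grid point gets a pyramidal-indentation approach curve: zero
    force until the (jittered) contact point, then the contact-model
    force for that point's true modulus, plus Gaussian force noise.
    """
    rng = np.random.default_rng(spec.seed)
    tip = TipModel(geometry="pyramid", half_angle_rad=spec.tip_half_angle_rad,
                   poisson_ratio=spec.poisson_ratio)
    nr, nc = spec.stiffness_field.shape
    span = spec.contact_offset_um + spec.contact_jitter_um + spec.max_indentation_um
    z = np.linspace(0.0, span, spec.samples_per_curve)

    curves: dict[tuple[int, int], ForceCurve] = {}
    z0_grid = np.empty((nr, nc))
    for r in range(nr):
        for c in range(nc):
            z0 = spec.contact_offset_um
            if spec.contact_jitter_um > 0:
                z0 += rng.uniform(-spec.contact_jitter_um, spec.contact_jitter_um)
            z0_grid[r, c] = z0
            f = pyramid_force(np.minimum(z - z0, spec.max_indentation_um),
                              spec.stiffness_field[r, c], tip)
            if spec.noise_sd_nn > 0:
                f = f + rng.normal(0.0, spec.noise_sd_nn, f.shape)
            curves[(r, c)] = ForceCurve(z_um=z, f_nn=f, segment="approach")
    return ForceVolumeData(curves=curves, truth_field_pa=spec.stiffness_field,
                           truth_contact_um=z0_grid, spec=spec)
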