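"""Parameter dataclasses for the synthetic-data generators.

Every generator input is an explicit spec with a mandatory seed: there
is no hidden global random state, and identical specs produce
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .. import params


@dataclass
class MechanicsTruth:
    """Ground-truth mechanical parameters of one simulated cell.

    Moduli are in Pa, forces in nN, lengths in um.  ``spring_constant``
    is the cantilever stiffness (nN/um); ``piezo_amplitude_um`` and
    ``piezo_speed_um_s`` define the commanded compression protocol.
    """

    compressive_modulus_pa: float
    tensile_modulus_pa: float
    adhesion_force_nn: float
    h0_um: float = 15.0
    d0_um: float = 18.0
    spring_constant: float = params.DEFAULT_SPRING_CONSTANT
    piezo_amplitude_um: float = params.PIEZO_AMPLITUDE_UM
    piezo_speed_um_s: float = params.PIEZO_SPEED_UM_S

    def __post_init__(self) -> None:
        for name in ("compressive_modulus_pa", "tensile_modulus_pa", "h0_um",
                     "d0_um", "spring_constant", "piezo_amplitude_um",
                     "piezo_speed_um_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.adhesion_force_nn < 0:
            raise ValueError("adhesion_force_nn must be non-negative")

    @property
    def contact_area_um2(self) -> float:
        """Initial circular contact area pi*d0^2/4 (um^2)."""
        return math.pi * self.d0_um**2 / 4.0


@dataclass
class ImagingConfig:
    """Rendering parameters for synthetic microplate frames.

    Intensity levels are 8-bit gray values; ``noise_sd`` is the standard
    deviation of additive Gaussian intensity noise (0 disables it), and
    ``blur_sigma_px`` an optional Gaussian point-spread width.
    """

    scale: float = params.SCALE_PX_PER_UM
    frame_interval_s: float = 0.25
    image_height: int = 224
    image_width: int = 128
    background_level: int = 200
    cell_level: int = 120
    cantilever_level: int = 40
    slide_level: int = 40
    cantilever_thickness_px: int = 12
    slide_band_px: int = 10
    noise_sd: float = 4.0
    blur_sigma_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.image_height < 32 or self.image_width < 16:
            raise ValueError("image too small")
        for name in ("background_level", "cell_level", "cantilever_level", "slide_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be within 0..255")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be non-negative")

    @property
    def slide_surface_row(self) -> int:
        """Topmost slide pixel row; physical height zero maps here."""
        return self.image_height - self.slide_band_px


@dataclass
class PopulationSpec:
    """Mixture specification for a per-cell mechanics population.

    ``proportions`` maps subgroup keys to mixing weights (must sum to
    one); ``components`` maps subgroup keys to per-property
    ``(mean, spread)`` pairs for CS/TS/AF.  ``spread_is`` selects how a
    printed dispersion is interpreted: as the component standard
    deviation (``"sd"``, default) or as a standard error to be scaled
    back up by ``sqrt(n)`` using ``component_n`` (``"sem"``).
    """

    group: str
    n: int
    seed: int
    proportions: dict[str, float]
    components: dict[str, dict[str, tuple[float, float]]]
    component_n: dict[str, dict[str, int]] | None = None
    spread_is: str = "sd"
    truncate_positive: bool = True

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        total = sum(self.proportions.values())
        # printed percentages may round to 99.9/100.1%
        if not math.isclose(total, 1.0, abs_tol=5e-3):
            raise ValueError(f"proportions must sum to 1 (got {total})")
        if self.spread_is not in ("sd", "sem"):
            raise ValueError("spread_is must be 'sd' or 'sem'")
        for sub, props in self.components.items():
            for prop, (mean, spread) in props.items():
                if spread < 0:
                    raise ValueError(f"negative spread for {sub}/{prop}")
        if self.spread_is == "sem" and self.component_n is None:
            raise ValueError("spread_is='sem' requires component_n")

    def component_sd(self, subgroup: str, prop: str) -> float:
        mean, spread = self.components[subgroup][prop]
        if self.spread_is == "sd":
            return spread
        return spread * math.sqrt(self.component_n[subgroup][prop])

    @classmethod
    def from_group(cls, group: str, n: int | None = None, seed: int = 0,
                   spread_is: str = "sd", truncate_positive: bool = True) -> "PopulationSpec":
        """Default spec for a recurrence group from the study tables."""
        if n is None:
            n = params.GROUP_CM[group]["CS"][2]
        comps = {sub: {p: (m, s) for p, (m, s, _) in props.items()}
                 for sub, props in params.SUBGROUP_CM[group].items()}
        ns = {sub: {p: cnt for p, (_, _, cnt) in props.items()}
              for sub, props in params.SUBGROUP_CM[group].items()}
        return cls(group=group, n=n, seed=seed,
                   proportions=dict(params.QUADRANT_PROPORTIONS[group]),
                   components=comps, component_n=ns,
                   spread_is=spread_is, truncate_positive=truncate_positive)


@dataclass
class FlowSpec:
    """Two-channel (Sca-1 / CD44) flow-cytometry event generator spec.

    Channel intensities are log10-scale; each marker-positive
    population sits at ``log_positive`` and each negative population at
    ``log_negative`` with common spread ``log_sd``.  The generating
    gate between them is at ``threshold`` on the log scale.
    """

    proportions: dict[str, float]
    n_events: int
    seed: int
    log_negative: float = -1.0
    log_positive: float = 1.0
    log_sd: float = 0.35
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        total = sum(self.proportions.values())
        if not math.isclose(total, 1.0, abs_tol=5e-3):
            raise ValueError(f"proportions must sum to 1 (got {total})")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")

    @classmethod
    def from_group(cls, group: str, n_events: int = 10_000, seed: int = 0) -> "FlowSpec":
        return cls(proportions=dict(params.QUADRANT_PROPORTIONS[group]),
                   n_events=n_events, seed=seed)


@dataclass
class AfmSpec:
    """Force-volume map generator spec.

    ``stiffness_field`` is the true elastic-modulus grid (Pa); the
    default geometry is a 10x10 grid spanning 50x50 um^2.  Curves are
    pyramidal-indentation approach curves with ``samples_per_curve``
    points, contact at ``contact_offset_um`` into the ramp (jittered by
    ``contact_jitter_um`` per point) and indentation up to
    ``max_indentation_um``.
    """

    stiffness_field: np.ndarray
    extent_um: tuple[float, float] = (50.0, 50.0)
    tip_half_angle_rad: float = params.DEFAULT_TIP_HALF_ANGLE
    poisson_ratio: float = 0.5
    max_indentation_um: float = 2.0
    samples_per_curve: int = 200
    contact_offset_um: float = 1.0
    contact_jitter_um: float = 0.1
    noise_sd_nn: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.stiffness_field = np.asarray(self.stiffness_field, dtype=float)
        if self.stiffness_field.ndim != 2:
            raise ValueError("stiffness_field must be a 2-D grid")
        if np.any(self.stiffness_field <= 0):
            raise ValueError("stiffness_field values must be positive")
        if not 0 < self.tip_half_angle_rad < math.pi / 2:
            raise ValueError("tip half-angle must be in (0, pi/2)")
        if self.max_indentation_um <= 0 or self.samples_per_curve < 20:
            raise ValueError("invalid indentation range or sampling")
        if self.noise_sd_nn < 0:
            raise ValueError("noise_sd_nn must be non-negative")

    @classmethod
    def from_stats(cls, mean_pa: float, sd_pa: float, shape: tuple[int, int] = (10, 10),
                   seed: int = 0, **kwargs) -> "AfmSpec":
        """Random heterogeneous field with log-normal point moduli
        matched to the requested mean and SD (guaranteed positive)."""
        rng = np.random.default_rng(seed)
        cv2 = (sd_pa / mean_pa) ** 2
        sigma2 = math.log1p(cv2)
        mu = math.log(mean_pa) - sigma2 / 2.0
        field_vals = rng.lognormal(mu, math.sqrt(sigma2), size=shape)
        return cls(stiffness_field=field_vals, seed=seed, **kwargs)


@dataclass
class CohortSpec:
    """Animal-cohort generator spec.

    Per-animal vectors over :data:`cytomech.params.COHORT_VARIABLES`
    are drawn through a Gaussian copula with ``correlation`` as target,
    then mapped to per-group marginal distributions.  ``marginals`` maps
    group -> variable -> ("normal"|"lognormal", mean, sd).
    """

    group_sizes: dict[str, int]
    seed: int
    correlation: np.ndarray | None = None
    marginals: dict[str, dict[str, tuple[str, float, float]]] | None = None
    days: np.ndarray = field(default_factory=lambda: np.arange(0, 50, 2))
    excision_day: int = 14
    regrowth_day: int = 21
    initial_volume_mm3: float = 20.0
    initial_body_weight_g: tuple[float, float] = (20.0, 1.2)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if self.correlation is None:
            self.correlation = default_cohort_correlation()
        self.correlation = np.asarray(self.correlation, dtype=float)
        k = len(params.COHORT_VARIABLES)
        if self.correlation.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}")
        if not np.allclose(self.correlation, self.correlation.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        eigmin = float(np.linalg.eigvalsh(self.correlation).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semidefinite "
                f"(minimum eigenvalue {eigmin:.4g})")
        if self.marginals is None:
            self.marginals = default_cohort_marginals(self.group_sizes.keys())

    @classmethod
    def from_defaults(cls, n_per_group: int = 5, seed: int = 0, **kwargs) -> "CohortSpec":
        return cls(group_sizes={"Non-Rec": n_per_group, "Rec": n_per_group},
                   seed=seed, **kwargs)


def default_cohort_correlation() -> np.ndarray:
    """Target correlation over (CS, TS, AF, TV, TW, BWG).

    Cross-block entries are the study's mechanics-indicator
    correlations; within-block entries are the package defaults.
    """
    names = params.COHORT_VARIABLES
    k = len(names)
    corr = np.eye(k)
    pairs = dict(params.CM_INDICATOR_CORR)
    pairs.update(params.DEFAULT_WITHIN_CORR)
    for (a, b), r in pairs.items():
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = r
    return corr


def default_cohort_marginals(groups) -> dict[str, dict[str, tuple[str, float, float]]]:
    """Per-group marginals: normal mechanics/weight indicators,
    log-normal tumor volume (strictly positive, right-skewed)."""
    out: dict[str, dict[str, tuple[str, float, float]]] = {}
    for g in groups:
        out[g] = {
            "CS": ("normal",) + params.GROUP_CM[g]["CS"][:2],
            "TS": ("normal",) + params.GROUP_CM[g]["TS"][:2],
            "AF": ("normal",) + params.GROUP_CM[g]["AF"][:2],
            "TV": ("lognormal",) + params.TUMOR_VOLUME_DAY14[g],
            "TW": ("normal",) + params.TUMOR_WEIGHT_G[g],
            "BWG": ("normal",) + params.BWG_RATIO[g],
        }
    return out
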