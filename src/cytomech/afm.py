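"""AFM force-curve analysis: contact-point detection, pyramidal
indentation fits and force-volume stiffness maps.

The default contact model is Bilodeau's solution for a four-sided
pyramidal indenter on an incompressible elastic half-space,

    F = 0.7453 * tan(theta) * E / (1 - nu^2) * delta^2,

with tip half-angle ``theta``, Poisson ratio ``nu`` (0.5 for soft
tissue) and indentation ``delta = z - z0`` past the contact point
``z0``.  Units are handled as nN / um / Pa throughout, so the model
force in nN carries a factor 1e-3 (1 Pa * um^2 = 1e-3 nN).  A
Hertz-sphere alternative is available for rounded tips.

Fits are quasi-static least squares, linear in E; the default maximum
fit depth (2 um) is 10% of a 20-um cryosection, limiting substrate
contributions on thin samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import params

#: Geometric prefactor of the four-sided pyramid contact solution.
PYRAMID_COEFF = 0.7453

#: Pa * um^2 expressed in nN.
PA_UM2_TO_NN = 1e-3


class NoContactError(ValueError):
    """Raised when a force curve shows no tip-sample contact."""


class FitError(ValueError):
    """Raised when an indentation fit is not possible."""


@dataclass
class TipModel:
    """Indenter geometry and sample Poisson ratio."""

    geometry: str = "pyramid"
    half_angle_rad: float = params.DEFAULT_TIP_HALF_ANGLE
    poisson_ratio: float = 0.5
    radius_um: float = 5.0  # only used by the Hertz-sphere model

    def __post_init__(self) -> None:
        if self.geometry not in ("pyramid", "sphere"):
            raise ValueError("geometry must be 'pyramid' or 'sphere'")
        if not 0 < self.half_angle_rad < math.pi / 2:
            raise ValueError("half-angle must be in (0, pi/2)")
        if not 0 <= self.poisson_ratio < 0.5 + 1e-9:
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")


@dataclass
class ForceCurve:
    """One indentation curve: piezo extension z (um, increasing on
    approach) versus cantilever force (nN)."""

    z_um: np.ndarray
    f_nn: np.ndarray
    segment: str = "approach"

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.f_nn = np.asarray(self.f_nn, dtype=float)
        if self.z_um.shape != self.f_nn.shape or self.z_um.ndim != 1:
            raise ValueError("z and force must be 1-D arrays of equal length")
        if not (np.isfinite(self.z_um).all() and np.isfinite(self.f_nn).all()):
            raise ValueError("force curve contains non-finite values")
        if self.segment == "approach" and np.any(np.diff(self.z_um) <= 0):
            raise ValueError("z must be strictly increasing on approach")

    def __len__(self) -> int:
        return len(self.z_um)


def pyramid_force(delta_um, e_pa: float, tip: TipModel) -> np.ndarray:
    """Model force (nN) of a pyramidal tip at indentation delta (um)."""
    delta = np.clip(np.asarray(delta_um, dtype=float), 0.0, None)
    coeff = PYRAMID_COEFF * math.tan(tip.half_angle_rad) / (1.0 - tip.poisson_ratio**2)
    return coeff * e_pa * delta**2 * PA_UM2_TO_NN


def hertz_force(delta_um, e_pa: float, tip: TipModel) -> np.ndarray:
    """Hertz model force (nN) of a spherical tip at indentation delta (um)."""
    delta = np.clip(np.asarray(delta_um, dtype=float), 0.0, None)
    coeff = (4.0 / 3.0) * math.sqrt(tip.radius_um) / (1.0 - tip.poisson_ratio**2)
    return coeff * e_pa * delta**1.5 * PA_UM2_TO_NN


def _baseline(curve: ForceCurve, fraction: float = 0.2, min_points: int = 5):
    """Linear pre-contact baseline fit over the first part of the ramp."""
    n = max(min_points, int(round(fraction * len(curve))))
    n = min(n, len(curve))
    z, f = curve.z_um[:n], curve.f_nn[:n]
    slope, intercept = np.polyfit(z, f, 1)
    resid_sd = float(np.std(f - (slope * z + intercept)))
    return slope, intercept, resid_sd


def detect_contact_point(curve: ForceCurve, min_segment: int = 5,
                         baseline_fraction: float = 0.2,
                         window: int | None = None) -> tuple[int, float]:
    """Locate the tip-sample contact point on an approach curve.

    The curve is baseline-corrected with a linear pre-contact fit, then
    scanned with the ratio-of-variances statistic: at each candidate
    index the variance of the force over the window just ahead is
    divided by the variance over the window just behind.  Before
    contact both windows hold baseline noise; at contact the ahead
    window picks up the indentation signal while the behind window is
    still flat, so the ratio peaks there.

    Returns
    -------
    (index, z0) : contact sample index and its extension value (um).

    Raises
    ------
    NoContactError
        If the curve never rises above the baseline noise.
    """
    if len(curve) < 3 * min_segment:
        raise FitError(f"curve too short ({len(curve)} samples)")
    if window is None:
        window = max(min_segment, len(curve) // 20)
    slope, intercept, resid_sd = _baseline(curve, baseline_fraction, min_segment)
    resid = curve.f_nn - (slope * curve.z_um + intercept)
    signal = float(resid.max())
    threshold = max(5.0 * resid_sd, 1e-9 * max(1.0, float(np.abs(curve.f_nn).max())), 1e-12)
    if signal < threshold:
        raise NoContactError("no contact detected: curve stays at baseline")
    floor = max(1e-12 * float(np.var(resid)), 1e-300)
    idx = np.arange(window, len(resid) - window)
    ahead = np.array([float(np.var(resid[i:i + window])) for i in idx])
    behind = np.array([max(float(np.var(resid[i - window:i])), floor) for i in idx])
    best = int(idx[np.argmax(ahead / behind)])
    return best, float(curve.z_um[best])


@dataclass
class PointFit:
    """Per-point indentation fit result."""

    e_pa: float
    contact_index: int
    z0_um: float
    n_samples: int
    rms_residual_nn: float


def _solve_modulus(z: np.ndarray, f: np.ndarray, z0: float, coeff: float,
                   exponent: float, max_fit_depth_um: float):
    """Closed-form least-squares modulus for a fixed contact point."""
    delta = z - z0
    post = (delta > 0) & (delta <= max_fit_depth_um)
    if post.sum() < 10:
        return None
    basis = delta[post] ** exponent
    denom = float(np.sum(basis**2))
    if denom <= 0:
        return None
    amp = float(np.sum(f[post] * basis) / denom)
    sse = float(np.sum((f[post] - amp * basis) ** 2))
    e_pa = amp / (coeff * PA_UM2_TO_NN)
    return e_pa, sse, int(post.sum())


def fit_indentation(curve: ForceCurve, tip: TipModel,
                    max_fit_depth_um: float = 2.0,
                    contact: tuple[int, float] | None = None,
                    refine_contact: bool = True) -> PointFit:
    """Fit the contact model to one curve and return the modulus (Pa).

    The fit is linear in E: for the pyramid, ``E`` solves
    ``min_E sum (F_i - c * E * delta_i^2)^2`` in closed form (``c`` the
    geometric prefactor); the Hertz sphere uses ``delta^1.5``.
    Indentation is capped at ``max_fit_depth_um``.

    The variance-ratio contact estimate is only sample-accurate — near
    contact the indentation force is buried in the force noise — so by
    default the contact position is refined by profile least squares:
    for every candidate ``z0`` the modulus is solved in closed form and
    the candidate minimizing the residual is kept (coarse grid over the
    samples, then a bounded scalar minimization between neighbours).
    """
    if contact is None:
        contact = detect_contact_point(curve, min_segment=5)
    else:
        refine_contact = False  # an explicit contact point is honored as-is
    idx, z0 = contact
    slope, intercept, _ = _baseline(curve)
    f = curve.f_nn - (slope * curve.z_um + intercept)
    if tip.geometry == "pyramid":
        exponent = 2.0
        coeff = PYRAMID_COEFF * math.tan(tip.half_angle_rad) / (1.0 - tip.poisson_ratio**2)
    else:
        exponent = 1.5
        coeff = (4.0 / 3.0) * math.sqrt(tip.radius_um) / (1.0 - tip.poisson_ratio**2)

    if refine_contact:
        from scipy.optimize import minimize_scalar

        def objective(cand: float) -> float:
            sol = _solve_modulus(curve.z_um, f, cand, coeff, exponent,
                                 max_fit_depth_um)
            return sol[1] if sol is not None else np.inf

        scores = np.array([objective(z) for z in curve.z_um])
        if np.isfinite(scores).any():
            i = int(np.nanargmin(np.where(np.isfinite(scores), scores, np.nan)))
            lo = curve.z_um[max(i - 1, 0)]
            hi = curve.z_um[min(i + 1, len(curve) - 1)]
            dz = float(np.median(np.diff(curve.z_um)))
            res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                  options={"xatol": dz * 1e-4})
            z0 = float(res.x) if np.isfinite(res.fun) else float(curve.z_um[i])

    sol = _solve_modulus(curve.z_um, f, z0, coeff, exponent, max_fit_depth_um)
    if sol is None:
        n_post = int(np.sum(curve.z_um > z0))
        raise FitError(f"only {n_post} post-contact samples (need >= 10)")
    e_pa, sse, n_samples = sol
    return PointFit(e_pa=e_pa, contact_index=idx, z0_um=z0,
                    n_samples=n_samples,
                    rms_residual_nn=float(math.sqrt(sse / n_samples)))


# Backwards-friendly alias: the pyramid is the default contact model.
fit_pyramid_model = fit_indentation


@dataclass
class StiffnessMap:
    """Grid of fitted elastic moduli with summary statistics.

    ``e_pa`` is NaN wherever the per-point fit failed; statistics are
    computed over valid points only.
    """

    e_pa: np.ndarray
    extent_um: tuple[float, float]
    n_valid: int = field(init=False)
    n_masked: int = field(init=False)
    mean_pa: float = field(init=False)
    sd_pa: float = field(init=False)

    def __post_init__(self) -> None:
        self.e_pa = np.asarray(self.e_pa, dtype=float)
        valid = np.isfinite(self.e_pa)
        self.n_valid = int(valid.sum())
        self.n_masked = int((~valid).sum())
        self.mean_pa = float(np.nanmean(self.e_pa)) if self.n_valid else float("nan")
        self.sd_pa = float(np.nanstd(self.e_pa, ddof=1)) if self.n_valid > 1 else float("nan")

    @property
    def positions_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (row, col) center positions of the grid points."""
        nr, nc = self.e_pa.shape
        ys = (np.arange(nr) + 0.5) * self.extent_um[0] / nr
        xs = (np.arange(nc) + 0.5) * self.extent_um[1] / nc
        return ys, xs


def build_stiffness_map(curves: dict[tuple[int, int], ForceCurve],
                        tip: TipModel,
                        grid_shape: tuple[int, int] | None = None,
                        extent_um: tuple[float, float] = (50.0, 50.0),
                        max_fit_depth_um: float = 2.0) -> StiffnessMap:
    """Fit every curve of a force-volume grid and assemble the map.

    ``curves`` maps (row, col) grid indices to approach curves.  Points
    whose fit fails (no contact, too few samples) are masked as NaN.
    """
    if not curves:
        raise ValueError("no curves supplied")
    if grid_shape is None:
        grid_shape = (max(r for r, _ in curves) + 1, max(c for _, c in curves) + 1)
    grid = np.full(grid_shape, np.nan)
    for (r, c), curve in curves.items():
        try:
            grid[r, c] = fit_indentation(curve, tip, max_fit_depth_um).e_pa
        except (NoContactError, FitError):
            pass
    return StiffnessMap(e_pa=grid, extent_um=extent_um)
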