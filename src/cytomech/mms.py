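"""Cell-mechanics recovery from microplate frame sequences.

The measurement chain mirrors the instrument's image pipeline: mean
filtering, histogram equalization, edge filtering and edge detection
locate the cantilever's lower edge in every frame; the deflection
(tracked tip motion relative to the commanded piezo base) times the
calibrated spring constant gives the force (Hooke's law); cell height
and diameter segmented from the same frames give axial strain
``eps = |h0 - h| / h0`` and the circular contact area
``Ac = pi d^2 / 4``; stress is ``sigma = F / Ac`` and the stiffness of
each phase is the origin-constrained slope of stress versus strain.
The adhesion force is the peak tensile force before the pull-off drop.

Units: um, nN, Pa; ``sigma[Pa] = 1000 * F[nN] / Ac[um^2]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from skimage.exposure import equalize_hist
from skimage.filters import sobel_h, threshold_otsu
from skimage.measure import label, regionprops

from . import params
from .frames import FrameSequence

NN_PER_UM2_TO_PA = 1000.0  # 1 nN/um^2 = 1 kPa


class MeasurementError(RuntimeError):
    """Raised when a sequence cannot be measured at all."""


class NoCellError(MeasurementError):
    """Raised when no cell is visible in a frame that requires one."""


class InsufficientFramesError(MeasurementError):
    """Raised when a sequence is too short to measure."""


@dataclass
class MeasurementConfig:
    """Tunable parameters of the measurement chain.

    ``scale`` (px/um) and ``spring_constant`` (nN/um) are instrument
    calibrations.  ``strain_window`` bounds the strains used in the
    linear stiffness fit; ``detachment_drop`` / ``detachment_floor``
    define the pull-off detector (force must fall by more than the
    drop fraction of the running peak and stay below the floor
    fraction); ``min_phase_frames`` is the minimum number of usable
    frames per phase.
    """

    scale: float = params.SCALE_PX_PER_UM
    spring_constant: float = params.DEFAULT_SPRING_CONSTANT
    strain_window: float = 0.20
    detachment_drop: float = 0.5
    detachment_floor: float = 0.2
    min_phase_frames: int = 5
    r2_threshold: float = 0.9
    max_missing_fraction: float = 0.2
    edge_strength_fraction: float = 0.5
    max_bar_thickness_px: int = 40
    fit_intercept: bool = True
    single_point_stiffness: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.spring_constant <= 0:
            raise ValueError("scale and spring_constant must be positive")
        for name in ("strain_window", "detachment_drop", "detachment_floor",
                     "max_missing_fraction", "edge_strength_fraction"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_phase_frames < 2:
            raise ValueError("min_phase_frames must be >= 2")


# ---------------------------------------------------------------------------
# image chain
# ---------------------------------------------------------------------------

def _filter_chain(img: np.ndarray) -> np.ndarray:
    """3x3 mean filter followed by histogram equalization (float in [0,1])."""
    return equalize_hist(uniform_filter(img.astype(float), size=3))


def _horizontal_edge_rows(eq: np.ndarray, strength_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Rows holding strong full-width horizontal edges.

    Returns (rows, scores) of local maxima of the column-averaged
    absolute horizontal-edge response that exceed the given fraction
    of the strongest response.
    """
    edges = np.abs(sobel_h(eq))
    score = edges.mean(axis=1)
    if score.max() <= 0:
        return np.array([], dtype=int), np.array([])
    strong = score >= strength_fraction * score.max()
    rows = []
    for r in np.flatnonzero(strong):
        lo, hi = max(r - 2, 0), min(r + 3, len(score))
        if score[r] == score[lo:hi].max():
            rows.append(r)
    rows = np.asarray(rows, dtype=int)
    # collapse plateaus of equal score
    keep = np.ones(len(rows), dtype=bool)
    for i in range(1, len(rows)):
        if rows[i] - rows[i - 1] <= 2 and score[rows[i]] == score[rows[i - 1]]:
            keep[i] = False
    rows = rows[keep]
    return rows, score[rows]


def _find_tip_row(eq: np.ndarray, config: MeasurementConfig,
                  previous: float | None) -> float:
    """Cantilever lower-edge row in one filtered frame, or NaN.

    The slide's top edge is the bottom-most strong full-width edge;
    the cantilever's top edge is the topmost.  The tip (lower edge of
    the bar) is the strongest edge below the bar top within the
    plausible bar thickness; ties are broken toward the previous
    frame's tip row.
    """
    rows, scores = _horizontal_edge_rows(eq, config.edge_strength_fraction)
    if len(rows) == 0:
        return float("nan")
    slide_row = rows[-1]
    band = rows[rows < slide_row - 2]
    band_scores = scores[rows < slide_row - 2]
    if len(band) == 0:
        return float("nan")
    bar_top = band[0]
    cand = (band > bar_top) & (band <= bar_top + config.max_bar_thickness_px)
    if not cand.any():
        return float(bar_top)
    cr, cs = band[cand], band_scores[cand]
    best = cs == cs.max()
    if best.sum() > 1 and previous is not None and np.isfinite(previous):
        chosen = cr[best][np.argmin(np.abs(cr[best] - previous))]
    else:
        chosen = cr[np.argmax(cs)]
    return float(chosen)


def track_cantilever(frames: FrameSequence, config: MeasurementConfig) -> pd.DataFrame:
    """Track the cantilever tip and derive its deflection per frame.

    Returns a frame with columns ``t_s, phase, tip_row, tip_offset_um,
    base_um, deflection_um``; ``deflection_um`` is
    ``|tip motion - commanded base motion|``.  Frames without a
    detectable edge get NaN (with a warning); more than
    ``max_missing_fraction`` missing frames is an error.
    """
    if len(frames) == 0:
        raise InsufficientFramesError("empty frame sequence")
    tip_rows = np.full(len(frames), np.nan)
    prev: float | None = None
    for i, img in enumerate(frames.frames):
        eq = _filter_chain(img)
        tip_rows[i] = _find_tip_row(eq, config, prev)
        if np.isfinite(tip_rows[i]):
            prev = tip_rows[i]
        else:
            warnings.warn(f"no cantilever edge found in frame {i}")
    missing = np.isnan(tip_rows).mean()
    if missing > config.max_missing_fraction:
        raise MeasurementError(
            f"cantilever lost in {missing:.0%} of frames "
            f"(> {config.max_missing_fraction:.0%})")
    ref = tip_rows[np.isfinite(tip_rows)][0]
    tip_offset = (ref - tip_rows) / config.scale  # um, upward positive
    base = frames.base_displacement_um
    deflection = np.abs(tip_offset - base)
    return pd.DataFrame({
        "t_s": frames.timestamps_s,
        "phase": frames.phases,
        "tip_row": tip_rows,
        "tip_offset_um": tip_offset,
        "base_um": base,
        "deflection_um": deflection,
    })


def extract_geometry(frames: FrameSequence, config: MeasurementConfig) -> pd.DataFrame:
    """Segment the cell and measure height/diameter per frame.

    The cell is the largest dark connected component after mean
    filtering and Otsu thresholding (thresholding precedes the
    histogram equalization of the tracking chain: Otsu's criterion is
    not invariant under that rank transform and is more stable on the
    filtered intensities).  Full-width dark rows — the cantilever bar
    and the slide — are excluded; while bar and cell are in contact
    the cell apex hides under the bar's lower edge, so an adjacent
    component top is snapped to it.  Height is the extent along the
    compression (vertical) axis, diameter the maximal transverse
    extent.  The reference ``h0``/``d0`` come from the first frame
    (captured before any compression is applied) and are stored in
    ``result.attrs``.
    """
    if len(frames) == 0:
        raise InsufficientFramesError("empty frame sequence")
    heights = np.full(len(frames), np.nan)
    diameters = np.full(len(frames), np.nan)
    touches = np.zeros(len(frames), dtype=bool)
    for i, img in enumerate(frames.frames):
        filt = uniform_filter(img.astype(float), size=3)
        thr = threshold_otsu(filt)
        dark = filt < thr
        full_width = dark.mean(axis=1) >= 0.9
        mask = dark & ~full_width[:, None]
        lab = label(mask)
        props = regionprops(lab)
        if not props:
            if i == 0:
                raise NoCellError("no cell detected in the reference frame")
            continue
        cell = max(props, key=lambda p: p.area)
        if cell.area < 9:
            if i == 0:
                raise NoCellError("no cell detected in the reference frame")
            continue
        r0, c0, r1, c1 = cell.bbox
        bar_rows = np.flatnonzero(full_width[:r0])
        if len(bar_rows) and r0 - bar_rows[-1] <= 3:
            r0 = bar_rows[-1] + 1  # apex continues under the bar's lower edge
        else:
            r0 -= 1  # 3x3 mean filter erodes the free apex by one pixel
        # same erosion acts on both lateral boundaries
        heights[i] = (r1 - r0) / config.scale
        diameters[i] = (c1 - c0 + 2) / config.scale
        h_img, w_img = img.shape
        touches[i] = r0 == 0 or c0 == 0 or r1 == h_img or c1 == w_img
    out = pd.DataFrame({
        "t_s": frames.timestamps_s,
        "phase": frames.phases,
        "height_um": heights,
        "diameter_um": diameters,
        "touches_border": touches,
    })
    out.attrs["h0_um"] = float(heights[0])
    out.attrs["d0_um"] = float(diameters[0])
    return out


# ---------------------------------------------------------------------------
# mechanics
# ---------------------------------------------------------------------------

def force_from_deflection(deflection_um, spring_constant: float) -> np.ndarray:
    """Hooke's law: F[nN] = k[nN/um] * deflection[um]."""
    if spring_constant <= 0:
        raise ValueError("spring_constant must be positive")
    return spring_constant * np.asarray(deflection_um, dtype=float)


def strain_series(height_um, h0_um: float) -> np.ndarray:
    """Axial strain |h0 - h| / h0 (height change over initial height)."""
    if not h0_um > 0:
        raise ValueError("initial height must be positive")
    return np.abs(h0_um - np.asarray(height_um, dtype=float)) / h0_um


def stress_series(force_nn, diameter_um) -> np.ndarray:
    """Stress (Pa) over the circular contact area of the same frame:
    ``sigma = F / (pi d^2 / 4)`` with nN/um^2 converted to Pa."""
    force = np.asarray(force_nn, dtype=float)
    d = np.asarray(diameter_um, dtype=float)
    area = np.pi * d**2 / 4.0
    return NN_PER_UM2_TO_PA * force / area


@dataclass
class StiffnessFit:
    """Origin-constrained stress-strain fit for one phase."""

    e_pa: float
    r_squared: float
    n_frames: int
    poor_fit: bool


def estimate_stiffness(stress_pa, strain, config: MeasurementConfig | None = None) -> StiffnessFit:
    """Elastic modulus as the linear stress-strain slope of one phase.

    Only strains inside ``(0, strain_window]`` enter the fit.  By
    default the regression carries a free intercept: the slope is the
    modulus while the intercept absorbs any constant stress offset
    (for image-tracked forces, the pixel quantization of the
    deflection reference otherwise leaks into the slope).  Setting
    ``fit_intercept=False`` constrains the line through the origin;
    ``single_point_stiffness`` instead returns the stress/strain ratio
    at the largest strain in the window.  Fits with R^2 below
    ``r2_threshold`` are flagged ``poor_fit``.
    """
    config = config or MeasurementConfig()
    sigma = np.asarray(stress_pa, dtype=float)
    eps = np.asarray(strain, dtype=float)
    ok = np.isfinite(sigma) & np.isfinite(eps) & (eps > 0) & (eps <= config.strain_window)
    if not ok.any():
        if np.all(eps[np.isfinite(eps)] == 0):
            raise MeasurementError("no deformation measured (all strains zero)")
        raise MeasurementError("no usable frames inside the strain window")
    sigma, eps = sigma[ok], eps[ok]
    if len(eps) < config.min_phase_frames:
        raise InsufficientFramesError(
            f"only {len(eps)} frames in the strain window "
            f"(need >= {config.min_phase_frames})")
    if config.single_point_stiffness:
        i = int(np.argmax(eps))
        e = float(sigma[i] / eps[i])
        resid = sigma - e * eps
        ss_tot = float(np.sum(sigma**2))
    elif config.fit_intercept:
        design = np.vstack([eps, np.ones_like(eps)]).T
        (e, intercept), *_ = np.linalg.lstsq(design, sigma, rcond=None)
        e = float(e)
        resid = sigma - (e * eps + intercept)
        ss_tot = float(np.sum((sigma - sigma.mean()) ** 2))
    else:
        e = float(np.sum(sigma * eps) / np.sum(eps**2))
        resid = sigma - e * eps
        ss_tot = float(np.sum(sigma**2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return StiffnessFit(e_pa=e, r_squared=r2, n_frames=len(eps),
                        poor_fit=bool(r2 < config.r2_threshold))


@dataclass
class DetachmentResult:
    af_nn: float
    detachment_index: int | None
    detached: bool


def adhesion_force(force_nn, phases, config: MeasurementConfig | None = None) -> DetachmentResult:
    """Peak tensile force before pull-off.

    Detachment is the first tension-or-later frame whose force has
    dropped by more than ``detachment_drop`` of the running peak and
    stays below ``detachment_floor`` of that peak for the rest of the
    record.  Returns the running peak before that frame as the
    adhesion force; if no such drop exists the record is flagged
    un-detached and the force is invalid (NaN).
    """
    config = config or MeasurementConfig()
    force = np.asarray(force_nn, dtype=float)
    phases = np.asarray(phases)
    idx = np.flatnonzero(phases != "compression")
    if len(idx) == 0:
        return DetachmentResult(float("nan"), None, False)
    f = force[idx]
    finite = np.isfinite(f)
    peak = -np.inf
    for j in range(len(f)):
        if not finite[j]:
            continue
        if f[j] > peak:
            peak = f[j]
            continue
        if peak <= 0:
            continue
        rest = f[j:][finite[j:]]
        if (f[j] < (1.0 - config.detachment_drop) * peak
                and np.all(rest <= config.detachment_floor * peak)):
            return DetachmentResult(float(peak), int(idx[j]), True)
    # an explicit post-detachment label also counts as a pull-off, even
    # when no tensile force built up first (instant release)
    post = np.flatnonzero(phases == "post-detachment")
    if len(post):
        af = float(peak) if peak > 0 else float("nan")
        return DetachmentResult(af, int(post[0]), True)
    return DetachmentResult(float("nan"), None, False)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

@dataclass
class CellMechanics:
    """Per-cell measurement result with QC flags.

    ``cs_pa``/``ts_pa``/``af_nn`` are NaN whenever the corresponding
    validity flag is false.  ``flags`` may contain
    ``early_detachment`` (cell released before enough tensile frames
    were collected; TS and AF excluded), ``no_detachment``,
    ``insufficient_frames`` and ``poor_fit``.
    """

    cs_pa: float = float("nan")
    ts_pa: float = float("nan")
    af_nn: float = float("nan")
    cs_valid: bool = False
    ts_valid: bool = False
    af_valid: bool = False
    flags: set[str] = field(default_factory=set)
    r2_compression: float = float("nan")
    r2_tension: float = float("nan")
    detachment_index: int | None = None
    frames_used: dict = field(default_factory=dict)

    def to_row(self, cell_id: str = "") -> dict:
        return dict(cell_id=cell_id, cs_pa=self.cs_pa, ts_pa=self.ts_pa,
                    af_nn=self.af_nn, cs_valid=self.cs_valid,
                    ts_valid=self.ts_valid, af_valid=self.af_valid,
                    flags=";".join(sorted(self.flags)),
                    r2_c=self.r2_compression, r2_t=self.r2_tension)


def measure_cell(frames: FrameSequence, config: MeasurementConfig | None = None) -> CellMechanics:
    """Run the full measurement chain on one frame sequence.

    Tracks the cantilever, segments the cell, converts deflection to
    force, builds per-phase stress/strain series, fits CS and TS and
    detects the pull-off.  Cells that detach before
    ``min_phase_frames`` tensile frames were recorded are flagged
    ``early_detachment`` and excluded from TS/AF statistics.
    """
    config = config or MeasurementConfig()
    if len(frames) < 2 * config.min_phase_frames:
        raise InsufficientFramesError(
            f"sequence has {len(frames)} frames; need at least "
            f"{2 * config.min_phase_frames}")
    trace = track_cantilever(frames, config)
    geom = extract_geometry(frames, config)
    h0 = geom.attrs["h0_um"]

    force = force_from_deflection(trace.deflection_um.to_numpy(), config.spring_constant)
    strain = strain_series(geom.height_um.to_numpy(), h0)
    stress = stress_series(force, geom.diameter_um.to_numpy())
    phases = np.asarray(frames.phases)

    result = CellMechanics()

    det = adhesion_force(force, phases, config)
    result.detachment_index = det.detachment_index

    comp = phases == "compression"
    tens = phases == "tension"
    if det.detached and det.detachment_index is not None:
        tens &= np.arange(len(phases)) < det.detachment_index

    try:
        fit_c = estimate_stiffness(stress[comp], strain[comp], config)
        result.cs_pa, result.cs_valid = fit_c.e_pa, True
        result.r2_compression = fit_c.r_squared
        result.frames_used["compression"] = fit_c.n_frames
        if fit_c.poor_fit:
            result.flags.add("poor_fit")
    except MeasurementError:
        result.flags.add("insufficient_frames")

    n_tension = int(tens.sum())
    early = det.detached and n_tension < config.min_phase_frames
    if early:
        result.flags.add("early_detachment")
    elif not det.detached:
        result.flags.add("no_detachment")
    else:
        result.af_nn, result.af_valid = det.af_nn, True

    if not early:
        try:
            fit_t = estimate_stiffness(stress[tens], strain[tens], config)
            result.ts_pa, result.ts_valid = fit_t.e_pa, True
            result.r2_tension = fit_t.r_squared
            result.frames_used["tension"] = fit_t.n_frames
            if fit_t.poor_fit:
                result.flags.add("poor_fit")
        except MeasurementError:
            result.flags.add("insufficient_frames")
    return result
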