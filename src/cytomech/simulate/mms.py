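"""Forward model and renderer for microplate compression/tension runs.

The cell and the cantilever form two springs in series.  At commanded
base displacement ``D`` (um) the cell deformation ``dc`` and cantilever
deflection ``db`` satisfy

    D = dc + db          and          k * db = E * (dc / h0) * Ac / 1000,

with ``k`` the spring constant (nN/um), ``E`` the phase modulus (Pa),
``h0`` the initial cell height (um) and ``Ac`` the circular contact
area (um^2); the factor 1000 converts Pa*um^2 to nN.  With ``Ac`` held
constant at ``pi*d0^2/4`` (default) the force is the closed form

    F(D) = D / (1/k + 1000*h0 / (E*Ac)).

The optional volume-conserving mode updates the diameter as
``d = d0*sqrt(h0/h)`` and solves the balance numerically per frame.

Compression pushes the base toward the slide by the commanded
amplitude; tension pulls away until the tensile force reaches the
adhesion force, at which point the cell releases in a single frame:
the cantilever snaps straight (``db = 0``) and the remaining frames
are labeled ``post-detachment``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ..frames import FrameSequence
from .specs import ImagingConfig, MechanicsTruth

TRUTH_COLUMNS = [
    "truth_t_s", "truth_phase", "truth_base_um", "truth_deflection_um",
    "truth_deformation_um", "truth_force_nn", "truth_height_um",
    "truth_diameter_um",
]


def series_spring_force(d_um, modulus_pa: float, truth: MechanicsTruth) -> np.ndarray:
    """Closed-form force (nN) at base displacement ``d_um`` for the
    constant-contact-area series-spring model."""
    compliance = 1.0 / truth.spring_constant + 1000.0 * truth.h0_um / (
        modulus_pa * truth.contact_area_um2)
    return np.asarray(d_um, dtype=float) / compliance


def _solve_deformation(d_um: float, modulus_pa: float, truth: MechanicsTruth,
                       area_policy: str, tension: bool) -> float:
    """Cell deformation dc (um) at base displacement d_um."""
    if d_um <= 0:
        return 0.0
    k, h0 = truth.spring_constant, truth.h0_um
    ac0 = truth.contact_area_um2
    if area_policy == "constant":
        force = series_spring_force(d_um, modulus_pa, truth)
        return float(force) * 1000.0 * h0 / (modulus_pa * ac0)
    sign = 1.0 if tension else -1.0  # height change direction

    def balance(dc: float) -> float:
        h = h0 + sign * dc
        ac = ac0 * h0 / h  # volume-conserving: d = d0*sqrt(h0/h)
        force = modulus_pa * (dc / h0) * ac / 1000.0
        return dc + force / k - d_um

    upper = d_um if tension else min(d_um, 0.999 * h0)
    return float(brentq(balance, 0.0, upper, xtol=1e-12))


def _render_frame(height_um: float, diameter_um: float, tip_z_um: float,
                  imaging: ImagingConfig, rng: np.random.Generator | None) -> np.ndarray:
    """Render one frame: slide band at the bottom, elliptical cell on
    the slide, cantilever bar whose lower edge tracks the tip."""
    h_px, w_px = imaging.image_height, imaging.image_width
    img = np.full((h_px, w_px), float(imaging.background_level))
    r_s = imaging.slide_surface_row

    # cell: ellipse centered mid-height on the slide surface
    ry = max(height_um * imaging.scale / 2.0, 0.5)
    rx = max(diameter_um * imaging.scale / 2.0, 0.5)
    cy = r_s - height_um * imaging.scale / 2.0
    cx = (w_px - 1) / 2.0
    rows = np.arange(h_px)[:, None]
    cols = np.arange(w_px)[None, :]
    mask = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
    img[mask] = imaging.cell_level

    img[r_s:, :] = imaging.slide_level

    lower = r_s - int(round(tip_z_um * imaging.scale))
    upper = lower - imaging.cantilever_thickness_px + 1
    if upper < 0:
        raise ValueError("cantilever travels above the image; enlarge image_height")
    img[max(upper, 0):lower + 1, :] = imaging.cantilever_level

    if imaging.blur_sigma_px > 0:
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, imaging.blur_sigma_px)
    if rng is not None and imaging.noise_sd > 0:
        img = img + rng.normal(0.0, imaging.noise_sd, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_mms_sequence(truth: MechanicsTruth, imaging: ImagingConfig,
                          area_policy: str = "constant",
                          max_tension_travel_um: float = 30.0,
                          post_detachment_frames: int = 10,
                          ) -> tuple[FrameSequence, pd.DataFrame]:
    """Simulate one compression/tension run and render its frames.

    Returns the rendered :class:`~cytomech.frames.FrameSequence` and a
    per-frame ground-truth table (``truth_`` columns: signed base
    displacement, cantilever deflection, cell deformation, force,
    height, diameter).

    Raises
    ------
    ValueError
        If the cell or cantilever would leave the image at any frame,
        or if the configuration is non-physical (tensile pull-off
        reached while still compressing).
    """
    if area_policy not in ("constant", "volume"):
        raise ValueError("area_policy must be 'constant' or 'volume'")
    dt = imaging.frame_interval_s
    step = truth.piezo_speed_um_s * dt
    rng = np.random.default_rng(imaging.seed) if imaging.noise_sd > 0 else None

    # commanded compression ramp: 0 ... amplitude (final frame exactly there)
    n_steps = int(math.floor(truth.piezo_amplitude_um / step + 1e-9))
    comp_d = [i * step for i in range(n_steps + 1)]
    if comp_d[-1] < truth.piezo_amplitude_um - 1e-9:
        comp_d.append(truth.piezo_amplitude_um)

    records: list[dict] = []
    phases: list[str] = []

    def push(phase: str, base_signed: float, dc: float, db: float,
             force: float, height: float, diameter: float) -> None:
        t = (len(records)) * dt
        records.append(dict(truth_t_s=t, truth_phase=phase, truth_base_um=base_signed,
                            truth_deflection_um=db, truth_deformation_um=dc,
                            truth_force_nn=force, truth_height_um=height,
                            truth_diameter_um=diameter))
        phases.append(phase)

    def diameter_at(height: float) -> float:
        if area_policy == "volume":
            return truth.d0_um * math.sqrt(truth.h0_um / height)
        return truth.d0_um

    # --- compression -------------------------------------------------
    for d in comp_d:
        dc = _solve_deformation(d, truth.compressive_modulus_pa, truth,
                                area_policy, tension=False)
        db = d - dc
        force = truth.spring_constant * db
        if force < 0 and abs(force) >= truth.adhesion_force_nn > 0:
            raise ValueError("non-physical configuration: adhesion force "
                             "reached during compression")
        h = truth.h0_um - dc
        push("compression", -d, dc, db, force, h, diameter_at(h))

    # --- tension until pull-off --------------------------------------
    detached = False
    d = 0.0
    while not detached:
        d += step
        if d > max_tension_travel_um:
            break  # no detachment within the allowed travel
        dc = _solve_deformation(d, truth.tensile_modulus_pa, truth,
                                area_policy, tension=True)
        db = d - dc
        force = truth.spring_constant * db
        if force >= truth.adhesion_force_nn:
            detached = True
            break
        h = truth.h0_um + dc
        push("tension", d, dc, db, force, h, diameter_at(h))

    if detached:
        # cell releases: cantilever snaps straight, cell relaxes on the slide
        for _ in range(post_detachment_frames):
            push("post-detachment", d, 0.0, 0.0, 0.0, truth.h0_um, truth.d0_um)

    table = pd.DataFrame.from_records(records, columns=TRUTH_COLUMNS)

    # image capacity check before rendering
    tip_max = (table.truth_base_um.clip(lower=0.0)
               - table.truth_deflection_um * (table.truth_phase == "tension")
               + truth.h0_um).max()
    needed = (imaging.slide_band_px + tip_max * imaging.scale
              + imaging.cantilever_thickness_px + 2)
    if needed > imaging.image_height:
        raise ValueError(
            f"cell plus cantilever exceed the image at maximum travel "
            f"(need >= {int(math.ceil(needed))} rows, have {imaging.image_height})")

    frames = np.empty((len(table), imaging.image_height, imaging.image_width),
                      dtype=np.uint8)
    for i, rec in enumerate(table.itertuples()):
        tip = rec.truth_height_um if rec.truth_phase != "post-detachment" \
            else truth.h0_um + rec.truth_base_um
        frames[i] = _render_frame(rec.truth_height_um, rec.truth_diameter_um,
                                  tip, imaging, rng)

    seq = FrameSequence(
        frames=frames,
        timestamps_s=table.truth_t_s.to_numpy(),
        phases=list(table.truth_phase),
        base_displacement_um=table.truth_base_um.to_numpy(),
        scale=imaging.scale,
        spring_constant=truth.spring_constant,
        metadata={
            "slide_surface_row": imaging.slide_surface_row,
            "area_policy": area_policy,
            "piezo_amplitude_um": truth.piezo_amplitude_um,
            "piezo_speed_um_s": truth.piezo_speed_um_s,
        },
    )
    return seq, table
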