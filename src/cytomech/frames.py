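"""Image-sequence container for microplate (cantilever-on-cell) recordings.

A :class:`FrameSequence` holds the time-ordered frames of one cell
squeezed between a glass slide (bottom of the image) and a flexible
cantilever (dark horizontal bar), together with the commanded piezo
base trajectory needed to convert tracked tip positions into
deflections.

Coordinate conventions
----------------------
* image origin top-left, row index increases downward, 0-based pixels;
* the compression axis is the image vertical axis;
* physical height ``z`` (um) is measured upward from the slide surface,
  so the pixel row of a feature at height ``z`` is
  ``slide_surface_row - round(z * scale)``;
* the commanded base displacement is signed: negative values move the
  cantilever base toward the slide (compression), positive values away
  (tension).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Valid phase labels, in protocol order.
PHASES = ("compression", "tension", "post-detachment")


@dataclass
class FrameSequence:
    """Time-stamped intensity frames with phase labels and piezo trajectory.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``, uint8 intensities.
    timestamps_s
        Strictly increasing acquisition times, seconds.
    phases
        Per-frame label from :data:`PHASES`; labels may change at most
        twice and only in protocol order.
    base_displacement_um
        Signed commanded piezo base displacement per frame (um),
        relative to the position at the first frame.
    scale
        Optical calibration, pixels per um.
    spring_constant
        Cantilever spring constant, nN/um.
    metadata
        Free-form extras (e.g. the slide surface row used at render
        time, truth-table provenance).
    """

    frames: np.ndarray
    timestamps_s: np.ndarray
    phases: list[str]
    base_displacement_um: np.ndarray
    scale: float
    spring_constant: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.base_displacement_um = np.asarray(self.base_displacement_um, dtype=float)
        self.phases = list(self.phases)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        n = len(self.frames)
        if not (len(self.timestamps_s) == len(self.phases) == len(self.base_displacement_um) == n):
            raise ValueError("timestamps, phases and base trajectory must match frame count")
        if n and np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels: {sorted(unknown)}")
        self._check_phase_order()

    def _check_phase_order(self) -> None:
        order = {p: i for i, p in enumerate(PHASES)}
        idx = [order[p] for p in self.phases]
        changes = sum(1 for a, b in zip(idx, idx[1:]) if a != b)
        if changes > 2:
            raise ValueError("phase labels may change at most twice")
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("phase labels must follow protocol order")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def phase_indices(self, phase: str) -> np.ndarray:
        """Frame indices carrying the given phase label."""
        return np.flatnonzero(np.asarray(self.phases) == phase)
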