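"""Reading and writing the pipeline's on-disk formats.

Frame sequences travel as multi-page TIFF stacks with a JSON sidecar
(timestamps, phase labels, commanded piezo trajectory, calibration,
spring constant); tables are UTF-8 CSV with a header row and ``.``
decimal separator; force-volume maps are long-format CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .afm import ForceCurve
from .frames import FrameSequence

SIDECAR_SUFFIX = ".json"


def write_frame_sequence(seq: FrameSequence, tiff_path: str | Path,
                         sidecar_path: str | Path | None = None) -> Path:
    """Write frames as a multi-page TIFF plus a JSON sidecar."""
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(SIDECAR_SUFFIX)
    tifffile.imwrite(tiff_path, seq.frames)
    sidecar = {
        "timestamps_s": seq.timestamps_s.tolist(),
        "phases": list(seq.phases),
        "base_displacement_um": seq.base_displacement_um.tolist(),
        "scale_px_per_um": seq.scale,
        "spring_constant_nn_per_um": seq.spring_constant,
        "metadata": _jsonable(seq.metadata),
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))
    return tiff_path


def read_frame_sequence(tiff_path: str | Path,
                        sidecar_path: str | Path | None = None) -> FrameSequence:
    """Read a frame sequence written by :func:`write_frame_sequence`."""
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(SIDECAR_SUFFIX)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = json.loads(Path(sidecar_path).read_text())
    return FrameSequence(
        frames=frames,
        timestamps_s=np.asarray(sidecar["timestamps_s"]),
        phases=sidecar["phases"],
        base_displacement_um=np.asarray(sidecar["base_displacement_um"]),
        scale=sidecar["scale_px_per_um"],
        spring_constant=sidecar["spring_constant_nn_per_um"],
        metadata=sidecar.get("metadata", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def curves_to_csv(curves: dict[tuple[int, int], ForceCurve], path: str | Path,
                  map_id: str = "map0") -> Path:
    """Write a force-volume curve grid as long-format CSV."""
    parts = []
    for (r, c), curve in sorted(curves.items()):
        parts.append(pd.DataFrame({
            "map_id": map_id, "row": r, "col": c,
            "z_um": curve.z_um, "f_nn": curve.f_nn, "segment": curve.segment,
        }))
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def curves_from_csv(path: str | Path,
                    map_id: str | None = None) -> dict[tuple[int, int], ForceCurve]:
    """Read a long-format force-volume CSV into a curve grid."""
    df = pd.read_csv(path)
    if map_id is not None:
        df = df[df.map_id == map_id]
    curves = {}
    for (r, c), sub in df.groupby(["row", "col"]):
        sub = sub.sort_values("z_um")
        seg = sub.segment.iloc[0] if "segment" in sub else "approach"
        curves[(int(r), int(c))] = ForceCurve(
            z_um=sub.z_um.to_numpy(), f_nn=sub.f_nn.to_numpy(), segment=seg)
    return curves


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) configuration file into a dict."""
    text = Path(path).read_text()
    return yaml.safe_load(text)
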