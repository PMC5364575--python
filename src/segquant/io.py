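"""File I/O: images, label masks, centroid tables and configs."""

from __future__ import annotations

import tomllib
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from imageio import v3 as iio

from .errors import ParameterError
from .pipeline import PipelineConfig
from .quantify import QuantificationResult
from .sdd import ThresholdRequest
from .union_seg import UnionCase

#: Centroid CSV column order; coordinates are 0-based (row, col).
CENTROID_COLUMNS = ["cell_id", "row", "col", "seed_area", "iteration"]


def read_image(path: str | Path, to_gray: str | None = None) -> np.ndarray:
    """Read a single-channel image.

    Multi-channel input is refused unless ``to_gray='luminance'`` is
    passed, in which case the ITU-R 601 luminance is taken.
    """
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        if to_gray != "luminance":
            raise ParameterError(
                f"{path} has {arr.shape[2]} channels; pass to_gray='luminance' "
                "to convert"
            )
        rgb = arr[..., :3].astype(float)
        return rgb @ np.array([0.299, 0.587, 0.114])
    raise ParameterError(f"unsupported image shape {arr.shape} in {path}")


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit image (0/255)."""
    out = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), out)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label mask as 16-bit TIFF."""
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)), dtype=np.int32)


def centroids_frame(result: QuantificationResult) -> pd.DataFrame:
    """Centroid table with seed areas and extraction iterations."""
    labels = result.seeds.labels
    rows = []
    for cell_id, (r, c) in zip(sorted(result.seeds.iteration_of), result.centroids):
        rows.append(
            {
                "cell_id": cell_id,
                "row": r,
                "col": c,
                "seed_area": int((labels == cell_id).sum()),
                "iteration": result.seeds.iteration_of[cell_id],
            }
        )
    return pd.DataFrame(rows, columns=CENTROID_COLUMNS)


def write_centroids(path: str | Path, result: QuantificationResult) -> None:
    centroids_frame(result).to_csv(Path(path), index=False)


def read_centroids(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def config_to_toml(config: PipelineConfig) -> str:
    """Serialize a pipeline config to TOML text."""
    d = asdict(config)
    lines = []
    for section in ("intensity", "gradient", "union_case"):
        sub = d.pop(section)
        lines.append(f"[{section}]")
        for k, v in sub.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    lines.append("[pipeline]")
    for k, v in d.items():
        if v is None:
            continue
        lines.append(f"{k} = {_toml_value(v)}")
    return "\n".join(lines) + "\n"


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    return str(v)


def write_config(path: str | Path, config: PipelineConfig) -> None:
    Path(path).write_text(config_to_toml(config))


def read_config(path: str | Path) -> PipelineConfig:
    data = tomllib.loads(Path(path).read_text())
    intensity = ThresholdRequest(**data.get("intensity", {}))
    gradient = ThresholdRequest(**data.get("gradient", {}))
    union_case = UnionCase(**data.get("union_case", {}))
    return PipelineConfig(
        intensity=intensity,
        gradient=gradient,
        union_case=union_case,
        **data.get("pipeline", {}),
    )
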