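"""File I/O: multichannel TIFF stacks, trace/result CSVs, run configuration.

CSV is the sole tabular interchange format (header row, UTF-8, '.' decimal).
Result CSVs written by the pipeline carry a comment line recording the tool
version and seed, so every output is traceable to its run.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import FormatError, ImageStack, IntensityTrace, ParameterError

__all__ = [
    "RunConfig",
    "read_image_stack",
    "write_image_stack",
    "read_traces_csv",
    "write_traces_csv",
    "write_result_csv",
    "load_config",
]

TRACE_COLUMNS = ["time_s", "intensity", "roi", "is_post_bleach"]


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as a multichannel TIFF.

    Channel order is preserved as stored (simulator order: membrane, DNA,
    fusion); channel names and pixel size travel in the TIFF metadata.
    """
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(stack.data),
        metadata={
            "channel_names": list(stack.channel_names),
            "pixel_size_nm": stack.pixel_size_nm,
        },
    )
    return path


def read_image_stack(path: str | Path, pixel_size_nm: float | None = None) -> ImageStack:
    """Read a 2-D or multichannel TIFF into an :class:`ImageStack`.

    Channel names and pixel size are taken from the file's metadata when
    present; ``pixel_size_nm`` overrides/supplies the pixel size otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta: dict[str, Any] = {}
            if tif.shaped_metadata:
                meta = dict(tif.shaped_metadata[0])
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2-D or (channels, rows, cols) data, got ndim={data.ndim}")
    names = meta.get("channel_names") or [f"ch{i}" for i in range(data.shape[0])]
    px = meta.get("pixel_size_nm") or pixel_size_nm
    if px is None:
        raise FormatError(f"{path} has no pixel size metadata; pass pixel_size_nm")
    return ImageStack(data, tuple(names), float(px))


def write_traces_csv(traces: list[IntensityTrace], path: str | Path) -> Path:
    """Write intensity traces as CSV (time_s, intensity, roi, is_post_bleach)."""
    rows = []
    for tr in traces:
        for i in range(len(tr)):
            rows.append({
                "time_s": tr.times_s[i],
                "intensity": tr.intensities[i],
                "roi": tr.roi_id,
                "is_post_bleach": i >= tr.bleach_index,
            })
    path = Path(path)
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)
    return path


def read_traces_csv(path: str | Path) -> list[IntensityTrace]:
    """Read traces written by :func:`write_traces_csv`, grouped by ROI."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing trace columns {missing}")
    traces = []
    for roi, grp in df.groupby("roi", sort=False):
        grp = grp.sort_values("time_s")
        post = np.asarray(grp["is_post_bleach"], dtype=bool)
        if not post.any() or post.all():
            raise FormatError(f"{path}: roi {roi!r} lacks a bleach event")
        traces.append(IntensityTrace(
            np.asarray(grp["time_s"], dtype=float),
            np.asarray(grp["intensity"], dtype=float),
            bleach_index=int(np.argmax(post)),
            roi_id=str(roi),
        ))
    return traces


def write_result_csv(df: pd.DataFrame, path: str | Path, *,
                     seed: int | None = None) -> Path:
    """Write a result table with a provenance comment header."""
    from . import __version__

    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# sporoquant {__version__} seed={seed}\n")
        df.to_csv(fh, index=False)
    return path


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    ``stages`` is an ordered list of ``{"stage": name, ...params}`` mappings;
    unknown top-level keys are rejected so typos fail loudly.
    """

    seed: int = 0
    output_dir: Path = Path("sporoquant_out")
    verbosity: int = 1
    stages: list[dict[str, Any]] = field(default_factory=list)

    _TOP_KEYS = frozenset({"seed", "output_dir", "verbosity", "stages"})

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - cls._TOP_KEYS
        if unknown:
            raise ParameterError(f"unknown configuration keys: {sorted(unknown)}")
        stages = raw.get("stages", [])
        if not isinstance(stages, list) or not all(
            isinstance(s, dict) and "stage" in s for s in stages
        ):
            raise ParameterError("stages must be a list of mappings with a 'stage' key")
        return cls(
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "sporoquant_out")),
            verbosity=int(raw.get("verbosity", 1)),
            stages=stages,
        )

    def to_mapping(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "verbosity": self.verbosity,
            "stages": self.stages,
        }

    def dump(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_mapping(), sort_keys=False))
        return path


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown top-level keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: configuration must be a mapping")
    return RunConfig.from_mapping(raw)
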