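"""Core in-memory containers shared across the simulation and analysis stages.

Conventions: pixel coordinates are 0-based ``(row, col)``; physical distances
are µm unless a field name says otherwise (``pixel_size_nm``); times are
seconds; intensities are arbitrary camera units (a.u.).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ImageStack",
    "IntensityTrace",
    "SporeRecord",
    "GroundTruth",
    "SporoquantError",
    "SizingError",
    "FormatError",
    "ParameterError",
]


class SporoquantError(Exception):
    """Base class for errors raised by this package."""


class SizingError(SporoquantError):
    """An image is too small to contain the requested scene."""


class FormatError(SporoquantError):
    """A file does not match the expected on-disk layout."""


class ParameterError(SporoquantError):
    """An invalid parameter value was supplied."""


@dataclass
class ImageStack:
    """A multichannel 2-D image with physical pixel size.

    ``data`` has shape ``(n_channels, n_rows, n_cols)`` and ``channel_names``
    has one entry per channel (fixed simulator order: membrane, DNA, fusion).
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3:
            raise FormatError(
                f"image stack must be 2-D or (channels, rows, cols); got ndim={self.data.ndim}"
            )
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if not self.pixel_size_nm > 0:
            raise ParameterError("pixel_size_nm must be > 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D plane for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.data[idx]


@dataclass
class IntensityTrace:
    """A timestamped ROI intensity series with a recorded bleach event.

    ``bleach_index`` is the index of the first post-bleach frame; frames
    ``[0, bleach_index)`` are pre-bleach.
    """

    times_s: np.ndarray
    intensities: np.ndarray
    bleach_index: int
    roi_id: str = "roi"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape or self.times_s.ndim != 1:
            raise ParameterError("times and intensities must be matching 1-D arrays")
        if len(self.times_s) >= 2 and not np.all(np.diff(self.times_s) > 0):
            raise ParameterError("times must be strictly increasing")
        if not (0 < self.bleach_index < len(self.times_s)):
            raise ParameterError(
                f"bleach_index {self.bleach_index} outside (0, {len(self.times_s)})"
            )

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def pre(self) -> np.ndarray:
        return self.intensities[: self.bleach_index]

    @property
    def post(self) -> np.ndarray:
        return self.intensities[self.bleach_index :]


@dataclass
class SporeRecord:
    """Simulator ground truth for one rendered spore."""

    spore_id: int
    mask: np.ndarray  # boolean, full image shape
    length_um: float
    nucleoid_mode: str  # "condensed" | "toroid"
    centroid_px: tuple[float, float]


@dataclass
class GroundTruth:
    """Everything the simulator knows about a rendered scene.

    ``foci_axial_um`` maps channel id -> sorted positions along the hypha
    axis; ``foci_px`` maps channel id -> (n, 2) array of (row, col).
    """

    seed: int
    spores: list[SporeRecord] = field(default_factory=list)
    foci_axial_um: dict[str, np.ndarray] = field(default_factory=dict)
    foci_px: dict[str, np.ndarray] = field(default_factory=dict)
    kinetics: dict[str, Any] = field(default_factory=dict)

    @property
    def n_spores(self) -> int:
        return len(self.spores)

    def spore_lengths_um(self) -> np.ndarray:
        return np.array([s.length_um for s in self.spores])

    def nucleoid_modes(self) -> list[str]:
        return [s.nucleoid_mode for s in self.spores]
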