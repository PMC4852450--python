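"""Detection of fluorescent foci along hyphae, spacing and colocalization.

Foci mark future septum sites; the quantities of interest are the fraction
of hyphae carrying foci (occupancy), the spacing of consecutive foci along
the hypha axis, and the two-channel overlap of foci from co-expressed
fusion proteins.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ParameterError

__all__ = [
    "FocusDetectionParams",
    "FocusSet",
    "SpacingStats",
    "ColocalizationResult",
    "detect_foci",
    "foci_spacing_stats",
    "colocalization_overlap",
]


@dataclass(frozen=True)
class FocusDetectionParams:
    """Settings for :func:`detect_foci`.

    A candidate peak must exceed the image background by
    ``k_sigma`` x (robust background noise sd) and by the absolute
    ``min_prominence`` (a.u.), whichever is larger; the prominence floor
    keeps dim extended structures (the hypha tube itself) out of the focus
    list in low-noise images.
    """

    smooth_sigma_px: float = 1.2
    k_sigma: float = 3.0
    min_prominence: float = 80.0
    min_distance_px: int = 3

    def __post_init__(self) -> None:
        if self.smooth_sigma_px < 0 or self.k_sigma < 0 or self.min_prominence < 0:
            raise ParameterError("detection thresholds must be >= 0")
        if self.min_distance_px < 1:
            raise ParameterError("min_distance_px must be >= 1")


@dataclass
class FocusSet:
    """Detected (or ground-truth) foci of one channel on one hypha.

    ``positions_px`` is (n, 2) sub-pixel (row, col); ``axial_um`` are the
    projections onto the hypha axis, sorted ascending; ``peak_intensity``
    follows the same order.
    """

    channel_id: str
    positions_px: np.ndarray
    axial_um: np.ndarray
    peak_intensity: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.positions_px = np.asarray(self.positions_px, dtype=float).reshape(-1, 2)
        self.axial_um = np.asarray(self.axial_um, dtype=float)
        self.peak_intensity = np.asarray(self.peak_intensity, dtype=float)
        if len(self.axial_um) > 1 and np.any(np.diff(self.axial_um) < 0):
            order = np.argsort(self.axial_um)
            self.positions_px = self.positions_px[order]
            self.axial_um = self.axial_um[order]
            self.peak_intensity = self.peak_intensity[order]

    @property
    def n(self) -> int:
        return len(self.axial_um)


@dataclass(frozen=True)
class SpacingStats:
    """Inter-focus spacing and per-hypha occupancy summary.

    ``mean_um``/``sem_um`` are NaN when no hypha contributed two foci
    (spacing undefined).
    """

    mean_um: float
    sem_um: float
    n_gaps: int
    occupancy_percent: float
    n_hyphae: int


@dataclass(frozen=True)
class ColocalizationResult:
    """Greedy one-to-one focus matching between two channels.

    ``percent_a`` is matched / |A| x 100 (NaN when A is empty), and
    symmetrically for ``percent_b``; the A denominator is the headline
    number, with both reported because the convention is ambiguous.
    """

    percent_a: float
    percent_b: float
    n_matched: int
    n_a: int
    n_b: int
    tolerance_nm: float


def _subpixel_offset(values: np.ndarray) -> float:
    """Quadratic-interpolation offset of a 3-sample peak, clipped to +/-0.5."""
    denom = values[0] - 2 * values[1] + values[2]
    if denom >= 0:  # not a strict local max along this axis
        return 0.0
    return float(np.clip(0.5 * (values[0] - values[2]) / denom, -0.5, 0.5))


def _principal_axis(weights: np.ndarray) -> np.ndarray:
    """Intensity-weighted principal axis (unit row, col vector) of a plane."""
    total = weights.sum()
    rows, cols = np.mgrid[0 : weights.shape[0], 0 : weights.shape[1]].astype(float)
    if total <= 0:
        return np.array([0.0, 1.0])
    mr = float((rows * weights).sum() / total)
    mc = float((cols * weights).sum() / total)
    crr = float(((rows - mr) ** 2 * weights).sum() / total)
    ccc = float(((cols - mc) ** 2 * weights).sum() / total)
    crc = float(((rows - mr) * (cols - mc) * weights).sum() / total)
    _, vecs = np.linalg.eigh(np.array([[crr, crc], [crc, ccc]]))
    return vecs[:, -1]


def detect_foci(plane: np.ndarray, pixel_size_nm: float,
                params: FocusDetectionParams | None = None,
                channel_id: str = "fusion") -> FocusSet:
    """Detect diffraction-limited foci in a single 2-D plane.

    Peaks are local maxima of the Gaussian-smoothed plane above
    background + max(k_sigma * noise_sd, min_prominence); background is the
    plane median and noise_sd its median absolute deviation (scaled).
    Positions are refined to sub-pixel precision by per-axis quadratic
    interpolation; axial positions come from projecting onto the
    intensity-weighted principal axis of the plane.
    """
    params = params or FocusDetectionParams()
    if not pixel_size_nm > 0:
        raise ParameterError("pixel_size_nm must be > 0")
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ParameterError("detect_foci expects a single 2-D plane")

    empty = FocusSet(channel_id, np.empty((0, 2)), np.empty(0), np.empty(0), pixel_size_nm)
    if np.ptp(plane) == 0:
        return empty

    sm = ndimage.gaussian_filter(plane, params.smooth_sigma_px) if params.smooth_sigma_px > 0 else plane
    background = float(np.median(sm))
    noise_sd = 1.4826 * float(np.median(np.abs(sm - background)))
    threshold = background + max(params.k_sigma * noise_sd, params.min_prominence)

    size = 2 * params.min_distance_px + 1
    local_max = (sm == ndimage.maximum_filter(sm, size=size)) & (sm > threshold)
    # collapse plateau ties (e.g. a peak exactly between two pixels) to one
    # representative per connected component
    comp, n_comp = ndimage.label(local_max, structure=np.ones((3, 3)))
    if n_comp == 0:
        return empty
    peak_rc = np.rint(
        ndimage.center_of_mass(local_max, comp, np.arange(1, n_comp + 1))
    ).astype(int)

    positions = []
    intensities = []
    for r, c in peak_rc:
        dr = dc = 0.0
        if 0 < r < sm.shape[0] - 1:
            dr = _subpixel_offset(sm[r - 1 : r + 2, c])
        if 0 < c < sm.shape[1] - 1:
            dc = _subpixel_offset(sm[r, c - 1 : c + 2])
        positions.append((r + dr, c + dc))
        intensities.append(sm[r, c])
    positions = np.array(positions)

    axis = _principal_axis(np.clip(sm - background, 0.0, None))
    axial_um = positions @ axis * (pixel_size_nm / 1000.0)
    return FocusSet(channel_id, positions, axial_um, np.array(intensities), pixel_size_nm)


def foci_spacing_stats(foci_per_hypha: list[FocusSet]) -> SpacingStats:
    """Spacing and occupancy over a collection of hyphae.

    Gaps are consecutive differences of sorted axial positions within each
    hypha; the mean and SEM pool all gaps.  Occupancy is the percentage of
    hyphae with at least one focus.
    """
    if not foci_per_hypha:
        raise ParameterError("foci_spacing_stats needs at least one hypha")
    gaps = np.concatenate(
        [np.diff(f.axial_um) for f in foci_per_hypha if f.n >= 2]
        or [np.empty(0)]
    )
    occupancy = 100.0 * sum(1 for f in foci_per_hypha if f.n >= 1) / len(foci_per_hypha)
    if len(gaps) == 0:
        return SpacingStats(math.nan, math.nan, 0, occupancy, len(foci_per_hypha))
    sem = float(np.std(gaps, ddof=1) / np.sqrt(len(gaps))) if len(gaps) > 1 else 0.0
    return SpacingStats(float(gaps.mean()), sem, len(gaps), occupancy, len(foci_per_hypha))


def colocalization_overlap(a: FocusSet, b: FocusSet,
                           tolerance_nm: float = 200.0) -> ColocalizationResult:
    """Greedy nearest-neighbour focus matching within a distance tolerance.

    Candidate pairs are ranked by distance; each focus is used at most once;
    only pairs closer than ``tolerance_nm`` match.
    """
    if tolerance_nm < 0:
        raise ParameterError("tolerance_nm must be >= 0")
    if a.pixel_size_nm != b.pixel_size_nm:
        raise ParameterError("focus sets must share a pixel size")
    n_matched = 0
    if a.n and b.n:
        diff = a.positions_px[:, None, :] - b.positions_px[None, :, :]
        dist_nm = np.hypot(diff[..., 0], diff[..., 1]) * a.pixel_size_nm
        order = np.argsort(dist_nm, axis=None)
        used_a = np.zeros(a.n, dtype=bool)
        used_b = np.zeros(b.n, dtype=bool)
        for flat in order:
            i, j = divmod(int(flat), b.n)
            if dist_nm[i, j] > tolerance_nm:
                break
            if used_a[i] or used_b[j]:
                continue
            used_a[i] = used_b[j] = True
            n_matched += 1
    percent_a = 100.0 * n_matched / a.n if a.n else math.nan
    percent_b = 100.0 * n_matched / b.n if b.n else math.nan
    return ColocalizationResult(percent_a, percent_b, n_matched, a.n, b.n, tolerance_nm)
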