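"""Synthetic epifluorescence imaging of sporulating *Streptomyces* hyphae.

Every generator in this module is seeded and returns, next to the rendered
pixels, the complete ground truth it used, so that each downstream analysis
stage (segmentation, profiling, spot detection, kinetics fitting) can be
verified by parameter recovery rather than against deposited raw images.

The imaging model is a single-plane widefield camera: scene photons are
rendered in continuous intensity units, convolved with a Gaussian
approximation of the point-spread function, offset by a flat background,
then passed through Poisson shot noise and additive Gaussian read noise.

Scene geometry:

* spore chains — 2-D capsules (rectangle plus semicircular caps) laid out
  along a common axis, each with a membrane envelope (bright ring centred on
  the capsule boundary over a dim cytoplasmic plateau) and one nucleoid,
  rendered either as a condensed Gaussian blob or as a toroid (annulus in
  projection, so the central intensity deficit emerges from the ring
  geometry);
* hyphae carrying fluorescent-fusion foci — a dim tube with Gaussian spots
  placed sequentially with truncated-Gaussian gaps;
* photobleaching series — donor-intensity frame sequences around an
  acceptor bleach (FRET mode) and bleached/reference ROI pairs following a
  single-exponential recovery under continuous imaging bleach (FRAP mode).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import (
    GroundTruth,
    ImageStack,
    IntensityTrace,
    ParameterError,
    SizingError,
    SporeRecord,
)

__all__ = [
    "ImagingConfig",
    "NucleoidModel",
    "SporeChainSpec",
    "FociFieldSpec",
    "PhotobleachSpec",
    "simulate_spore_chain",
    "simulate_foci_hypha",
    "simulate_fretap_series",
    "simulate_frap_series",
    "draw_spore_lengths",
]

# Rendering amplitudes (a.u., before PSF blur).  The source images' dynamic
# range is not constrained by any measurement, so these are free package
# defaults chosen to give a realistic signal-to-background ratio (~2-7x)
# under the default camera noise.
MEMBRANE_RIM_AMPLITUDE = 1200.0
MEMBRANE_BODY_AMPLITUDE = 60.0
DNA_AMPLITUDE = 800.0
HYPHA_TUBE_AMPLITUDE = 40.0

#: Physical pixel pitch of the emulated camera (nm / pixel).
DEFAULT_PIXEL_SIZE_NM = 37.5


@dataclass(frozen=True)
class ImagingConfig:
    """Camera and optics parameters for all image-producing simulators.

    psf_sigma_nm approximates the widefield PSF of a 1.4 NA objective at
    green emission (sigma ~ 0.21 lambda / NA ~ 80 nm).
    """

    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    psf_sigma_nm: float = 80.0
    background_level: float = 100.0
    shot_noise: bool = True
    shot_gain: float = 1.0  # photons per a.u. for the Poisson stage
    read_noise_sd: float = 2.0
    image_shape_px: tuple[int, int] | None = None  # None -> sized to fit the scene

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ParameterError("pixel_size_nm must be > 0")
        if self.psf_sigma_nm < 0 or self.background_level < 0:
            raise ParameterError("psf_sigma_nm and background_level must be >= 0")
        if self.read_noise_sd < 0 or self.shot_gain <= 0:
            raise ParameterError("read_noise_sd must be >= 0 and shot_gain > 0")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    def noise_free(self) -> "ImagingConfig":
        """A copy of this config with all camera noise switched off."""
        return replace(self, shot_noise=False, read_noise_sd=0.0)


@dataclass(frozen=True)
class NucleoidModel:
    """Shape model for one spore's nucleoid.

    ``condensed`` renders an isotropic Gaussian blob at the spore centre;
    ``toroid`` renders an annulus of radius ``toroid_radius_um`` and radial
    thickness ``toroid_sigma_um`` in single-plane projection.  The central
    intensity deficit of a toroid is implied by the geometry, not painted.
    """

    mode: str = "condensed"
    condensed_sigma_um: float = 0.15
    toroid_radius_um: float = 0.22
    toroid_sigma_um: float = 0.08

    def __post_init__(self) -> None:
        if self.mode not in ("condensed", "toroid"):
            raise ParameterError(f"unknown nucleoid mode {self.mode!r}")
        if min(self.condensed_sigma_um, self.toroid_radius_um, self.toroid_sigma_um) <= 0:
            raise ParameterError("nucleoid shape parameters must be > 0")


@dataclass(frozen=True)
class SporeChainSpec:
    """Population parameters for one simulated spore chain.

    Spore lengths are Gaussian (redrawn when a draw is <= 0); the default
    mean/sd describe the wild-type population (mean 0.96 µm, lengths ranging
    roughly 0.8-1.2 µm).  ``rim_fraction`` is the probability that a spore's
    nucleoid is toroidal when modes are drawn randomly; the wild-type default
    is 0.14.  ``nucleoid_modes`` fixes the per-spore modes explicitly.
    """

    n_spores: int = 10
    length_mean_um: float = 0.96
    length_sd_um: float = 0.10
    diameter_um: float = 0.80
    orientation_deg: float = 0.0
    septum_gap_um: float = 0.35  # free space between consecutive spore envelopes
    rim_fraction: float = 0.14
    nucleoid_modes: tuple[str, ...] | None = None
    nucleoid: NucleoidModel = field(default_factory=NucleoidModel)

    def __post_init__(self) -> None:
        if self.n_spores < 0:
            raise ParameterError("n_spores must be >= 0")
        if self.length_mean_um <= 0 or self.length_sd_um < 0 or self.diameter_um <= 0:
            raise ParameterError("spore length/diameter parameters must be positive")
        if not 0.0 <= self.rim_fraction <= 1.0:
            raise ParameterError("rim_fraction must be in [0, 1]")
        if self.septum_gap_um < 0:
            raise ParameterError("septum_gap_um must be >= 0")
        if self.nucleoid_modes is not None and len(self.nucleoid_modes) != self.n_spores:
            raise ParameterError("nucleoid_modes must list one mode per spore")
        if self.nucleoid.toroid_radius_um >= self.length_mean_um / 2:
            raise ParameterError("toroid radius must be smaller than the spore half-length")


@dataclass(frozen=True)
class FociFieldSpec:
    """Layout of fluorescent-fusion foci along one hypha.

    Defaults describe the wild-type regime: foci in 80% of hyphae at
    1.25 +/- 0.14 µm spacing; ``co_placement_fraction`` duplicates that
    fraction of channel-A foci into channel B within ``co_jitter_nm``.
    """

    hypha_length_um: float = 20.0
    hypha_diameter_um: float = 0.7
    spacing_mean_um: float = 1.25
    spacing_sd_um: float = 0.14
    occupancy: float = 0.80
    focus_amplitude: float = 500.0
    focus_sigma_um: float = 0.10
    co_placement_fraction: float = 0.0
    co_jitter_nm: float = 50.0
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.spacing_mean_um <= 0 or self.hypha_length_um <= 0:
            raise ParameterError("hypha_length_um and spacing_mean_um must be > 0")
        if self.spacing_sd_um < 0 or self.co_jitter_nm < 0:
            raise ParameterError("spread parameters must be >= 0")
        for name in ("occupancy", "co_placement_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.focus_amplitude < 0 or self.focus_sigma_um <= 0:
            raise ParameterError("focus amplitude/size must be positive")


@dataclass(frozen=True)
class PhotobleachSpec:
    """Frame protocol and kinetics for photobleaching series.

    FRET mode uses ``true_ratio`` (donor post/pre intensity ratio; > 1 means
    donor dequenching after acceptor bleach).  FRAP mode uses the recovery
    rate ``recovery_rate_k_per_s``, ``mobile_fraction``, the immediate
    post-bleach level ``bleach_floor`` and an imaging-bleach decay applied to
    bleached and reference ROI alike.  Defaults follow the acquisition
    protocol: 3 usable pre-bleach frames and a 15 s post-bleach follow.
    """

    n_pre_frames: int = 3
    n_post_frames: int = 60
    frame_interval_s: float = 0.25
    noise_sd_rel: float = 0.0
    # FRET mode
    true_ratio: float = 1.0
    # FRAP mode
    recovery_rate_k_per_s: float = math.log(2) / 5.0
    mobile_fraction: float = 1.0
    bleach_floor: float = 0.2
    imaging_bleach_rate_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pre_frames < 3 or self.n_post_frames < 3:
            raise ParameterError("need at least 3 frames on each side of the bleach")
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be > 0")
        if self.true_ratio <= 0:
            raise ParameterError("true_ratio must be > 0")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ParameterError("mobile_fraction must be in [0, 1]")
        if min(self.recovery_rate_k_per_s, self.imaging_bleach_rate_per_s, self.noise_sd_rel) < 0:
            raise ParameterError("rates and noise must be >= 0")
        if not 0.0 <= self.bleach_floor < 1.0:
            raise ParameterError("bleach_floor must be in [0, 1)")


# ---------------------------------------------------------------------------
# geometry helpers


def _axis_vector(orientation_deg: float) -> np.ndarray:
    """Unit vector (row, col) of the chain/hypha axis; 0 deg -> along columns."""
    theta = math.radians(orientation_deg)
    return np.array([math.sin(theta), math.cos(theta)])


def _distance_to_segment(shape: tuple[int, int], p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Per-pixel distance (px) from pixel centres to the segment p0-p1."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0.0:
        return np.hypot(rows - p0[0], cols - p0[1])
    t = ((rows - p0[0]) * d[0] + (cols - p0[1]) * d[1]) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(rows - (p0[0] + t * d[0]), cols - (p0[1] + t * d[1]))


def _capsule(shape: tuple[int, int], centre: np.ndarray, axis: np.ndarray,
             length_px: float, radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (boolean capsule mask, signed-ish boundary distance array).

    The capsule is the set of pixels within ``radius_px`` of the central
    segment of length ``length_px - 2 * radius_px``.
    """
    half = max(length_px / 2.0 - radius_px, 0.0)
    p0 = centre - axis * half
    p1 = centre + axis * half
    dseg = _distance_to_segment(shape, p0, p1)
    return dseg <= radius_px, dseg - radius_px


def _apply_camera(scene: np.ndarray, imaging: ImagingConfig, rng: np.random.Generator) -> np.ndarray:
    """PSF blur, flat background, Poisson shot noise, Gaussian read noise."""
    img = scene
    if imaging.psf_sigma_px > 0:
        img = ndimage.gaussian_filter(img, imaging.psf_sigma_px)
    img = img + imaging.background_level
    if imaging.shot_noise:
        img = rng.poisson(np.clip(img, 0, None) * imaging.shot_gain) / imaging.shot_gain
    if imaging.read_noise_sd > 0:
        img = img + rng.normal(0.0, imaging.read_noise_sd, img.shape)
    return np.clip(img, 0.0, None)


def _required_extent_px(total_axis_px: float, transverse_px: float,
                        axis: np.ndarray, margin_px: float) -> tuple[int, int]:
    rows = abs(axis[0]) * total_axis_px + abs(axis[1]) * transverse_px + 2 * margin_px
    cols = abs(axis[1]) * total_axis_px + abs(axis[0]) * transverse_px + 2 * margin_px
    return int(math.ceil(rows)), int(math.ceil(cols))


def draw_spore_lengths(n: int, mean_um: float, sd_um: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw n spore lengths from a Gaussian truncated at > 0 (by redraw)."""
    lengths = rng.normal(mean_um, sd_um, n)
    bad = lengths <= 0
    while np.any(bad):
        lengths[bad] = rng.normal(mean_um, sd_um, int(bad.sum()))
        bad = lengths <= 0
    return lengths


# ---------------------------------------------------------------------------
# spore chains


def simulate_spore_chain(spec: SporeChainSpec, imaging: ImagingConfig | None = None,
                         seed: int = 0) -> tuple[ImageStack, GroundTruth]:
    """Render one spore chain into a membrane + DNA two-channel image.

    Spores are capsules laid end to end along the chain axis, separated by
    ``septum_gap_um``.  The membrane channel carries a bright envelope ring
    centred on each capsule boundary over a dim cytoplasmic plateau; the DNA
    channel carries one nucleoid per spore, condensed or toroid per the
    spec.  Identical ``(spec, imaging, seed)`` give bit-identical output.
    """
    imaging = imaging or ImagingConfig()
    rng = np.random.default_rng(seed)
    px_um = imaging.pixel_size_um
    axis = _axis_vector(spec.orientation_deg)

    lengths_um = draw_spore_lengths(spec.n_spores, spec.length_mean_um, spec.length_sd_um, rng)
    if spec.nucleoid_modes is not None:
        modes = list(spec.nucleoid_modes)
    else:
        modes = ["toroid" if rng.random() < spec.rim_fraction else "condensed"
                 for _ in range(spec.n_spores)]

    lengths_px = lengths_um / px_um
    gap_px = spec.septum_gap_um / px_um
    radius_px = spec.diameter_um / 2.0 / px_um
    total_axis_px = float(np.sum(lengths_px) + gap_px * max(spec.n_spores - 1, 0))
    margin_px = 2 * radius_px + 4 * imaging.psf_sigma_px + 4

    need = _required_extent_px(total_axis_px, 2 * radius_px, axis, margin_px)
    if imaging.image_shape_px is None:
        shape = need
    else:
        shape = tuple(imaging.image_shape_px)
        if shape[0] < need[0] or shape[1] < need[1]:
            raise SizingError(
                f"image_shape_px {shape} too small for the chain; need at least {need}"
            )

    centre_img = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])
    membrane = np.zeros(shape)
    dna = np.zeros(shape)
    truth = GroundTruth(seed=seed)

    # rim ring: Gaussian ridge centred on the capsule boundary
    rim_sigma_px = max(1.0, 40.0 / imaging.pixel_size_nm)

    pos = -total_axis_px / 2.0
    for i in range(spec.n_spores):
        length_px = float(lengths_px[i])
        centre = centre_img + axis * (pos + length_px / 2.0)
        # a spore drawn shorter than its diameter is rendered as a sphere of
        # diameter equal to its length, keeping mask extent == recorded length
        mask, bdist = _capsule(shape, centre, axis, length_px, min(radius_px, length_px / 2.0))
        membrane += MEMBRANE_BODY_AMPLITUDE * mask
        near = np.abs(bdist) < 4 * rim_sigma_px
        membrane[near] += MEMBRANE_RIM_AMPLITUDE * np.exp(
            -(bdist[near] ** 2) / (2 * rim_sigma_px**2)
        )

        rho = np.hypot(*(np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
                         - centre.reshape(2, 1, 1)))
        nuc = spec.nucleoid
        if modes[i] == "condensed":
            sig = nuc.condensed_sigma_um / px_um
            dna += DNA_AMPLITUDE * np.exp(-(rho**2) / (2 * sig**2))
        else:
            ring_r = nuc.toroid_radius_um / px_um
            ring_sig = nuc.toroid_sigma_um / px_um
            dna += DNA_AMPLITUDE * np.exp(-((rho - ring_r) ** 2) / (2 * ring_sig**2))

        truth.spores.append(
            SporeRecord(
                spore_id=i,
                mask=mask,
                length_um=float(lengths_um[i]),
                nucleoid_mode=modes[i],
                centroid_px=(float(centre[0]), float(centre[1])),
            )
        )
        pos += length_px + gap_px

    data = np.stack([
        _apply_camera(membrane, imaging, rng),
        _apply_camera(dna, imaging, rng),
    ])
    stack = ImageStack(data, ("membrane", "dna"), imaging.pixel_size_nm)
    return stack, truth


# ---------------------------------------------------------------------------
# foci along hyphae


def simulate_foci_hypha(spec: FociFieldSpec, imaging: ImagingConfig | None = None,
                        seed: int = 0) -> tuple[ImageStack, GroundTruth]:
    """Render one hypha with fluorescent foci in two fusion channels.

    Foci are placed sequentially along the axis with truncated-Gaussian
    gaps (redraw on <= 0).  With probability ``1 - occupancy`` the hypha
    carries no foci at all.  Channel B receives a ``co_placement_fraction``
    subset of channel-A positions jittered by ``co_jitter_nm`` per axis.
    """
    imaging = imaging or ImagingConfig()
    rng = np.random.default_rng(seed)
    px_um = imaging.pixel_size_um
    axis = _axis_vector(spec.orientation_deg)
    perp = np.array([-axis[1], axis[0]])

    length_px = spec.hypha_length_um / px_um
    radius_px = spec.hypha_diameter_um / 2.0 / px_um
    margin_px = 2 * radius_px + 4 * imaging.psf_sigma_px + 6
    need = _required_extent_px(length_px, 2 * radius_px, axis, margin_px)
    if imaging.image_shape_px is None:
        shape = need
    else:
        shape = tuple(imaging.image_shape_px)
        if shape[0] < need[0] or shape[1] < need[1]:
            raise SizingError(
                f"image_shape_px {shape} too small for the hypha; need at least {need}"
            )
    centre_img = np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])

    # axial focus positions (µm from the hypha start)
    positions_a: list[float] = []
    if spec.occupancy > 0 and rng.random() < spec.occupancy:
        pos = float(rng.uniform(0.0, spec.spacing_mean_um))
        while pos < spec.hypha_length_um:
            positions_a.append(pos)
            gap = float(rng.normal(spec.spacing_mean_um, spec.spacing_sd_um))
            while gap <= 0:
                gap = float(rng.normal(spec.spacing_mean_um, spec.spacing_sd_um))
            pos += gap

    jitter_um = spec.co_jitter_nm / 1000.0
    positions_b: list[np.ndarray] = []  # (axial_um, transverse_um)
    for p in positions_a:
        if rng.random() < spec.co_placement_fraction:
            positions_b.append(np.array([p, 0.0]) + rng.normal(0.0, jitter_um, 2))

    def to_px(axial_um: float, transverse_um: float) -> np.ndarray:
        s = (axial_um - spec.hypha_length_um / 2.0) / px_um
        return centre_img + axis * s + perp * (transverse_um / px_um)

    def render_channel(points: list[np.ndarray]) -> np.ndarray:
        scene = np.zeros(shape)
        p0 = centre_img - axis * length_px / 2.0
        p1 = centre_img + axis * length_px / 2.0
        dseg = _distance_to_segment(shape, p0, p1)
        scene += HYPHA_TUBE_AMPLITUDE * (dseg <= radius_px)
        sig = spec.focus_sigma_um / px_um
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        for pt in points:
            r2 = (rows - pt[0]) ** 2 + (cols - pt[1]) ** 2
            scene += spec.focus_amplitude * np.exp(-r2 / (2 * sig**2))
        return scene

    pts_a = [to_px(p, 0.0) for p in positions_a]
    pts_b = [to_px(p[0], p[1]) for p in positions_b]
    data = np.stack([
        _apply_camera(render_channel(pts_a), imaging, rng),
        _apply_camera(render_channel(pts_b), imaging, rng),
    ])
    stack = ImageStack(data, ("fusion_a", "fusion_b"), imaging.pixel_size_nm)

    truth = GroundTruth(seed=seed)
    truth.foci_axial_um = {
        "fusion_a": np.array(sorted(positions_a)),
        "fusion_b": np.array(sorted(p[0] for p in positions_b)),
    }
    truth.foci_px = {
        "fusion_a": np.array(pts_a).reshape(-1, 2),
        "fusion_b": np.array(pts_b).reshape(-1, 2),
    }
    return stack, truth


# ---------------------------------------------------------------------------
# photobleaching series


def simulate_fretap_series(spec: PhotobleachSpec, seed: int = 0) -> IntensityTrace:
    """Donor-intensity frames around an acceptor photobleach.

    Pre-bleach frames are centred on 1.0 and post-bleach frames on
    ``true_ratio`` (donor dequenching gives ratios > 1); each frame carries
    multiplicative Gaussian noise of relative sd ``noise_sd_rel``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_pre_frames + spec.n_post_frames
    times = np.arange(n) * spec.frame_interval_s
    ideal = np.concatenate([
        np.ones(spec.n_pre_frames),
        np.full(spec.n_post_frames, spec.true_ratio),
    ])
    noise = 1.0 + rng.normal(0.0, spec.noise_sd_rel, n) if spec.noise_sd_rel > 0 else 1.0
    return IntensityTrace(times, ideal * noise, bleach_index=spec.n_pre_frames, roi_id="donor")


def frap_recovery_curve(t_post_s: np.ndarray, spec: PhotobleachSpec) -> np.ndarray:
    """Closed-form bleached-ROI recovery, excluding imaging bleach and noise.

    I(t) = floor + M (1 - floor) (1 - exp(-k t)); with M = 1 the curve
    returns to the pre-bleach level of 1 at t -> inf.
    """
    f = spec.bleach_floor
    return f + spec.mobile_fraction * (1.0 - f) * (
        1.0 - np.exp(-spec.recovery_rate_k_per_s * np.asarray(t_post_s, dtype=float))
    )


def simulate_frap_series(spec: PhotobleachSpec, seed: int = 0) -> tuple[IntensityTrace, IntensityTrace]:
    """Bleached-ROI and reference-ROI traces for one FRAP experiment.

    Both ROIs decay by ``exp(-imaging_bleach_rate_per_s * t)`` from the first
    frame; the bleached ROI additionally follows the single-exponential
    recovery of :func:`frap_recovery_curve` from the first post-bleach frame.
    Defaults give a 15 s post-bleach follow at 0.25 s frame interval.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_pre_frames + spec.n_post_frames
    times = np.arange(n) * spec.frame_interval_s
    t_post = times[spec.n_pre_frames :] - times[spec.n_pre_frames]

    bleached = np.concatenate([np.ones(spec.n_pre_frames), frap_recovery_curve(t_post, spec)])
    reference = np.ones(n)
    decay = np.exp(-spec.imaging_bleach_rate_per_s * times)
    bleached = bleached * decay
    reference = reference * decay
    if spec.noise_sd_rel > 0:
        bleached = bleached * (1.0 + rng.normal(0.0, spec.noise_sd_rel, n))
        reference = reference * (1.0 + rng.normal(0.0, spec.noise_sd_rel, n))
    bi = spec.n_pre_frames
    return (
        IntensityTrace(times, bleached, bleach_index=bi, roi_id="bleached"),
        IntensityTrace(times, reference, bleach_index=bi, roi_id="reference"),
    )
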