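"""Generator correctness: determinism, geometry, and generative moments."""
import math

import numpy as np
import pytest
from scipy import ndimage

from sporoquant import (
    FociFieldSpec,
    ImagingConfig,
    PhotobleachSpec,
    SporeChainSpec,
    simulate_foci_hypha,
    simulate_frap_series,
    simulate_fretap_series,
    simulate_spore_chain,
)
from sporoquant.core import ParameterError, SizingError
from sporoquant.morphometry import principal_axis_extent_px


def test_default_pixel_size_matches_acquisition_resolution():
    assert ImagingConfig().pixel_size_nm == 37.5


def test_empty_chain_gives_background_only_image(default_imaging):
    stack, truth = simulate_spore_chain(SporeChainSpec(n_spores=0), default_imaging, seed=1)
    assert truth.n_spores == 0
    assert stack.channel("membrane").shape == stack.channel("dna").shape


def test_chain_is_deterministic_for_identical_seed(default_imaging):
    spec = SporeChainSpec(n_spores=5)
    s1, t1 = simulate_spore_chain(spec, default_imaging, seed=42)
    s2, t2 = simulate_spore_chain(spec, default_imaging, seed=42)
    np.testing.assert_array_equal(s1.data, s2.data)
    np.testing.assert_array_equal(t1.spore_lengths_um(), t2.spore_lengths_um())
    s3, _ = simulate_spore_chain(spec, default_imaging, seed=43)
    assert not np.array_equal(s1.data, s3.data)


def test_ground_truth_mask_extents_match_recorded_lengths(noise_free_imaging):
    """Mask-derived pole-to-pole extents agree with drawn lengths within 2 px."""
    spec = SporeChainSpec(n_spores=10, length_mean_um=1.0, length_sd_um=0.0)
    stack, truth = simulate_spore_chain(spec, noise_free_imaging, seed=7)
    px_um = stack.pixel_size_um
    for s in truth.spores:
        extent_um = principal_axis_extent_px(s.mask) * px_um
        assert abs(extent_um - s.length_um) <= 2 * px_um


def test_short_spores_render_with_extent_equal_to_length(noise_free_imaging):
    """Spores drawn shorter than the chain diameter become spheres, not fatter."""
    spec = SporeChainSpec(n_spores=4, length_mean_um=0.6, length_sd_um=0.0, diameter_um=0.8)
    stack, truth = simulate_spore_chain(spec, noise_free_imaging, seed=3)
    for s in truth.spores:
        extent_um = principal_axis_extent_px(s.mask) * stack.pixel_size_um
        assert abs(extent_um - s.length_um) <= 2 * stack.pixel_size_um


def test_one_connected_nucleoid_object_per_spore(noise_free_imaging):
    stack, truth = simulate_spore_chain(
        SporeChainSpec(rim_fraction=0.5), noise_free_imaging, seed=11
    )
    dna = stack.channel("dna")
    _, n_objects = ndimage.label(dna > noise_free_imaging.background_level + 150)
    assert n_objects == truth.n_spores


def test_too_small_image_raises_sizing_error(default_imaging):
    import dataclasses

    small = dataclasses.replace(default_imaging, image_shape_px=(20, 20))
    with pytest.raises(SizingError, match="need at least"):
        simulate_spore_chain(SporeChainSpec(n_spores=5), small, seed=0)


def test_spore_length_population_moments(rng):
    """Drawn lengths converge to the requested Gaussian (3-SEM check)."""
    from sporoquant import draw_spore_lengths

    lengths = draw_spore_lengths(2000, 0.96, 0.10, rng)
    assert np.all(lengths > 0)
    assert abs(lengths.mean() - 0.96) < 3 * 0.10 / math.sqrt(2000)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_spores": -1},
        {"length_mean_um": 0.0},
        {"rim_fraction": 1.5},
        {"nucleoid_modes": ("condensed",)},  # wrong count for default n_spores
    ],
)
def test_invalid_chain_spec_rejected(kwargs):
    with pytest.raises(ParameterError):
        SporeChainSpec(**kwargs)


# ---------------------------------------------------------------------------
# foci


def test_zero_occupancy_hypha_has_no_foci(default_imaging):
    stack, truth = simulate_foci_hypha(FociFieldSpec(occupancy=0.0), default_imaging, seed=5)
    assert truth.foci_axial_um["fusion_a"].size == 0
    assert truth.foci_axial_um["fusion_b"].size == 0


def test_focus_gap_moments_match_spacing_parameters(default_imaging):
    """Pooled ground-truth gaps land within 3 SEM of the 1.25 µm spacing mean."""
    rng = np.random.default_rng(99)
    gaps = []
    spec = FociFieldSpec(occupancy=1.0, spacing_mean_um=1.25, spacing_sd_um=0.14)
    while len(gaps) < 1000:
        _, truth = simulate_foci_hypha(spec, default_imaging, seed=int(rng.integers(2**31)))
        gaps.extend(np.diff(truth.foci_axial_um["fusion_a"]))
    gaps = np.asarray(gaps[:1000])
    assert np.all(gaps > 0)
    assert abs(gaps.mean() - 1.25) < 3 * gaps.std(ddof=1) / math.sqrt(len(gaps))


def test_full_coplacement_with_zero_jitter_duplicates_positions(default_imaging):
    spec = FociFieldSpec(occupancy=1.0, co_placement_fraction=1.0, co_jitter_nm=0.0)
    _, truth = simulate_foci_hypha(spec, default_imaging, seed=8)
    np.testing.assert_allclose(
        truth.foci_px["fusion_b"], truth.foci_px["fusion_a"], atol=1e-12
    )


def test_hypha_shorter_than_one_spacing_yields_at_most_one_focus(default_imaging):
    spec = FociFieldSpec(hypha_length_um=1.0, spacing_mean_um=1.25, occupancy=1.0)
    _, truth = simulate_foci_hypha(spec, default_imaging, seed=2)
    assert truth.foci_axial_um["fusion_a"].size <= 1


# ---------------------------------------------------------------------------
# photobleaching series


def test_fretap_noise_free_identity_ratio_is_constant():
    trace = simulate_fretap_series(PhotobleachSpec(true_ratio=1.0), seed=0)
    np.testing.assert_allclose(trace.intensities, 1.0)


def test_fretap_noise_free_post_frames_scale_by_true_ratio():
    trace = simulate_fretap_series(PhotobleachSpec(true_ratio=1.08), seed=0)
    np.testing.assert_allclose(trace.post, 1.08 * trace.pre[: len(trace.post)].mean())
    assert trace.bleach_index == 3


def test_fretap_measured_ratio_unbiased_over_replicates():
    """Law of large numbers: mean measured ratio within 3 SEM of true_ratio."""
    from sporoquant.photokinetics import fretap_efficiency

    spec = PhotobleachSpec(true_ratio=1.05, noise_sd_rel=0.02)
    ratios = np.array(
        [fretap_efficiency(simulate_fretap_series(spec, seed=s)).ratio for s in range(10_000)]
    )
    sem = ratios.std(ddof=1) / math.sqrt(len(ratios))
    assert abs(ratios.mean() - 1.05) < 3 * sem


def test_frap_noise_free_trace_equals_closed_form():
    k, m, f = 0.2, 0.7, 0.25
    spec = PhotobleachSpec(
        recovery_rate_k_per_s=k, mobile_fraction=m, bleach_floor=f,
        imaging_bleach_rate_per_s=0.0, noise_sd_rel=0.0,
    )
    bleached, reference = simulate_frap_series(spec, seed=0)
    t = bleached.times_s[bleached.bleach_index :] - bleached.times_s[bleached.bleach_index]
    expected = np.array([f + m * (1 - f) * (1 - math.exp(-k * ti)) for ti in t])
    np.testing.assert_allclose(bleached.post, expected, rtol=1e-9)
    np.testing.assert_allclose(reference.intensities, 1.0)


def test_frap_immobile_fraction_gives_flat_post_bleach_trace():
    spec = PhotobleachSpec(mobile_fraction=0.0, imaging_bleach_rate_per_s=0.0)
    bleached, _ = simulate_frap_series(spec, seed=0)
    np.testing.assert_allclose(bleached.post, spec.bleach_floor)


def test_frap_default_duration_covers_fifteen_seconds():
    spec = PhotobleachSpec()
    bleached, _ = simulate_frap_series(spec, seed=0)
    t_post = bleached.times_s[-1] - bleached.times_s[bleached.bleach_index]
    assert t_post >= 14.5


def test_imaging_bleach_applies_to_both_rois():
    spec = PhotobleachSpec(mobile_fraction=0.0, imaging_bleach_rate_per_s=0.05)
    bleached, reference = simulate_frap_series(spec, seed=0)
    decay = np.exp(-0.05 * reference.times_s)
    np.testing.assert_allclose(reference.intensities, decay, rtol=1e-12)
    np.testing.assert_allclose(bleached.pre, decay[: bleached.bleach_index], rtol=1e-12)
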