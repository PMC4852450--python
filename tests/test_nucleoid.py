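"""Axial profile extraction and rim-localization classification."""
import numpy as np
import pytest
from scipy.signal import find_peaks

from sporoquant import (
    AxialProfile,
    RimCall,
    RimClassifierParams,
    SporeChainSpec,
    average_profiles,
    classify_rim_localization,
    extract_axial_profile,
    rim_fraction,
    segment_spores,
    simulate_spore_chain,
)
from sporoquant.core import ParameterError
from sporoquant.morphometry import LabeledRegions
from sporoquant.nucleoid import N_PROFILE_POINTS, ProfileError

POSITIONS = np.linspace(0.0, 1.0, N_PROFILE_POINTS)


def _rect_region(shape=(21, 60), rows=slice(5, 16), cols=slice(10, 50)):
    label_image = np.zeros(shape, dtype=int)
    label_image[rows, cols] = 1
    return LabeledRegions(label_image)


def test_uniform_spore_gives_flat_profile_of_ones():
    regions = _rect_region()
    plane = np.where(regions.label_image > 0, 5.0, 0.0)
    prof = extract_axial_profile(plane, regions, 1, background=0.0)
    np.testing.assert_allclose(prof.intensities, 1.0)


def test_centred_gaussian_blob_profiles_symmetric_with_central_peak():
    regions = _rect_region()
    rr, cc = np.mgrid[0:21, 0:60].astype(float)
    plane = np.exp(-((rr - 10) ** 2 + (cc - 29.5) ** 2) / (2 * 5.0**2))
    prof = extract_axial_profile(plane, regions, 1, background=0.0)
    assert abs(prof.positions[np.argmax(prof.intensities)] - 0.5) <= 0.02
    np.testing.assert_allclose(prof.intensities, prof.intensities[::-1], atol=0.02)


def test_profile_invariant_under_image_scaling(noise_free_imaging):
    stack, _ = simulate_spore_chain(SporeChainSpec(n_spores=3), noise_free_imaging, seed=9)
    regions = segment_spores(stack.channel("membrane"))
    dna = stack.channel("dna")
    p1 = extract_axial_profile(dna, regions, 2)
    p2 = extract_axial_profile(dna * 7.3, regions, 2)
    np.testing.assert_allclose(p1.intensities, p2.intensities, atol=1e-12)


def test_too_short_region_rejected():
    regions = _rect_region(rows=slice(5, 8), cols=slice(10, 13))  # 3 x 3 px
    with pytest.raises(ProfileError):
        extract_axial_profile(np.ones((21, 60)), regions, 1, background=0.0)


def test_toroid_profile_maxima_match_annulus_projection(noise_free_imaging):
    """Rendered toroid maxima sit where the analytic ring projection puts them."""
    L, D, R, SIG = 1.0, 0.8, 0.22, 0.08
    spec = SporeChainSpec(
        n_spores=3, length_mean_um=L, length_sd_um=0.0, diameter_um=D,
        nucleoid_modes=("toroid",) * 3,
    )
    stack, _ = simulate_spore_chain(spec, noise_free_imaging, seed=2)
    regions = segment_spores(stack.channel("membrane"))
    prof = extract_axial_profile(stack.channel("dna"), regions, 2)
    peaks, _ = find_peaks(prof.intensities)
    assert len(peaks) == 2

    # independent numeric projection of the annulus model over the same band
    s = np.linspace(-L / 2, L / 2, 2001)
    t = np.linspace(-D / 4, D / 4, 401)
    S, T = np.meshgrid(s, t, indexing="ij")
    f = np.exp(-((np.sqrt(S**2 + T**2) - R) ** 2) / (2 * SIG**2)).mean(axis=1)
    expected = (s[find_peaks(f)[0]] + L / 2) / L
    np.testing.assert_allclose(prof.positions[peaks], expected, atol=0.05)


def test_average_of_identical_profiles_is_unchanged():
    y = np.exp(-((POSITIONS - 0.5) ** 2) / 0.02)
    y /= y.max()
    prof = AxialProfile(POSITIONS, y)
    avg = average_profiles([prof, prof, prof])
    np.testing.assert_allclose(avg.intensities, y)


def test_average_is_pointwise_mean_renormalized():
    y1 = np.linspace(0, 1, N_PROFILE_POINTS)
    y2 = np.ones(N_PROFILE_POINTS)
    avg = average_profiles([AxialProfile(POSITIONS, y1), AxialProfile(POSITIONS, y2)])
    expected = (y1 + y2) / 2
    np.testing.assert_allclose(avg.intensities, expected / expected.max())


def test_average_profiles_rejects_empty_list():
    with pytest.raises(ParameterError):
        average_profiles([])


def test_average_over_rim_localized_spores_shows_central_dip(default_imaging):
    spec = SporeChainSpec(n_spores=10, nucleoid_modes=("toroid",) * 10)
    stack, _ = simulate_spore_chain(spec, default_imaging, seed=21)
    regions = segment_spores(stack.channel("membrane"))
    profiles = [
        extract_axial_profile(stack.channel("dna"), regions, int(lab))
        for lab in regions.labels
    ]
    avg = average_profiles(profiles)
    centre = avg.intensities[45:56].min()
    left_shoulder = avg.intensities[20:45].max()
    right_shoulder = avg.intensities[56:81].max()
    assert centre < 0.9 * avg.intensities.max()
    assert centre < min(left_shoulder, right_shoulder)


def test_monotone_and_single_peak_profiles_are_condensed():
    mono = AxialProfile(POSITIONS, np.linspace(0, 1, N_PROFILE_POINTS))
    assert classify_rim_localization(mono).call == "condensed"
    single = np.exp(-((POSITIONS - 0.5) ** 2) / 0.01)
    assert classify_rim_localization(AxialProfile(POSITIONS, single / single.max())).call == "condensed"


def test_flat_profile_is_condensed_with_zero_dip():
    call = classify_rim_localization(AxialProfile(POSITIONS, np.ones(N_PROFILE_POINTS)))
    assert call.call == "condensed"
    assert call.dip_depth == 0.0


def test_constructed_double_peak_recovers_dip_depth():
    y = np.exp(-((POSITIONS - 0.3) ** 2) / 0.005) + np.exp(-((POSITIONS - 0.7) ** 2) / 0.005)
    y = y / y.max()
    dip_true = 1.0 - y[50] / (0.5 * (y[30] + y[70]))
    call = classify_rim_localization(AxialProfile(POSITIONS, y))
    assert call.call == "rim_localized"
    assert call.dip_depth == pytest.approx(dip_true, abs=0.05)


def test_noise_free_toroid_called_rim_localized(noise_free_imaging):
    spec = SporeChainSpec(n_spores=3, length_mean_um=1.0, length_sd_um=0.0,
                          nucleoid_modes=("toroid",) * 3)
    stack, _ = simulate_spore_chain(spec, noise_free_imaging, seed=6)
    regions = segment_spores(stack.channel("membrane"))
    prof = extract_axial_profile(stack.channel("dna"), regions, 2)
    call = classify_rim_localization(prof)
    assert call.call == "rim_localized"
    assert call.dip_depth > 0.1  # well clear of the default 0.1 call threshold


def test_classifier_monotone_in_dip_depth():
    """Deepening the central minimum never flips rim_localized to condensed."""
    base = np.exp(-((POSITIONS - 0.3) ** 2) / 0.005) + np.exp(-((POSITIONS - 0.7) ** 2) / 0.005)
    base = base / base.max()
    call0 = classify_rim_localization(AxialProfile(POSITIONS, base))
    assert call0.call == "rim_localized"
    prev_depth = call0.dip_depth
    for scale in (0.8, 0.5, 0.2, 0.0):
        y = base.copy()
        y[40:61] *= scale
        call = classify_rim_localization(AxialProfile(POSITIONS, y))
        assert call.call == "rim_localized"
        assert call.dip_depth >= prev_depth - 1e-9
        prev_depth = call.dip_depth


def test_rim_fraction_zero_when_all_condensed():
    calls = [RimCall("condensed", 0.0, 1, i) for i in range(20)]
    res = rim_fraction(calls)
    assert res.percent == 0.0
    assert res.ci_low_percent == 0.0


def test_rim_fraction_printed_count_examples():
    calls = [RimCall("rim_localized", 0.3, 2, i) for i in range(14)] + [
        RimCall("condensed", 0.0, 1, i) for i in range(86)
    ]
    assert rim_fraction(calls).percent == pytest.approx(14.0)
    # 1 of 7 spores: exact fraction 14.3%, printed in coarser rounding as ~13%
    calls7 = [RimCall("rim_localized", 0.3, 2, 0)] + [
        RimCall("condensed", 0.0, 1, i) for i in range(6)
    ]
    res = rim_fraction(calls7)
    assert res.percent == pytest.approx(100.0 / 7.0)
    assert abs(res.percent - 13.0) < 1.5
    assert res.ci_low_percent < res.percent < res.ci_high_percent
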