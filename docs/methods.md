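# Methods

This note documents the models, defaults and numerical choices behind
`sporoquant`, and what the synthetic-data tests do and do not establish
about real micrographs.

## Imaging model

All image generators share one camera model (`ImagingConfig`): scene
photons rendered in continuous units, convolved with an isotropic Gaussian
PSF, offset by a flat background, then Poisson shot noise followed by
additive Gaussian read noise. Defaults: 37.5 nm/pixel (the pixel pitch of
the emulated epifluorescence acquisition), PSF sigma 80 nm (≈ 0.21 λ/NA for
green emission at NA 1.4), background 100 a.u., shot gain 1, read noise
sd 2. The source imaging regime constrains only the pixel pitch; the
amplitude scale of each channel is a free package default chosen for a
realistic signal-to-background ratio (membrane rim 1200, cytoplasmic
plateau 60, DNA 800, hypha tube 40, focus 500 a.u., all pre-blur).
Out of scope by design: 3-D/PSF-accurate optics, depletion-microscopy
physics, drift, and electron-microscopy modalities.

## Spore chains and segmentation

Spores are 2-D capsules laid along a common axis. Lengths are Gaussian
draws truncated at > 0 by redraw; the wild-type default is 0.96 ± 0.10 µm
(lengths spanning roughly 0.8–1.2 µm), diameter 0.80 µm. The null-mutant
regime used in tests and in the acceptance script is 1.24 µm with a broader
sd of 0.15 µm (the mutant's dispersion is described only qualitatively, so
the value is a package choice), and the complemented regime 1.06 ± 0.10 µm.
A spore drawn shorter than the chain diameter is rendered as a sphere of
diameter equal to its length, so recorded lengths always match rendered
geometry. Consecutive envelopes are separated by a 0.35 µm septum gap —
large enough that adjacent envelope rings remain resolvable at any chain
orientation under the default PSF; mid-constriction chains with touching
compartments can be produced by shrinking the gap, and the watershed
splitter in segmentation exists for exactly that case.

The membrane channel renders each envelope as a Gaussian ridge (sigma
40 nm) centred on the capsule boundary over a dim cytoplasmic plateau.
Segmentation (`segment_spores`) thresholds (Otsu by default), fills ring
interiors, and then shrinks the filled object back to the envelope
midline: the thresholded ring straddles the true boundary symmetrically,
so the filled object is dilated by half the ring thickness; the thickness
is estimated from the mean Euclidean distance transform of the ring mask
(mean EDT of a discrete strip of width w is ≈ (w + 2)/4, hence the
half-pixel correction in the code), and the object is shrunk by that
half-thickness via the EDT of the filled mask. Touching compartments are
split by marker-controlled watershed on the smoothed distance transform,
with markers at > 60% of each object's peak interior distance. On
noise-free defaults this recovers per-spore masks at IoU ≥ 0.9 with length
errors within about half a pixel; these figures were calibrated on
simulations during development.

**Length definition.** Spore length is the extent of the region's pixel
projections along its second-moment principal axis, plus one pixel for the
pixel footprint, times the pixel size. (The second-moment *ellipse axis
length*, 4σ along the major axis, is a different and for capsules strongly
biased quantity; the extent definition is what makes a 27-px, 1-px-wide
segment measure exactly 27 × 37.5 nm.) Lengths measured this way on
fluorescence masks are only approximately comparable to manual
measurements on electron micrographs. At exactly axis-aligned orientations
the extent is quantized to the pixel lattice; distribution-level tests
therefore sample random chain orientations, which is also the realistic
condition.

Population statistics use the sample sd (n − 1 denominator, defined 0 at
n = 1) and two-sided Welch tests throughout (the sidedness of the original
comparisons is not stated; two-sided is the conservative choice).
Heat-survival rates are 100 × treated/untreated CFU with optional dilution
factors; no treatment model is implied.

## Nucleoids and the rim ("dent") classifier

Condensed nucleoids are isotropic Gaussian blobs (sigma 0.15 µm); toroidal
nucleoids are annuli in single-plane projection (radius 0.22 µm, radial
sigma 0.08 µm), so the central intensity deficit emerges from ring
geometry rather than being painted. With the default optics the projected,
band-averaged toroid profile has a central dip of relative depth ≈ 0.18;
deeper dips appear at larger ring radii or tighter PSFs.

Profiles are sampled with bilinear interpolation along the region's
principal axis, averaged transversely over a band of half the minor-axis
extent, background-subtracted (mean intensity outside all segmented
objects; the synthetic background is flat, and the estimator is
configurable), clipped at zero, resampled to 101 points on [0, 1] and
max-normalized. 101-point pole-to-pole normalization makes profiles
comparable across spore sizes. Regions shorter than 5 px along the axis
are rejected as unprofilable.

The classifier smooths with a 5-point centred moving average (enough to
suppress single-sample noise without erasing a two-maximum structure at
101 points), finds local maxima (profile endpoints count when the profile
rises into them), and calls *rim_localized* iff some local minimum inside
the central 60% window has relative depth
`1 − I_min / mean(highest flanking maxima)` ≥ 0.1. Flanking with the
*highest* maximum on each side, rather than the nearest, prevents a small
noise bump adjacent to the minimum from masking a deep dip. No quantitative
dent definition exists in the literature this emulates; the 0.1 depth and
0.6 window are package decisions calibrated on simulations and are
configurable. Rim calls are per spore (whether the original counts were
per spore or per chain is ambiguous; per spore is implemented). Fractions
carry Wilson 95% intervals.

## Foci, spacing, colocalization

Foci are placed sequentially along the hypha axis with truncated-Gaussian
gaps (redraw on ≤ 0); wild-type defaults: 1.25 ± 0.14 µm spacing, 80%
occupancy, 20 µm hyphae. A second channel duplicates a configurable
fraction of first-channel positions with Gaussian jitter (default 50 nm
per axis).

Detection smooths with a 1.2 px Gaussian and takes local maxima above
`background + max(k·noise_sd, min_prominence)`, with background the plane
median, noise sd its scaled median absolute deviation, k = 3 and an
absolute prominence floor of 80 a.u.; the floor keeps the dim extended
hypha tube out of the focus list when noise is negligible. Plateau ties
(a peak exactly between two pixels) are collapsed to one detection;
positions are refined per axis by quadratic interpolation. Axial positions
are projections onto the intensity-weighted principal axis of the plane.
Spacing statistics pool consecutive gaps across hyphae; occupancy is the
percentage of hyphae with ≥ 1 focus. Colocalization matches foci greedily,
closest pairs first, each focus used once, within 200 nm by default; the
first channel is the headline denominator and both denominators are
reported, since "overlap of their foci" does not fix one.

## FRET (acceptor photobleaching)

The frame protocol is fixed: I_pre is the mean of the three frames
immediately preceding the bleach, I_post the mean of the first three
frames after it — later frames never enter, so lengthening a trace cannot
change the result, and the ratio is invariant to detector gain. The
post/pre ratio is the headline quantity (> 1 = donor dequenching =
interaction); the conventional efficiency E = 1 − I_pre/I_post is emitted
alongside for comparability with the wider FRET literature. Aggregation
reports mean, sample sd and n — sd and n are the stored pair, from which
the standard error is derivable; the source tables label the dispersion
row inconsistently as sd vs sem, and sd is what is emulated here — plus a
two-sided two-sample Welch test against a control pair's ratios.

The generator draws pre-bleach frames centred on 1 and post-bleach frames
centred on the true ratio, with multiplicative Gaussian noise (typical
regime sd 0.02–0.03).

## FRAP

The bleached-ROI model is single-exponential:
I(t) = floor + M (1 − floor)(1 − e^(−kt)), with t = 0 at the first
post-bleach frame, M the mobile fraction and floor the immediate
post-bleach level (default 0.2). Both ROIs additionally decay as
e^(−b·t) for imaging bleach. One timescale is fitted because the emulated
measurements report a single half-time; multi-component models are out of
scope. Correction divides the trace by the reference normalized to its
pre-bleach mean, then renormalizes the corrected pre-bleach mean to 1;
this inverts an exponential imaging decay exactly.

Fitting is bounded least squares (scipy `curve_fit`, trf, tolerances
1e-14) on post-bleach frames only, initialized with floor = first
post-bleach value, plateau = last value and k from a log-linear regression
of (plateau − I); t½ = ln 2 / k holds identically on every fit. Failures
(no recovery amplitude, non-convergence, k ≤ 0) return a diagnostic
result, never an exception, and an immobile trace reports mobile fraction
≈ 0 rather than a spurious rate.

**Follow time.** The default series is 60 post-bleach frames at 0.25 s
(a 15 s follow, the emulated acquisition protocol). A 15 s window
determines a 5 s half-time to ~2% at 1% frame noise, but carries almost no
curvature information about a 42.3 s half-time — the fitted rate is then
unidentifiable (median error ≈ 26% in simulation). Slow-regime analyses in
the tests and the acceptance script therefore follow for about two
half-times (90 s for the 42.3 s regime, 180 s for the 82.3 s regime),
which restores median errors below 2%. This is a statistical requirement
of the estimator, not a tuning knob.

## Problem sizes and determinism

Every generator draws all randomness from a single `numpy` Generator
seeded per call; identical (spec, imaging, seed) triples are bit-identical,
and the pipeline writes its resolved configuration and stamps every result
CSV with the seed and package version. Test and acceptance problem sizes —
130 spores per strain for morphometry, 200 spores per rim-fraction regime,
50 hyphae for spacing, 100 seeds per FRAP noise regime, 24 + 12 series per
FRET comparison — were chosen to match the emulated study's scales while
keeping the full suite under a minute of compute.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analyses assume:
capsule geometry, flat background, Gaussian PSF, Poisson + read noise,
single-exponential recovery, and the stated population distributions.
Real micrographs add autofluorescent mycelium, uneven illumination,
out-of-focus light from 3-D structure, chain curvature, partially
constricted septa and debris; none of these are emulated, so parameter
recovery here validates the estimators' correctness, not their robustness
to every real-world artefact. The segmentation and dent thresholds are
exposed precisely so they can be re-tuned on real data.

## Known limitations

* Single-plane 2-D geometry throughout; no axial (z) information.
* The envelope-midline shrink assumes a roughly symmetric ring cross
  section; heavily saturated or one-sided membrane signals would bias it.
* The dent classifier is threshold-based, not model-based; very small
  toroids (ring radius ≲ PSF sigma) project to single peaks and are
  intrinsically uncallable in 2-D.
* Greedy colocalization is order-stable and adequate at the emulated focus
  densities but is not an optimal assignment.
* FRAP fitting assumes full bleach-correction and normalization upstream;
  reaction–diffusion models and sensitized-emission/lifetime FRET are out
  of scope.
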