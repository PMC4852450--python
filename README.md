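# sporoquant

Quantitative fluorescence-microscopy analysis of sporulation-specific cell
division in *Streptomyces coelicolor* — and, by extension, of any bacterium
whose development is read out through spore morphometry, nucleoid
organization, division-site markers and photobleaching kinetics.

During sporulation, the multigenomic aerial hyphae of *Streptomyces* are
converted almost simultaneously into long chains of unigenomic spores by
ladders of FtsZ rings placed at regularly spaced sites. Studying this
process quantitatively means answering, from micrographs and bleaching
series, questions such as: are mutant spores longer than wild-type spores,
and is the difference significant? Is the nucleoid condensed at the spore
centre or pushed to the rim (a toroidal, "doughnut" nucleoid)? How are
division-site marker foci spaced along a hypha, and do two markers
colocalize? Do two fusion proteins interact (acceptor-photobleaching FRET),
and is a protein membrane-integrated (FRAP recovery half-time)?

`sporoquant` implements that analysis stack as a tested, reusable library
with a thin CLI, plus a seeded synthetic-imaging generator that renders
spore chains, focus-bearing hyphae and photobleaching series with known
ground truth, so that every stage is verified by parameter recovery rather
than by eye.

## What it computes

* **Spore morphometry** — membrane-channel segmentation (Otsu threshold,
  ring filling, envelope-midline shrinking, distance-transform watershed),
  per-spore pole-to-pole length (second-moment principal-axis extent ×
  pixel size), population summaries (mean, sd, sem) and Welch's
  unequal-variance *t*-test with Welch–Satterthwaite degrees of freedom;
  heat-survival percentages from dilution-corrected CFU counts.
* **Nucleoid axial profiles** — background-subtracted DNA intensity along
  each spore's axis, resampled to 101 points on the normalized pole-to-pole
  coordinate; spores are called *rim-localized* when the smoothed profile
  shows two maxima flanking a central dip of relative depth
  ≥ `min_dip_depth` (default 0.1); population rim fractions carry Wilson
  95% confidence intervals.
* **Focus detection and spacing** — Gaussian-smoothed local maxima with
  sub-pixel quadratic refinement; per-hypha occupancy, consecutive axial
  gap statistics, and greedy one-to-one two-channel colocalization within a
  distance tolerance (default 200 nm).
* **Acceptor-photobleaching FRET** — the fixed frame protocol: donor
  intensity averaged over the three frames before and the first three
  frames after the acceptor bleach; the post/pre ratio (> 1 = dequenching,
  i.e. interaction) plus the conventional efficiency E = 1 − I_pre/I_post;
  aggregation with Welch test against a control pair.
* **FRAP kinetics** — reference-ROI bleach correction, then a
  single-exponential fit I(t) = floor + (plateau − floor)(1 − e^(−kt)) on
  the post-bleach frames, reporting t½ = ln 2 / k and the mobile fraction.
* **Synthetic imaging** — 2-D capsule spore chains with membrane-envelope
  and DNA channels (condensed blob or projected-annulus toroid nucleoids),
  focus-bearing hyphae, FRET and FRAP frame series; Gaussian PSF, flat
  background, Poisson shot noise and Gaussian read noise at 37.5 nm/pixel.

## Worked example

```python
from sporoquant import (ImagingConfig, SporeChainSpec, simulate_spore_chain,
                        segment_spores, measure_spore_lengths, summarize_lengths,
                        extract_axial_profile, classify_rim_localization, rim_fraction)

imaging = ImagingConfig()                      # 37.5 nm/px camera model
stack, truth = simulate_spore_chain(
    SporeChainSpec(n_spores=10, rim_fraction=0.74), imaging, seed=1)

regions = segment_spores(stack.channel("membrane"))
sample = measure_spore_lengths(regions, stack.pixel_size_nm, strain_id="sepG-null")
stats = summarize_lengths(sample)
print(f"{stats.n} spores, mean length {stats.mean:.3f} um (sd {stats.sd:.3f})")

calls = [classify_rim_localization(
             extract_axial_profile(stack.channel("dna"), regions, int(lab)))
         for lab in regions.labels]
frac = rim_fraction(calls)
print(f"rim-localized DNA: {frac.percent:.0f}% "
      f"(95% CI {frac.ci_low_percent:.0f}-{frac.ci_high_percent:.0f}%, n={frac.n})")
```

prints

```
10 spores, mean length 0.974 um (sd 0.067)
rim-localized DNA: 80% (95% CI 49-94%, n=10)
```

i.e. the ten simulated spores (drawn at 0.96 ± 0.10 µm) measure 0.974 µm on
average, and 8 of the 10 — drawn with a 74% toroid probability — are called
rim-localized, with the wide interval reflecting n = 10.

The same stages are available as subcommands of the `sporoquant` CLI
(`simulate-chain`, `simulate-foci`, `simulate-fret`, `simulate-frap`,
`measure`, `profile`, `foci`, `coloc`, `fret`, `frap`, and config-driven
`run`), exchanging multichannel TIFFs and CSV tables.

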