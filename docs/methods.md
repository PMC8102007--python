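# Methods

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter for reproducing
its output.

## Image segmentation

The segmentation chain targets epinephrine-treated fish, in which pigment
granules are contracted to compact spots so individual cells are separable.

1. **Bright-outlier removal.** Iridophore glare appears as small near-white
   disks. Each pixel brighter than the median of its circular 25 px
   neighborhood by more than *t* = 50 grey units is replaced by that median.
   The operator names only its window and intent; the replace-if-brighter rule
   and *t* are our internals, chosen so small saturated artifacts are erased
   while cells (large, darker than background) are untouched. The operator is
   idempotent on outlier-free images, and *t* is configurable.
2. **Sauvola local threshold.** On the red channel (melanophores are dark in
   red; xanthophores and the pinkish skin are bright), the per-pixel threshold
   is T = m·(1 + k·(s/R − 1)) with m, s the mean and standard deviation of the
   square window of side 2r+1 (r = 25), k = 0.34, and dynamic range R = 128
   (the common 8-bit convention). Borders are replicate-padded. Pixels darker
   than T are foreground. The implementation uses integral images and is
   tested pixel-exact against direct per-window evaluation; on a constant
   image s = 0 gives T = 0.66·m and an empty mask. A square window was chosen
   over a circular one because it admits an exact integral-image
   implementation and an unambiguous oracle; both window radius and R are
   exposed.
3. **Components and size bands.** Connected components (8-connectivity)
   between 100 and 1500 px are melanophores; components of the inverted,
   clipped red-minus-blue difference image between 10 and 200 px are
   xanthophores. Centroids are unweighted means of component pixel coordinates
   (0-based pixel centers, x = column, y = row). The xanthophore channel
   arithmetic detects high (red − blue) as dark objects on the inverted
   difference; the source protocol's wording of the subtraction direction is
   internally inconsistent, and this reading is the one consistent with
   xanthophores being high-red/low-blue.
4. **Corrections.** Manual edits are consumed as add/remove lists; added
   cells become circles of diameter 15 px (area 177 px), the same convention
   used when correcting improperly segmented cells, so planted and corrected
   cells are commensurate.

## Pattern morphospace

Patterns are summarized on binary element masks: every pixel within 20 px of
a melanophore center (20 px approximates the average nearest-neighbor
distance, so cells of one stripe or spot fuse into one element). An
`expand_blur` variant (Gaussian σ = 5 px, rethreshold at 50%) fills residual
gaps to approximate natural cell edges; σ and the threshold are our choices,
as the source protocol states the expansion-and-blur step without parameters.
For images that cannot be segmented cell-wise there is a global threshold
chosen to hit a target foreground fraction (ties to the lower threshold).

DV variation is the standard deviation across rows of the row-mean grey
profile of the mask; AP variation is the column-wise reciprocal. The sample
(n−1) standard deviation is the default, with a population-SD switch, since
the convention used upstream is unstated. The morphospace coordinate
log₂(DV:AP) floors both terms at 0.5 grey units to avoid degenerate ratios on
near-empty patterns. Element statistics use 8-connected components, and
perimeter counts 4-adjacent foreground/background pixel edges (image borders
count as background) — exact integer arithmetic rather than a Crofton
estimate, so a 10×10 square has perimeter 40. Phenotype PCA standardizes
columns and eigendecomposes the correlation matrix; the share of variance per
component sums to 1, and signs are fixed so each component's
largest-magnitude loading is positive.

## Cell and motion metrics

Nearest-neighbor distances are same-class Euclidean distances (KD-tree,
verified against an all-pairs oracle). Median NN distance is reported only for
individuals with ≥ 10 cells of the class; aggregation across individuals uses
the median of per-individual medians. Densities are counts per ROI area;
pigment area (the 2-D area of contracted melanin) proxies melanin content.

Daily point sets are registered rigidly: candidate correspondences are point
pairs with matching inter-point distances (rigidity preserves distances),
each hypothesis is scored by inliers within 3 px, and the best is refined by
2-D Kabsch least squares on its inlier set; a fit requires ≥ 20% inliers.
Series are registered to the first frame by composing pairwise transforms.
Linking minimizes frame-to-frame distance under a 100 px/day cap; a track may
skip one day and reconnect within 2× the cap (the gap-closing distance is our
choice; the upstream protocol is silent). The default greedy nearest-pair
linker is deterministic and order-independent (ties broken by coordinates);
an optimal assignment variant (`method="optimal"`) is provided and agrees at
small n. Motion statistics include tracks spanning ≥ 7 days with ≤ 1 missing
day and report net displacement and the median per-day speed.

## Genetics

Backcross genotypes are coded 0/1 per transmitting parent: the F1 hybrid
parent's transmission segregates interspecific variants, the pure *kyathit*
parent's transmission segregates intraspecific variants over its two
haplotypes, and the two are scanned separately. Haley–Knott regression
regresses the phenotype on the expected genotype: observed codes where
genotyped and conditional expectations from the nearest flanking genotyped
markers under the Haldane mapping function where missing (markers with
missing data are retained by default; `drop_missing=True` reproduces the
stricter exclude-them convention). LOD = (n/2)·log₁₀(RSS₀/RSS₁), capped at
300 with a degenerate-fit flag when RSS₁ vanishes. Genome-wide thresholds are
the empirical (1−α) quantile (type-7 interpolation) of the maximum LOD over
phenotype permutations; a marker-wise Benjamini–Hochberg mode is available in
the F_ST scan, since "false discovery threshold" wording admits both
readings. Support intervals take the contiguous run of markers within 1.5 LOD
of the peak, extended one marker beyond on each side (conservative). Percent
variance explained is 100·(1 − RSS₁/RSS₀) at the peak marker.

Two-locus epistasis compares the four genotype combinations by one-way ANOVA,
the 2×2 interaction contrast m₁₁ − m₁₀ − m₀₁ + m₀₀ with its pooled-variance
standard error, and Tukey–Kramer all-pairs comparisons on the studentized
range, summarized as compact letters (insert-and-absorb; classes sharing a
letter are not significantly different). A variance-stabilizing transform
(e.g. ln of element counts) can be applied first.

Extreme-phenotype scans select the ⌈f·n⌉ lowest and highest individuals
(f = 0.035 by default; boundary ties broken by index). At n = 457 this gives
16 per tail; the published analysis this mirrors reports 18 per tail while
calling it 3.5%, a discrepancy the selection rule does not try to reproduce.
F_ST is the Weir–Cockerham (1984) two-population estimator; backcross
individuals contribute one transmitted allele each, so the haploid
mean-squares form applies: θ = (MSP − MSG)/(MSP + (n_c − 1)·MSG). The
estimator may be slightly negative under no differentiation and is not
clamped; monomorphic markers are reported missing. Permutation P values with
Benjamini–Hochberg adjustment flag significant markers (α = 0.01 by default).

## Synthetic data: what it emulates, and what it does not

Images emulate aligned, epinephrine-treated flank ROIs: melanophores as dark
filled disks (radius 7 px, Gaussian-perturbed by 10%, giving areas near the
15 px circle convention) tiling the dark elements of the layout on a jittered
lattice of pitch 24 px (near observed nearest-neighbor spacing); xanthophores
as orange disks (radius 4 px) tiling the light regions; a pinkish skin
background (190, 160, 155); and glare as near-white (≥ 245) disks of radius
1–3 px sprinkled to a target pixel fraction. The uniform layout spreads the
same cell complement the elements would hold evenly across the whole flank,
as in patternless fish. Identical seeds give bit-identical output.

Developmental series move cells either toward targets scattered about their
element's centroid ("spot_consolidate", up to the drift cap per day) or hold
them with a small jiggle ("stripe_hold", 10% of drift). Cells are physical
disks and may not overlap: blocked or arrived cells wobble in place at one
cell-diameter separation, which is what makes identity tracking well-posed
and matches the dense packing of spotted adults. New cells appear unpaired
(de novo differentiation) inside elements; losses are Poisson. No
quantitative appearance or loss rates are available from observation, so the
defaults (0/day) are free parameters, not calibrated values. The generator
does not attempt realistic iridophore textures, erythrophores, uncontracted
cell morphology, lighting gradients, or body growth/rescaling — passing tests
demonstrate correctness of the measurement chain on idealized cells, not
robustness to those real-world nuisances.

Backcross families simulate one recombinant gamete per parent per individual
as a Markov chain along each chromosome with Haldane switch probabilities
(no interference — the simplest standard model with a closed-form oracle,
r = (1 − e^(−2d/100))/2). Phenotype = mean + Σ additive effects + epistatic
terms (applied to one stated genotype combination) + Gaussian noise. The
default map is 25 chromosomes × 10 markers at 10 cM — a deliberately coarser
map than a real RAD-seq panel, dense enough that a planted locus is always at
a marker.

## Study conditions used in tests and the acceptance script

Simulated mapping designs mirror the real crosses in size: n = 158 for
single-QTL and epistasis analyses, n = 457 with 3.5% tails for the
extreme-phenotype scan. A planted additive QTL "explaining 15%" uses effect
a = 1 and residual SD chosen from a²/4 · (1 − f)/f. The epistasis model
shifts only the double stripe-allele class (means 5.5 vs 2.8 "elements",
residual SD 2.7, chosen to match the F ≈ 10 scale of the real four-class
comparison); the extreme-scan locus is major-effect (half the phenotypic
variance), the regime extreme sampling is designed for. Permutation
thresholds use 200 permutations in simulation batteries and 1000 in worked
examples; null calibration uses 200 families × 200 permutations in the test
suite (scaled from 1000), and the acceptance script uses 100 families and
50-simulation batteries. Morphospace batteries use 512×512 images, 20 seeds
per layout in the test suite and 10 in the acceptance script.

## Known limitations

- The greedy linker can differ from optimal assignment in dense, fast-moving
  fields; the optimal variant exists but both share the same cap heuristics.
- Compact-letter displays from the insert-and-absorb heuristic are the
  standard presentation but are not unique when the significance pattern is
  non-transitive.
- Sauvola window shape/R and the blur parameters of the element-mask variant
  are conventions, exposed as configuration, because the upstream protocol
  does not state them.
- The F_ST permutation P resolution is 1/(n_perm + 1); reaching
  Benjamini–Hochberg significance at α = 0.01 across hundreds of markers
  requires n_perm in the thousands.
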