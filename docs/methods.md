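# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic generators do and do not emulate,
and the design decisions taken where more than one reasonable convention
exists.

## Shell profiling ("nuclear circle analysis")

**Model.** For each segmented nucleus, every pixel is assigned the
Euclidean distance to the nearest pixel outside that nucleus (computed per
label, so touching neighbours count as exterior). Shells are iso-distance
layers one pixel wide: the contour layer — every mask pixel whose nearest
exterior pixel is one pixel unit away — is shell 0, and shell *k* collects
pixels with distance in (*k*, *k*+1] pixel units, i.e. `k = floor(d_px) − 1`.
The nominal depth of shell *k* is `k × pixel_size_um`. This realizes
"curves parallel to the nuclear periphery with decreasing perimeter" as
distance-transform level sets, which is reproducible and exact for
arbitrary star-convex and non-convex masks.

**Compartments.** The NP band is the pixel-count-weighted mean over shells
with depth strictly below `band_um` (default 1.5 µm; at 90 nm pixels that
is shells 0–16, the partial next shell being excluded — the boundary
convention shifts compartment means by under 2 % on realistic nuclei and is
config-exposed). The nucleoplasm is the weighted mean over all deeper
shells. Background (mean intensity of pixels farther than 2 µm from every
nucleus) is subtracted from the two compartment *means*, not per pixel, and
the per-nucleus ratio is `nucleoplasm_bgsub / np_bgsub`. Nuclei whose
deepest shell lies inside the band have no nucleoplasm and are flagged
invalid, as are nuclei with non-positive background-subtracted NP signal.

**Statistics.** One value per nucleus enters the statistics (ratios are
averaged per nucleus, never as a ratio of group means). NP vs nucleoplasm
within a group: paired *t*-test; between groups: Welch's *t*-test,
two-sided. Degenerate inputs (all paired differences zero) are flagged and
reported with p = 1 rather than NaN.

## Segmentation and background

Nuclei are segmented on the DNA channel: Otsu threshold, morphological
closing (radius 2 px), hole filling, area filter (default 20 µm²), optional
distance-transform watershed for touching nuclei, and exclusion of
border-touching nuclei by default (their periphery band is truncated). An
optional refinement dilates each mask (≤ 0.5 µm) to the ring where the
central-NUP channel's boundary intensity peaks, for stains in which the
pore signal sits slightly outside the chromatin edge; it is off by default
because the DNA mask alone is reproducible. Background estimation requires
pixels farther than an exclusion margin (default 2 µm) from every nucleus,
keeping perinuclear haze out of "areas with no cells".

## NPC density

Spots are thresholded (Otsu within the analysis mask), labeled with
8-connectivity (the ImageJ Particle Analyzer convention), filtered to
[`min_area_px`, `max_area_px`] (defaults 1 and 100; the generator's point
emitters occupy single pixels, hence the permissive lower bound) and
reported as count / mask area. Touching spots count once; watershed
splitting is deliberately not applied by default.

## Gene-level ChIP binding

**Counting.** Coordinates are 0-based half-open throughout (BED
convention; GFF3 is converted on read). Single-end reads are extended to
the estimated fragment length (default 300 bp) in the 5'→3' direction, and
a read is assigned to a gene iff the extended fragment's midpoint falls in
[start, end). Midpoint assignment avoids double counting at gene
boundaries inside broad enriched domains; an any-overlap mode is exposed.
A read can land in two overlapping genes, but contributes at most once per
gene.

**Binding call.** `bound ⇔ reads/kbp ≥ 17 AND reads/gene ≥ 100`, both
bounds inclusive, with `reads/kbp = count / (length_bp / 1000)`. The
thresholds are treated as given parameters.

**Differential binding.** Size factors are median-of-ratios over genes
positive in all samples. Dispersions are per-gene method-of-moments
estimates on normalized counts, pooled within conditions (the Poisson term
uses `mean(1/s)` so unequal library sizes do not bias the estimate),
floored at 10⁻⁸; optional shrinkage toward an `a₁/μ + a₀` trend is off by
default. The NB fit is a two-group mean model — exactly the NB GLM with
condition as the only covariate and `log s_j` offsets — solved per gene by
vectorized Newton–Raphson on the group log-mean (score
`Σ (y−μ)/(1+αμ)`, Fisher information `Σ μ/(1+αμ)`, steps clipped to ±5,
convergence 10⁻¹⁰). The Wald statistic is `log2FC / SE` with
`SE = sqrt(1/I_ref + 1/I_alt)/ln 2`.

**Wald reference distribution.** With unshrunken per-gene dispersions and
3 + 3 samples, the asymptotic normal reference is anticonservative
(observed type-I error ≈ 0.11 at α = 0.05 in simulation): genes whose
sample variance happens to be small get an underestimated dispersion and an
overstated *z*. The default therefore refers the statistic to a Student *t*
with the residual degrees of freedom (`n_samples − 2`), the standard
small-sample correction for estimated-variance Wald tests; this restores
type-I error to ≈ 0.05 in the same simulation and converges to the normal
as replication grows. `reference="normal"` restores the asymptotic
behaviour. P-values for genes with zero counts in a condition are
undefined (NaN) and excluded from BH adjustment, which is the plain
step-up formula capped at 1.

**Clustering.** The variance-stabilizing transform is
`log2(count/s + 1)`; distances are Euclidean between sample profiles and
linkage is complete. The scientific conclusions drawn from the tree are
structural (which samples bipartition together), not height-exact, because
the exact VST is package-specific.

## qPCR

Technical replicates with CT > 30 are excluded individually (the most
permissive reading of the CT ≤ 30 rule); remaining replicates are averaged
on the Ct scale before ΔCT (the standard Livak convention);
ΔΔCT = ΔCT − mean calibrator ΔCT per gene; fold = 2^−ΔΔCT. Targets whose
replicates are all excluded are flagged absent rather than dropped.
ChIP-qPCR folds are computed against the H3 immunoprecipitate of the same
gene, from either quantities (ratio) or Cts (2^−ΔCt); fold > 1 (strict) is
the binding flag. Expression folds are log-transformed for statistics
(one-sample *t* vs the calibrator, Welch between groups); ChIP-qPCR folds
are square-root transformed, matching the source conventions.
Amplification-efficiency correction (Pfaffl) is out of scope.

## Morphometry

A myotube is a cell with ≥ 2 nuclei (config-exposed; the literature does
not fix the threshold). The fusion index is fused nuclei / total nuclei;
pooling images pools counts. Width from a mask is twice the maximum of the
Euclidean distance transform (the largest inscribed circle, centred on the
medial axis), which agrees with a manual perpendicular line at the widest
point to within one pixel and is rotation-invariant at that tolerance;
manual measurement tables remain the primary input path.

## Synthetic generators

All generators are pure functions of (spec, seed): identical inputs give
bit-identical outputs (per-nucleus substreams come from spawned seed
sequences, so one nucleus's retries do not perturb the next).

* **Image fields.** Nuclei are ellipses (axis ratio 0.9–1.1) with a
  low-order radial Fourier perturbation (modes 2–4, total amplitude
  ≤ 10 % of radius): non-circular but star-convex, so the distance
  transform is exercised without pathological shapes. Defaults emulate
  confocal imaging of C2C12 nuclei: 90 nm pixels, 5 ± 0.5 µm radius, a
  1.5 µm rim at 10 000 AU, background 1000 AU, additive Gaussian noise at
  5 % of rim intensity (Poisson/gain noise available). The rim band is
  defined by the same shell rule the analysis uses, so generated truth and
  recovered ratio share one coordinate convention. Placement is
  non-overlapping by default with a 4 px minimum gap (so distinct nuclei
  survive morphological closing); failure after 300 retries per nucleus
  raises an explicit error. Optional nucleoli (dark interior disks) are
  off by default. Not emulated: 3-D structure, PSF blur, chromatin
  texture, intensity gradients — so passing recovery tests demonstrates
  correctness of the measurement chain, not robustness to every real-image
  artifact.
* **NPC fields.** The spot count is Poisson(density × area); spots are
  single-pixel emitters placed uniformly in the mask under a
  no-8-adjacency constraint. NPCs are physical complexes that cannot
  overlap; without the constraint, unconstrained placement at 10 spots/µm²
  and 90 nm pixels would merge roughly half of all spots into joint
  components and no counter could be unbiased.
* **Count tables.** Gene lengths are log-normal (median ≈ 20 kb, as for
  mouse genes). Means follow baseline × bound-enrichment × size factor ×
  2^(lfc·[MT]); counts are gamma-Poisson (exactly Poisson at dispersion 0).
  Defaults: 2000 genes, 3 samples per condition with alternating
  TPR-N/TPR-C antibody labels, baseline 50, dispersion 0.1, 30 % bound at
  8-fold enrichment, 10 % differential at log2FC 2.
* **Ct tables.** Target Ct = reference Ct + gene offset − log2(fold) +
  noise (sd 0.2 by default, triplicates); the calibrator group encodes
  fold 1, so the noiseless ΔΔCT round trip is exact by construction.

## Validation problem sizes

The acceptance checks use sizes chosen to make Monte-Carlo error small
relative to the tolerances while keeping a laptop-scale run: ~50 nuclei
per intensity regime (5 fields × 10 nuclei, 800×800 px), 100 spot fields
of ~100 µm² per density, 2000 genes for calibration (type-I error) with
power measured on ~200 differential genes simulated at the default 10 %
differential fraction (a global fold in *all* genes would be absorbed by
median-of-ratios normalization and is unidentifiable by design), 100
clustering simulations, 10⁴ random p-vectors for the BH formula check, and
exhaustive brute-force oracles for shell binning and read counting on
≥ 1000 and 100 random instances respectively.

## Known limitations

* 2-D only: one mid-section per nucleus, no z-aggregation; peripheral
  z-sections for NPC counting are treated as given.
* No nucleolus or interior-structure exclusion in the nucleoplasm mean.
* The NB model has no log-fold-change shrinkage; estimates for weakly
  covered genes are noisy (their p-values are calibrated, their point
  estimates are not moderated).
* The VST is not height-identical to package-specific transforms used
  elsewhere; only clustering structure should be interpreted.
* Binding thresholds (17 reads/kbp, 100 reads/gene) are inputs, not
  derived; no input-track subtraction or peak calling is performed.
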