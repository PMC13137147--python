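# Methods

This note documents the models, parameter choices, and limitations of the
pipeline. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted beyond what the
code measures.

## Segment transcriptomics (GeoMx-style)

**Probe QC.** For every gene with ≥3 probes, the log of each probe's
geometric-mean count across segments is tested with a two-sided Grubbs
outlier test at α = 0.01, one iteration; the critical value is
G = ((n−1)/√n)·√(t²/(n−2+t²)) with t the (1 − α/2n) quantile of t(n−2).
Zero-variance probe sets are never flagged. Probes are excluded before the
gene-level collapse (geometric mean of retained probes, zeros floored at 1
inside the log); the alternative order (collapse first) is not supported.

**Limit of quantification.** Per segment,
LOQ = geomean(negatives) · geoSD(negatives)^2, clamped below at 2 counts,
with negative-probe zeros replaced by 1 before the log. This is the
NanoString-guideline form; the exponent (2 SD) and floor are exposed as
arguments. A gene is *detected* in a segment iff its count strictly
exceeds the segment LOQ.

**Filters.** Segments need ≥100 nuclei (inclusive: exactly 100 passes).
Genes detected in fewer than `min_frac · N` segments are excluded with a
*strict* inequality, which reproduces the printed equivalence that 5% of
126 segments excludes genes detected in ≤6 segments (6 < 6.3).

**Q3 normalization.** Per segment, Q3 is the 75th percentile of the
detected genes' counts; the scale factor is geomean(all Q3)/Q3, which
equalizes detected-gene third quartiles exactly, then values are
log₂(count·factor + 1). The +1 pseudocount keeps zeros finite and is
standard practice; it is not part of the Q3 definition itself.

**Clustering.** Segments are clustered on the top-20% most variable genes
(variance of log₂ expression, stable tie-break) via a shared-nearest-
neighbour graph (k = min(10, n−1), Jaccard weights) and Louvain
(igraph multilevel). The resolution is binary-searched until exactly two
communities exist, because the biology of interest is a two-way
inflamed/non-inflamed split; the cluster with higher mean expression of a
configurable immune marker list (defaults B2M, HLA-A/B/E, C1S, C1R, TRAC)
is named "inflamed". Samples take the majority label of their segments;
exact ties are reported as "tied", not broken arbitrarily.

**Differential expression.** Per feature, a linear mixed model
`y ~ group + (1 | sample)` is fitted by REML (statsmodels MixedLM, default
EM+BFGS optimizer) and the group coefficient tested with a Wald z test;
p-values are BH-adjusted. The random intercept absorbs the correlation of
multiple segments per tumor. Singular fits fall back to OLS and are
flagged. Choices and their measured consequences: the Wald z on the REML
fit gives a null type-I error of ≈0.05–0.06 in the calibration simulation
(10 samples × 6 segments, sample SD 0.3, residual SD 0.5, 2,000 features);
the quasi-Newton default optimizer matters — an L-BFGS fit left the z
statistics over-dispersed (SD ≈ 1.11) and the type-I error at ≈0.08.

**ssGSEA.** For one sample, genes are ranked by expression (descending,
ties broken by stable input order) with rank statistic N…1; the score is
Σᵢ (P_in(i) − P_out(i)) where P_in is the ECDF of in-set genes weighted by
|rank|^α (α = 0.25, the method's canonical default) and P_out the
unweighted ECDF of out-of-set genes. No sample-wise rescaling is applied.
The implementation is verified exactly (≤1e−10) against a literal
running-sum oracle on all 56 three-gene sets over an eight-gene universe.
Differential pathway selection applies the same mixed model to score
matrices and keeps the top floor(10% · P) pathways by adjusted p with an
|effect| tie-break; ranking by effect size is available via an argument
(the two orderings correspond to two defensible readings of the original
workflow).

## MALDI-MSI preprocessing

**Baseline.** TopHat = signal minus its morphological opening with a flat
element of 200 data points (the native unit of morphological filters),
clipped at 0; idempotent, verified against a brute-force sliding
min-then-max oracle.

**Tissue segmentation.** Bisecting k-means on log TIC (one bisection by
default); the leaf with the highest mean TIC is on-tissue. Degenerate
all-identical input labels everything on-tissue with a warning.

**Peak picking.** On the arithmetic mean of baseline-corrected on-tissue
spectra. Noise is the windowed median absolute deviation (501 points,
scaled 1.4826), floored at half the global MAD because the windowed
estimate collapses at the array edges; signal height is measured above the
windowed median (the morphological correction leaves a small positive
pedestal on averaged spectra). Local maxima with height/noise **strictly**
greater than 9 become peaks. Apex m/z is refined by three-point quadratic
interpolation of log intensities, which is exact for Gaussian peaks and
necessary because the synthetic TOF axis (constant relative spacing
4×10⁻⁵, ≈3 samples per FWHM at resolving power 10,000) would otherwise
quantize apexes at the tens-of-ppm level.

**Calibration.** Reference masses are matched to the nearest picked peak
within 100 ppm; signed ppm errors are regressed on m/z (ordinary least
squares, affine model) and the axis corrected as m/(1 + err(m)/10⁶). With
<2 matches the identity model is returned with a warning. On planted
affine drifts within ±50 ppm the residual median |error| is ≈0.01–0.03 ppm.

**Matrix-peak removal.** Ion images are TIC-normalized and correlated with
the principal [NEDC+Cl]⁻ image **over all pixels** — the off-tissue pixels
carry the discriminating signal, and restricting to on-tissue pixels
introduces compositional correlations that can falsely remove analyte
peaks. Peaks with Pearson r ≥ 0.5 are removed (threshold exposed; the
planted-data separation is insensitive across ≈0.3–0.7); zero-variance
images get r = 0 and are retained. The matrix is then restricted to
on-tissue pixels; row sums carry over from the TIC step, so they are ≤1
after matrix columns are dropped (zero-TIC pixels are excluded and
reported).

## Annotation

ppm error is (observed − theoretical)/theoretical × 10⁶. Adducts are
[M−H]⁻ (−1.00727646 Da) and [M+Cl]⁻ (+34.96885268 Da, ³⁵Cl); the electron
mass (<0.6 mDa) is neglected, consistently on both the generator and
matcher side. All tolerances are inclusive (|ppm| ≤ tol). Tier 1 matches
the calibrated TOF axis against a metabolite table at ±30 ppm; tier 2
matches HRAM peak lists against a lipid table restricted to PA/PE/PI/PS/PG
at ±3 ppm. Manual curation is replaced by a deterministic surrogate that
enforces the single-species contract: peaks with >1 candidate species are
dropped entirely; when one species matches via both adducts, [M−H]⁻ is
preferred. Curated assignments transfer to TOF peaks within ±40 ppm of
exactly one annotated HRAM peak; several TOF peaks may inherit the same
annotation, but a TOF peak near two species is dropped.

The packaged reference tables are *synthetic* mini-snapshots (152 lipids
from closed-form glycerophospholipid formula arithmetic, verified against
literature deprotonated masses; 39 common metabolites), not copies of any
licensed database. Masses are derived from formulas at load time via
pyteomics, so stored masses can never drift from their formulas.

## Region-level MSI analysis

Artifact (hole/necrosis-like) pixels are removed by k-means (k = 5) on
normalized profiles, excluding clusters whose mean raw TIC falls below 0.2
of the median cluster TIC — the original criterion was visual, so the
threshold is a package choice and exposed. Pixels are clustered on log1p
intensities (kNN k = 15, Louvain at resolution 1.0; the community count is
data-driven, not forced). Clusters take the majority tumor/stroma label of
a labeled reference subset (the histology stand-in); clusters without
labeled overlap are excluded, so the reference must cover the section —
the drivers use a uniform pixel grid subsample. Region means are
arithmetic means per (sample, region, peak). Tumor vs stroma is a paired
two-sided Student t test across samples with BH correction; inflamed vs
non-inflamed is an unpaired two-sided Student t test per region on raw
p-values (no adjustment column, by design). Equal-variance (Student)
rather than Welch tests are used throughout. Zero-variance degeneracies
are deterministic: all-zero differences give p = 1; equal non-zero
differences give the significant limit (p = smallest positive float).

## qPCR

Technical triplicates are averaged per (gene, condition); incomplete
triplets warn and use the available wells. Per housekeeping gene h,
ΔCt = Ct_target − Ct_h, ΔΔCt = ΔCt_condition − ΔCt_mock, FC = 2^(−ΔΔCt);
fold changes (not ΔΔCt) are averaged across the two housekeeping genes
with a sample SD (n−1). Amplification efficiency is fixed at 2; no
standard-curve correction. The reference condition's fold change is
exactly 1 by construction, and the whole computation is invariant to
adding a constant to all Ct values.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions used by every test:

* **Counts**: negative binomial (dispersion 0.08) with log-normal gene
  means, 10% pure-background genes at the negative-probe level, a
  multiplicative per-sample random effect (log₂ SD 0.3 by default), a
  planted log₂ fold change (default 1.0) on 10% of expressed genes in
  inflamed segments, and 15 samples × 2–5 ROIs × {tumor, stroma}. The
  broader detected-gene repertoire of inflamed segments is emulated by
  extra dropout (rate 0.12) in non-inflamed segments confined to the
  bottom quintile of baseline means — the band around the LOQ — so that
  detectability changes while bulk log-count means stay balanced (<0.1)
  when the planted effect is zero. No count model is published for this
  platform's probe counts; dispersion and library-size distributions are
  package choices, not fits to real data.
* **Pixel spectra**: profile mode on a geometric m/z axis (60–1200,
  relative step 4×10⁻⁵), Gaussian peaks at TOF-like resolving power
  10,000 (FWHM), a smooth exponential baseline, white noise, matrix ions
  sharing a spatial pattern and concentrated off-tissue, and an affine
  ppm drift a + b·m applied to every observed center. Spectra are
  generated lazily per pixel from spawned seed sequences (a 64×64 grid of
  ~75k-point profiles is never held in memory). An elliptical tissue with
  a tumor core / stroma rim stands in for real morphology; isotope
  patterns, detector saturation, and spectral interference are not
  simulated, so passing tests demonstrate correctness of the processing
  logic, not robustness to every instrumental artifact.
* **Cohort matrices**: a fast path emits per-sample TIC-normalized
  pixels×peaks matrices directly (13 samples, 6 inflamed / 7 non-inflamed,
  region enrichment 2×, log-normal pixel noise CV 0.25) for region-level
  statistics and clustering at cohort scale without the spectral layer.
* **HRAM lists**: stick spectra of the planted species at Gaussian ppm
  error (SD ≤ 3 ppm, hard-capped), with optional decoys placed ≥50 ppm
  from every reference ion of either adduct.
* **Ct tables**: stable housekeeping genes and one induced positive
  control whose Ct drops by log₂(fold) under treatment; one noise scale
  governs both condition-level and replicate variation.

All generators require an explicit seed and are byte-reproducible; the
problem sizes used by the tests and the acceptance script (800–2,000
genes, 16×16 to 64×64 grids, 10-seed repetitions) were chosen so the whole
validation runs comfortably on a laptop-class single core.

## Known limitations

* The LMM uses a Wald z test; small-sample degrees-of-freedom corrections
  (Satterthwaite/Kenward-Roger) are not implemented.
* Louvain resolution search assumes the target community count is
  reachable on the SNN graph; pathological graphs raise with diagnostics.
* Matrix-peak removal assumes the principal matrix ion was picked; if it
  is absent from the axis the pipeline stops rather than guessing.
* Transfer annotation treats all ions as singly charged and ignores
  isotopologues; MS/MS-level identification is out of scope.
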