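# chordomics

Spatial multi-omics analysis of chordoma immunogenicity, rebuilt as a
tested, reusable Python pipeline and exercised end-to-end on synthetic data
with planted ground truth.

Chordomas are rare bone tumors of notochordal origin driven by the
transcription factor TBXT (brachyury). Profiling their tumor–stroma
interface combines three assays, and this package implements the
computational side of each:

* **Digital spatial profiling (GeoMx-style)** — segment-level whole
  transcriptome counts from tumor (pan-cytokeratin⁺) and stroma segments of
  regions of interest (ROIs). Processing follows the NanoString guideline:
  Grubbs probe QC, a per-segment limit of quantification (LOQ) from
  negative probes, `LOQ = geomean(neg) · geoSD(neg)²` floored at 2, a 5%
  detection filter, Q3 (third-quartile) normalization, log₂. Analysis:
  top-20% variable genes, shared-nearest-neighbour Louvain clustering into
  inflamed vs non-inflamed segments, differential expression by a linear
  mixed model `expr ~ group + (1 | sample)` (REML, Wald z,
  Benjamini–Hochberg), single-sample GSEA (weighted ECDF difference,
  α = 0.25) with top-10% differential pathway selection, and majority-vote
  sample classification.
* **MALDI-TOF mass spectrometry imaging** — per-pixel negative-mode spectra
  (NEDC matrix, m/z 60–1200). Preprocessing: TopHat (morphological opening)
  baseline subtraction (width 200 points), bisecting k-means on/off-tissue
  segmentation on log TIC, peak picking on the mean on-tissue spectrum at
  SNR > 9 (windowed-MAD noise), internal calibration with an affine
  ppm-error model `err(m) = a + b·m`, TIC normalization, and matrix-peak
  removal by ion-image Pearson correlation (r ≥ 0.5) with the principal
  [NEDC+Cl]⁻ ion. Annotation is two-tier and adduct-aware ([M−H]⁻,
  [M+Cl]⁻): metabolites on the TOF axis at ±30 ppm; lipids (PA/PE/PI/PS/PG)
  on high-resolution accurate-mass (HRAM) peak lists at ±3 ppm, curated to
  single species and transferred to the TOF axis at ±40 ppm. Region-level
  analysis: Louvain pixel clustering, cluster→region assignment against a
  histology mask, per-sample region means, paired tumor-vs-stroma t tests
  (BH-corrected) and unpaired inflamed-vs-non-inflamed t tests (raw p).
* **qPCR** — relative quantification by 2^(−ΔΔCt) with dual housekeeping
  normalization (HPRT1, TBP), fold changes averaged across the two
  housekeeping genes (mean ± SD).

A first-class synthetic-data module generates every input with known
ground truth (planted fold changes, lipid species with region enrichment,
matrix peaks, an affine ppm mass drift, induced qPCR fold changes), so all
downstream claims are tested against planted answers.

## Layout

```
src/chordomics/      library: synthetic, geomx_preprocess, geomx_analysis,
                     msi_preprocess, msi_annotation, msi_analysis, qpcr,
                     references, stats, graph, io
analysis/            numbered narrative drivers (simulate → GeoMx → MSI → qPCR)
scripts/acceptance.py  recomputes the headline numbers from scratch
tests/               pytest suite with independent oracles
docs/methods.md      model assumptions, parameter choices, limitations
```

## Worked example

```bash
python analysis/01_simulate_inputs.py
python analysis/02_geomx_expression.py
```

prints, for a 15-sample simulation (seed 20260930):

```
GeoMx: 2345 probes x 96 segments (48 ROIs, 46 inflamed segments), 180 planted DE genes, 200 background genes
Preprocessing: 3 probes excluded by Grubbs QC, 1779 genes retained in 96 segments (0 segments dropped)
Clustering: top 20% = 355 variable genes; 2 Louvain clusters at resolution 1; ARI vs planted inflammation = 1.00
Mixed-model DE: 231 genes at q<0.05; 99% of planted DE genes recovered
ssGSEA: top 10% = 5 pathways; 5/5 planted-active pathways among them
Samples: 8 inflamed, 7 non-inflamed, 0 tied; nuclei t-test t=38.09, p=6.2e-59
```

i.e. the probe QC catches the planted outlier probes, the detection filter
keeps expressed genes and discards background, clustering recovers the
planted inflammation labels exactly (adjusted Rand index 1.0), the mixed
model recovers 99% of the planted differentially expressed genes, and all
five planted-active pathways land in the top-10% selection.
`analysis/03_msi_lipidomics.py` and `analysis/04_qpcr_induction.py` do the
same for the imaging and qPCR arms (calibration residual ~0.01 ppm against
a planted −10 + 0.045·m ppm drift; B2M induction recovered at ~4-fold with
TBXT isoforms flat).

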