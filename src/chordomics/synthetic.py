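"""Synthetic data generators with planted ground truth.

Every pipeline input — segment-level probe counts, pixel-resolved MALDI
spectra, high-resolution accurate-mass (HRAM) peak lists, and qPCR Ct
tables — can be generated here with a known answer, so each downstream
stage is testable without patient data.

Design of the emulation (see docs/methods.md for the full account):

* Probe counts are negative binomial with log-normal gene means, a
  multiplicative per-sample random effect, and a planted log2 fold change
  on a designated gene subset in "inflamed" segments.  Non-inflamed
  segments additionally drop out low-expressed genes more often, so the
  detected-gene repertoire is broader in inflamed segments.
* MALDI-TOF pixel spectra are profile-mode: Gaussian peaks at adduct m/z
  of planted species (TOF-like resolving power 10,000 at FWHM) on a smooth
  baseline with white noise, plus matrix-derived peaks that are intense
  off-tissue and spatially correlated with the principal matrix ion
  [NEDC+Cl]-.  All observed m/z carry a planted affine ppm drift.
* HRAM peak lists are stick spectra of the same species at <=3 ppm error,
  optionally with decoy peaks >=50 ppm away from every true ion.
* Ct tables have stable housekeeping genes and one induced positive
  control whose Ct drops by log2(fold) under treatment.

All generators require an explicit integer seed and are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .references import (
    ADDUCTS,
    adduct_mz,
    nedc_principal_mz,
    load_lipid_references,
    load_metabolite_references,
)

# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every synthetic dataset."""

    segment_compartment: dict = field(default_factory=dict)   # segment -> tumor/stroma
    segment_inflamed: dict = field(default_factory=dict)      # segment -> bool
    sample_of_segment: dict = field(default_factory=dict)     # segment -> sample id
    de_genes: dict = field(default_factory=dict)              # gene -> planted log2FC
    background_genes: list = field(default_factory=list)      # genes planted as pure background
    outlier_probes: list = field(default_factory=list)        # probes planted as Grubbs outliers
    pathway_truth: dict = field(default_factory=dict)         # pathway -> active flag
    lipid_species: list = field(default_factory=list)         # dicts: name, mass, adduct, mz, region
    matrix_peaks: list = field(default_factory=list)          # planted matrix m/z (first = principal)
    mass_drift: tuple = (0.0, 0.0)                            # ppm drift = a + b*mz
    tissue_mask: np.ndarray | None = None                     # pixel -> on-tissue
    region_mask: np.ndarray | None = None                     # pixel -> tumor/stroma/''
    ct_truth: dict = field(default_factory=dict)              # gene -> true fold change

    def validate(self) -> None:
        for seg in self.segment_compartment:
            if seg not in self.sample_of_segment or seg not in self.segment_inflamed:
                raise ValueError(f"segment {seg} missing sample or inflammation label")
        for g, fc in self.de_genes.items():
            if not np.isfinite(fc):
                raise ValueError(f"non-finite planted effect for {g}")


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("an explicit integer seed is required (reproducibility)")
    return np.random.default_rng(int(seed))


# ---------------------------------------------------------------------------
# GeoMx-style probe counts
# ---------------------------------------------------------------------------


@dataclass
class ProbeCountMatrix:
    """Raw probe x segment counts plus probe annotation.

    ``counts`` rows are probe ids; ``probe_to_gene`` maps each probe to its
    gene (negative probes map to the pseudo-gene "NegProbe");
    ``is_negative`` flags the negative-control probes used for the limit of
    quantification.
    """

    counts: pd.DataFrame
    probe_to_gene: pd.Series
    is_negative: pd.Series

    def __post_init__(self):
        if not self.counts.index.equals(self.probe_to_gene.index) or not (
            self.counts.index.equals(self.is_negative.index)
        ):
            raise ValueError("probe annotation index must match count rows")
        if not bool(self.is_negative.any()):
            raise ValueError("at least one negative probe is required")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")

    def subset_probes(self, probes) -> "ProbeCountMatrix":
        return ProbeCountMatrix(
            self.counts.loc[probes],
            self.probe_to_gene.loc[probes],
            self.is_negative.loc[probes],
        )

    def subset_segments(self, segments) -> "ProbeCountMatrix":
        return ProbeCountMatrix(
            self.counts[list(segments)], self.probe_to_gene, self.is_negative
        )


def generate_geomx(
    n_samples: int = 15,
    rois_per_sample: tuple[int, int] = (2, 5),
    n_genes: int = 2000,
    n_neg_probes: int = 25,
    effect_log2fc: float = 1.0,
    sample_sd: float = 0.3,
    seed: int | None = None,
    *,
    background_frac: float = 0.10,
    de_frac: float = 0.10,
    dispersion: float = 0.08,
    noninflamed_dropout: float = 0.12,
    multiprobe_frac: float = 0.04,
    n_outlier_probes: int = 3,
) -> tuple[ProbeCountMatrix, pd.DataFrame, GroundTruth]:
    """Generate a probe count matrix, segment metadata, and ground truth.

    Each sample contributes 2-5 regions of interest (ROIs); each ROI is
    captured in two illumination passes, one tumor and one stroma segment,
    so the segment count is exactly twice the ROI count.  A random subset
    of genes is shifted by ``effect_log2fc`` (log2 scale) in inflamed
    segments; each sample carries a multiplicative random effect with
    log2-scale sd ``sample_sd``.

    Returns
    -------
    (ProbeCountMatrix, segment metadata DataFrame, GroundTruth)
    """
    rng = _require_seed(seed)
    if n_samples <= 0 or n_genes <= 0 or n_neg_probes <= 0:
        raise ValueError("dimensions must be positive")
    lo, hi = rois_per_sample
    if lo < 2 or hi > 5 or lo > hi:
        raise ValueError("rois_per_sample must lie within 2..5")
    if not np.isfinite(effect_log2fc):
        raise ValueError("effect_log2fc must be finite")

    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_bg = int(round(background_frac * n_genes))
    bg_idx = rng.choice(n_genes, size=n_bg, replace=False)
    is_bg = np.zeros(n_genes, bool)
    is_bg[bg_idx] = True

    # Baseline per-gene means: expressed genes log-normal well above the
    # negative-probe background; background genes at the negative level.
    neg_mu = 4.0
    base_mean = np.where(
        is_bg,
        rng.uniform(0.6, 1.1, n_genes) * neg_mu,
        np.exp(rng.normal(np.log(60.0), 1.1, n_genes)),
    )

    expressed_idx = np.flatnonzero(~is_bg)
    n_de = int(round(de_frac * len(expressed_idx)))
    de_idx = rng.choice(expressed_idx, size=n_de, replace=False)
    de_mask = np.zeros(n_genes, bool)
    de_mask[de_idx] = True

    # Segment layout: per sample, 2..5 ROIs x {tumor, stroma}; inflammation is
    # an ROI-level property, biased by a per-sample propensity.
    gt = GroundTruth(mass_drift=(0.0, 0.0))
    seg_ids, meta_rows = [], []
    sample_propensity = rng.permutation(
        np.r_[np.full(n_samples // 2, 0.8), np.full(n_samples - n_samples // 2, 0.2)]
    )
    for s in range(n_samples):
        sample = f"S{s + 1:02d}"
        n_roi = int(rng.integers(lo, hi + 1))
        for r in range(n_roi):
            roi = f"{sample}_ROI{r + 1}"
            inflamed = bool(rng.random() < sample_propensity[s])
            for comp in ("tumor", "stroma"):
                seg = f"{roi}_{comp}"
                seg_ids.append(seg)
                gt.segment_compartment[seg] = comp
                gt.segment_inflamed[seg] = inflamed
                gt.sample_of_segment[seg] = sample
                nuclei = int(rng.poisson(420 if inflamed else 260))
                meta_rows.append(
                    dict(
                        segment_id=seg,
                        sample_id=sample,
                        roi_id=roi,
                        compartment=comp,
                        nuclei=nuclei,
                        area_mm2=float(np.round(rng.uniform(0.05, 0.4), 4)),
                    )
                )
    meta = pd.DataFrame(meta_rows).set_index("segment_id", drop=False)
    n_seg = len(seg_ids)

    sample_ids = sorted({v for v in gt.sample_of_segment.values()})
    sample_effect = {
        sm: 2.0 ** rng.normal(0.0, sample_sd) for sm in sample_ids
    }
    inflamed_vec = np.array([gt.segment_inflamed[s] for s in seg_ids])
    seg_factor = np.array([sample_effect[gt.sample_of_segment[s]] for s in seg_ids])

    mu = base_mean[:, None] * seg_factor[None, :]
    mu = mu * np.where(
        de_mask[:, None] & inflamed_vec[None, :], 2.0 ** effect_log2fc, 1.0
    )

    r_nb = 1.0 / dispersion
    p_nb = r_nb / (r_nb + mu)
    counts = rng.negative_binomial(r_nb, p_nb)

    # Broader detected repertoire in inflamed segments: genes in the
    # background-proximal band (bottom quintile of baseline means, i.e. the
    # ones that hover around the LOQ) drop out more often in non-inflamed
    # segments.  Confining dropout to this band changes detectability
    # without materially shifting bulk log-count means.
    near_background = base_mean < np.quantile(base_mean, 0.20)
    dropout_p = np.where(
        near_background[:, None] & ~inflamed_vec[None, :], noninflamed_dropout, 0.0
    )
    counts = np.where(rng.random(counts.shape) < dropout_p, 0, counts)

    # Probes: most genes one probe; a few genes get 5 probes whose counts are
    # noisy replicates of the gene draw; a handful of probes are planted as
    # gross outliers for the Grubbs QC to catch.
    n_multi = int(round(multiprobe_frac * n_genes))
    multi_idx = set(rng.choice(n_genes, size=n_multi, replace=False).tolist())
    probe_rows, probe_ids, probe_gene = [], [], []
    for gi, g in enumerate(genes):
        if gi in multi_idx:
            for pi in range(5):
                noise = rng.normal(1.0, 0.08, n_seg)
                probe_rows.append(np.maximum(0, np.round(counts[gi] * noise)).astype(int))
                probe_ids.append(f"{g}_p{pi + 1}")
                probe_gene.append(g)
        else:
            probe_rows.append(counts[gi])
            probe_ids.append(f"{g}_p1")
            probe_gene.append(g)
    probe_mat = np.vstack(probe_rows)

    multi_probe_ids = [p for p, g in zip(probe_ids, probe_gene)
                       if g in {genes[i] for i in multi_idx}]
    outliers = rng.choice(len(multi_probe_ids), size=min(n_outlier_probes, len(multi_probe_ids)),
                          replace=False)
    outlier_probes = [multi_probe_ids[i] for i in outliers]
    pidx = {p: i for i, p in enumerate(probe_ids)}
    for p in outlier_probes:
        probe_mat[pidx[p]] = np.maximum(1, probe_mat[pidx[p]] * 12)

    neg_ids = [f"NegProbe_p{i + 1}" for i in range(n_neg_probes)]
    neg_counts = rng.negative_binomial(
        1.0 / 0.15, (1.0 / 0.15) / (1.0 / 0.15 + neg_mu * seg_factor[None, :]),
        size=(n_neg_probes, n_seg),
    )

    all_ids = probe_ids + neg_ids
    counts_df = pd.DataFrame(
        np.vstack([probe_mat, neg_counts]), index=all_ids, columns=seg_ids
    )
    probe_to_gene = pd.Series(
        probe_gene + ["NegProbe"] * n_neg_probes, index=all_ids, name="gene"
    )
    is_negative = pd.Series(
        [False] * len(probe_ids) + [True] * n_neg_probes, index=all_ids, name="is_negative"
    )

    gt.de_genes = {genes[i]: float(effect_log2fc) for i in sorted(de_idx)}
    gt.background_genes = [genes[i] for i in sorted(bg_idx)]
    gt.outlier_probes = outlier_probes
    gt.validate()
    return ProbeCountMatrix(counts_df, probe_to_gene, is_negative), meta, gt


# ---------------------------------------------------------------------------
# MALDI-MSI pixel spectra
# ---------------------------------------------------------------------------

MZ_MIN, MZ_MAX = 60.0, 1200.0
#: relative spacing of the geometric profile m/z axis (~3 samples per FWHM
#: at resolving power 10,000)
AXIS_REL_STEP = 4.0e-5
RESOLVING_POWER = 10_000.0
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def profile_mz_axis(mz_min: float = MZ_MIN, mz_max: float = MZ_MAX,
                    rel_step: float = AXIS_REL_STEP) -> np.ndarray:
    """Geometrically spaced profile axis (constant relative spacing)."""
    n = int(np.ceil(np.log(mz_max / mz_min) / np.log1p(rel_step))) + 1
    return mz_min * (1.0 + rel_step) ** np.arange(n)


def _smooth_field(rng: np.random.Generator, w: int, h: int, scale: float = 6.0) -> np.ndarray:
    """Spatially coherent positive random field on a w x h grid (flattened)."""
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.normal(size=(h, w)), sigma=scale, mode="nearest")
    f = (f - f.min()) / max(float(np.ptp(f)), 1e-12)
    return (0.5 + f).ravel()


@dataclass
class MsiDataset:
    """Lazily generated collection of profile-mode pixel spectra.

    Spectra are regenerated deterministically per pixel from a spawned seed
    sequence, so the full grid never needs to be held in memory.  Pixel
    ``i`` corresponds to grid coordinate ``coords[i] = (x, y)``.
    """

    mz: np.ndarray
    coords: np.ndarray                 # n_pixels x 2 (x, y)
    peak_centers: np.ndarray           # observed (drifted) centers, all planted ions
    peak_sigma: np.ndarray             # Gaussian sigma per planted ion (Da)
    amplitudes: np.ndarray             # n_pixels x n_ions
    baseline_shape: np.ndarray         # shared baseline curve on the axis
    baseline_scale: np.ndarray         # per-pixel baseline multiplier
    noise_sd: float
    seed: int

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    def spectrum(self, i: int) -> np.ndarray:
        """Intensity vector of pixel ``i`` on the shared m/z axis."""
        child = np.random.default_rng(
            np.random.SeedSequence([self.seed, 7919, int(i)])
        )
        y = self.baseline_shape * self.baseline_scale[i]
        amps = self.amplitudes[i]
        mz = self.mz
        for c, s, a in zip(self.peak_centers, self.peak_sigma, amps):
            if a <= 0:
                continue
            j0, j1 = np.searchsorted(mz, [c - 6 * s, c + 6 * s])
            if j1 > j0:
                y[j0:j1] += a * np.exp(-0.5 * ((mz[j0:j1] - c) / s) ** 2)
        if self.noise_sd > 0:
            y = y + child.normal(0.0, self.noise_sd, mz.size)
        return np.maximum(y, 0.0)

    def iter_spectra(self):
        for i in range(self.n_pixels):
            yield i, self.spectrum(i)


def _select_species(rng: np.random.Generator, n_species: int,
                    min_sep_ppm: float = 120.0) -> list[dict]:
    """Draw mutually mass-separated species (lipids + a few metabolites)
    from the packaged reference tables, with an adduct each."""
    lip = load_lipid_references()
    met = load_metabolite_references()
    n_met = max(2, n_species // 6)
    pool = pd.concat(
        [
            lip.sample(n=min(len(lip), 4 * n_species), random_state=int(rng.integers(2**31))),
            met.sample(n=min(len(met), 4 * n_met), random_state=int(rng.integers(2**31))),
        ]
    ).reset_index(drop=True)
    chosen, taken_mz = [], []
    order = rng.permutation(len(pool))
    for idx in order:
        row = pool.iloc[idx]
        adduct = "[M-H]-" if rng.random() < 0.8 else "[M+Cl]-"
        mz = adduct_mz(row["monoisotopic_mass"], adduct)
        if not (MZ_MIN + 20 < mz < MZ_MAX - 20):
            continue
        if any(abs(mz - t) / t * 1e6 < min_sep_ppm for t in taken_mz):
            continue
        chosen.append(
            dict(name=row["name"], mass=float(row["monoisotopic_mass"]),
                 compound_class=row["class"], adduct=adduct, mz=float(mz))
        )
        taken_mz.append(mz)
        if len(chosen) == n_species:
            break
    if len(chosen) < n_species:
        raise ValueError("could not place the requested number of species")
    return chosen


def generate_msi(
    grid_w: int = 64,
    grid_h: int = 64,
    n_species: int = 30,
    n_matrix_peaks: int = 5,
    drift_ppm: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> tuple[MsiDataset, GroundTruth]:
    """Generate a grid of profile-mode pixel spectra with planted truth.

    The tissue is an ellipse on the grid, split into a tumor core and a
    stroma rim; each planted species is enriched ~3x in one region.  Matrix
    peaks (first entry = the principal [NEDC+Cl]- ion) are intense
    off-tissue and share a spatial pattern, so their ion images correlate.
    All observed m/z are displaced by the affine ppm drift
    ``a + b * m/z`` with ``(a, b) = drift_ppm``.
    """
    rng = _require_seed(seed)
    if grid_w * grid_h < 4:
        raise ValueError("grid must contain at least 4 pixels")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    xs, ys = np.meshgrid(np.arange(grid_w), np.arange(grid_h))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    n_pix = coords.shape[0]

    # tissue = ellipse; tumor = inner ellipse, stroma = rim
    cx, cy = (grid_w - 1) / 2, (grid_h - 1) / 2
    rx, ry = grid_w * 0.42, grid_h * 0.42
    d2 = ((coords[:, 0] - cx) / rx) ** 2 + ((coords[:, 1] - cy) / ry) ** 2
    tissue = d2 <= 1.0
    tumor = d2 <= 0.45
    region = np.where(tumor, "tumor", np.where(tissue, "stroma", ""))

    species = _select_species(rng, n_species)
    for sp in species:
        sp["region"] = "tumor" if rng.random() < 0.5 else "stroma"

    a_ppm, b_ppm = drift_ppm

    def drifted(m):
        return m * (1.0 + (a_ppm + b_ppm * m) / 1e6)

    # matrix ions: principal [NEDC+Cl]- plus satellites (cluster ions)
    principal = nedc_principal_mz()
    matrix_mz = [principal]
    while len(matrix_mz) < n_matrix_peaks:
        cand = float(rng.uniform(80, 500))
        if all(abs(cand - m) / m * 1e6 > 300 for m in matrix_mz) and all(
            abs(cand - sp["mz"]) / sp["mz"] * 1e6 > 300 for sp in species
        ):
            matrix_mz.append(cand)

    centers = np.array([drifted(sp["mz"]) for sp in species] + [drifted(m) for m in matrix_mz])
    sigma = centers / RESOLVING_POWER * _FWHM_TO_SIGMA

    # per-pixel amplitudes
    field = _smooth_field(rng, grid_w, grid_h)          # species spatial texture
    matrix_field = _smooth_field(rng, grid_w, grid_h)   # shared matrix pattern
    amp = np.zeros((n_pix, centers.size))
    for k, sp in enumerate(species):
        base = rng.uniform(60.0, 160.0)
        enriched = region == sp["region"]
        level = np.where(tissue, np.where(enriched, 3.0, 1.0), 0.02) * base
        amp[:, k] = level * field * rng.lognormal(0.0, 0.15, n_pix)
    off = ~tissue
    for k in range(len(matrix_mz)):
        scale = rng.uniform(150.0, 260.0) if k == 0 else rng.uniform(60.0, 140.0)
        level = np.where(off, 1.0, 0.15) * scale
        amp[:, n_species + k] = level * matrix_field * (1.0 + rng.normal(0, 0.05, n_pix))
    amp = np.maximum(amp, 0.0)

    mz_axis = profile_mz_axis()
    baseline_shape = 18.0 * np.exp(-(mz_axis - MZ_MIN) / 180.0) + 2.0
    baseline_scale = np.where(tissue, 1.0, 0.6) * (1.0 + rng.normal(0, 0.05, n_pix))

    ds = MsiDataset(
        mz=mz_axis,
        coords=coords,
        peak_centers=centers,
        peak_sigma=sigma,
        amplitudes=amp,
        baseline_shape=baseline_shape,
        baseline_scale=np.maximum(baseline_scale, 0.1),
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
    gt = GroundTruth(
        lipid_species=species,
        matrix_peaks=[float(m) for m in matrix_mz],
        mass_drift=(float(a_ppm), float(b_ppm)),
        tissue_mask=tissue,
        region_mask=region,
    )
    return ds, gt


def generate_msi_cohort(
    n_samples: int = 13,
    n_inflamed: int = 6,
    grid_w: int = 24,
    grid_h: int = 24,
    n_species: int = 30,
    tumor_fold: float = 2.0,
    inflamed_fold: float = 2.0,
    noise_cv: float = 0.25,
    seed: int | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Fast multi-sample cohort of pixels x peaks intensity matrices.

    Skips the profile-spectrum layer and emits, per sample, the TIC-style
    peak intensity matrix a preprocessed MSI dataset would yield, together
    with per-pixel region labels.  Species planted as tumor-enriched are
    ``tumor_fold`` higher in tumor pixels; a subset of species additionally
    differs between inflamed and non-inflamed samples within their region
    (``inflamed_fold``).  Used for region-level differential abundance and
    pixel-clustering validation at cohort scale.

    Returns
    -------
    matrices : list of DataFrame (pixels x peak m/z), one per sample
    pixel_meta : DataFrame with sample_id, pixel index, region
    GroundTruth : species list carries ``region`` and ``inflamed_direction``
    """
    rng = _require_seed(seed)
    if not 2 <= n_inflamed <= n_samples - 2:
        raise ValueError("need >=2 samples per inflammation group")
    species = _select_species(rng, n_species)
    for sp in species:
        sp["region"] = "tumor" if rng.random() < 0.5 else "stroma"
        r = rng.random()
        sp["inflamed_direction"] = 0 if r < 0.6 else (1 if r < 0.8 else -1)

    inflamed_samples = set(rng.choice(n_samples, size=n_inflamed, replace=False).tolist())
    peak_cols = [sp["mz"] for sp in species]
    base = np.array([rng.uniform(40.0, 120.0) for _ in species])

    matrices, meta_rows = [], []
    gt = GroundTruth(lipid_species=species)
    for s in range(n_samples):
        sample = f"M{s + 1:02d}"
        inflamed = s in inflamed_samples
        xs, ys = np.meshgrid(np.arange(grid_w), np.arange(grid_h))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        cx, cy = (grid_w - 1) / 2, (grid_h - 1) / 2
        d2 = ((coords[:, 0] - cx) / (grid_w * 0.45)) ** 2 + (
            (coords[:, 1] - cy) / (grid_h * 0.45)
        ) ** 2
        tissue = d2 <= 1.0
        tumor = d2 <= 0.45
        region = np.where(tumor, "tumor", np.where(tissue, "stroma", ""))
        keep = tissue
        n_keep = int(keep.sum())
        sample_factor = rng.lognormal(0.0, 0.1)
        mat = np.empty((n_keep, len(species)))
        reg_keep = region[keep]
        for k, sp in enumerate(species):
            # region fold applies in the species' enriched region; inflamed
            # modulation on top for the inflammation-responsive subset
            level = np.where(reg_keep == sp["region"], tumor_fold, 1.0)
            if sp["inflamed_direction"] != 0 and inflamed:
                level = level * inflamed_fold ** sp["inflamed_direction"]
            mat[:, k] = base[k] * level * sample_factor * rng.lognormal(
                0.0, noise_cv, n_keep
            )
        mat = mat / mat.sum(axis=1, keepdims=True)  # TIC-style normalization
        df = pd.DataFrame(mat, columns=peak_cols)
        df.index = [f"{sample}_px{i}" for i in range(n_keep)]
        matrices.append(df)
        for i, r in enumerate(reg_keep):
            meta_rows.append(
                dict(pixel_id=f"{sample}_px{i}", sample_id=sample,
                     region=r, inflamed=inflamed)
            )
        gt.sample_of_segment[sample] = sample
        gt.segment_inflamed[sample] = inflamed
    pixel_meta = pd.DataFrame(meta_rows).set_index("pixel_id")
    return matrices, pixel_meta, gt


def generate_gene_sets(
    genes: list[str],
    de_genes: list[str],
    n_sets: int = 50,
    n_active: int = 5,
    set_size: int = 20,
    seed: int | None = None,
) -> tuple[dict[str, list[str]], dict[str, bool]]:
    """Toy pathway collection with planted activity.

    ``n_active`` sets draw most of their members from the differentially
    expressed genes (so their enrichment scores respond to the planted
    contrast); the rest are random draws from the universe.  Returns the
    collection and a pathway -> active flag map.
    """
    rng = _require_seed(seed)
    de_genes = [g for g in de_genes if g in set(genes)]
    if n_active > 0 and len(de_genes) < max(2, set_size // 2):
        raise ValueError("not enough DE genes to build active sets")
    sets, truth = {}, {}
    other = [g for g in genes if g not in set(de_genes)]
    for i in range(n_sets):
        name = f"PW{i + 1:03d}"
        active = i < n_active
        if active:
            n_de = min(len(de_genes), int(0.7 * set_size))
            members = list(rng.choice(de_genes, size=n_de, replace=False))
            members += list(rng.choice(other, size=set_size - n_de, replace=False))
        else:
            members = list(rng.choice(other, size=set_size, replace=False))
        sets[name] = members
        truth[name] = active
    return sets, truth


# ---------------------------------------------------------------------------
# HRAM peak lists
# ---------------------------------------------------------------------------


def generate_hram(
    ground_truth: GroundTruth,
    ppm_error_sd: float = 1.0,
    seed: int | None = None,
    n_decoys: int = 0,
    decoy_min_ppm: float = 50.0,
) -> pd.DataFrame:
    """High-resolution accurate-mass peak list for the planted species.

    One stick peak per planted species+adduct with Gaussian relative mass
    error (sd ``ppm_error_sd``, capped at 3 ppm by contract); optional
    decoy peaks are placed at least ``decoy_min_ppm`` from every true ion
    m/z and from every packaged reference ion m/z (both adducts), so they
    can never legitimately match.
    """
    rng = _require_seed(seed)
    if ppm_error_sd > 3:
        raise ValueError("HRAM mass error sd must be <= 3 ppm")
    rows = []
    for sp in ground_truth.lipid_species:
        err = rng.normal(0.0, ppm_error_sd) if ppm_error_sd > 0 else 0.0
        err = float(np.clip(err, -3.0, 3.0))
        mz = sp["mz"] * (1.0 + err / 1e6)
        rows.append(dict(mz=mz, intensity=float(rng.uniform(1e3, 1e5)),
                         true_name=sp["name"], true_adduct=sp["adduct"], is_decoy=False))
    if n_decoys > 0:
        all_ref = pd.concat([load_lipid_references(), load_metabolite_references()])
        forbidden = np.sort(
            np.concatenate(
                [all_ref["monoisotopic_mass"].values + d for d in ADDUCTS.values()]
                + [np.array([sp["mz"] for sp in ground_truth.lipid_species])]
            )
        )
        placed = 0
        while placed < n_decoys:
            cand = float(rng.uniform(MZ_MIN + 30, MZ_MAX - 30))
            if np.min(np.abs(forbidden - cand) / cand) * 1e6 >= decoy_min_ppm:
                rows.append(dict(mz=cand, intensity=float(rng.uniform(1e3, 1e4)),
                                 true_name=None, true_adduct=None, is_decoy=True))
                placed += 1
    df = pd.DataFrame(rows).sort_values("mz").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def generate_ct_table(
    genes: list[str] | None = None,
    conditions: list[str] | None = None,
    induced_fc: float = 4.0,
    hk_noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    housekeeping: tuple[str, str] = ("HPRT1", "TBP"),
    induced_gene: str = "B2M",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Ct table (gene, condition, rep1..rep3) with a planted induction.

    Housekeeping genes are stable across conditions (condition-level and
    replicate noise sd = ``hk_noise_sd``); the induced gene's Ct drops by
    log2(``induced_fc``) in every non-reference condition.
    """
    rng = _require_seed(seed)
    if genes is None:
        genes = list(housekeeping) + [induced_gene, "TBXT-202", "TBXT-201/203", "TBXT-all"]
    if conditions is None:
        conditions = ["mock", "treated-1day", "treated-3days"]
    if "mock" not in conditions:
        raise ValueError("conditions must include the 'mock' reference")
    if induced_fc <= 0:
        raise ValueError("induced_fc must be positive")

    base_ct = {g: float(rng.uniform(17.0, 26.0)) for g in genes}
    rows = []
    gt = GroundTruth()
    for g in genes:
        gt.ct_truth[g] = induced_fc if g == induced_gene else 1.0
    for g in genes:
        for cond in conditions:
            mu = base_ct[g]
            if g == induced_gene and cond != "mock":
                mu -= np.log2(induced_fc)
            if hk_noise_sd > 0:
                mu = mu + rng.normal(0.0, hk_noise_sd)
            reps = [
                mu + (rng.normal(0.0, hk_noise_sd) if hk_noise_sd > 0 else 0.0)
                for _ in range(3)
            ]
            rows.append(dict(gene=g, condition=cond,
                             rep1=reps[0], rep2=reps[1], rep3=reps[2]))
    return pd.DataFrame(rows), gt
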