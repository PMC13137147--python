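#!/usr/bin/env python
"""Generate every pipeline input with planted ground truth.

Writes segment-level probe counts + metadata, a high-resolution (HRAM) peak
list, and a qPCR Ct table under results/simulated/.  The profile-mode MSI
grid is regenerated on demand by 03_msi_lipidomics.py (it is defined by its
seed); an imzML copy can optionally be exported to scratch/ (binary .ibd
companion, so it stays out of the tracked results).
"""

import json
from pathlib import Path

from chordomics import io
from chordomics.synthetic import generate_ct_table, generate_geomx, generate_hram, generate_msi

SEED = 20260930
OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)

pcm, meta, gt = generate_geomx(n_samples=15, n_genes=2000, seed=SEED)
io.write_probe_counts(pcm, OUT / "probe_counts.csv")
meta.to_csv(OUT / "segment_meta.csv", index=False)
truth = {
    "de_genes": gt.de_genes,
    "background_genes": gt.background_genes,
    "outlier_probes": gt.outlier_probes,
    "segment_inflamed": gt.segment_inflamed,
}
(OUT / "geomx_truth.json").write_text(json.dumps(truth, indent=2))
n_inflamed = sum(gt.segment_inflamed.values())
print(f"GeoMx: {pcm.counts.shape[0]} probes x {pcm.counts.shape[1]} segments "
      f"({meta['roi_id'].nunique()} ROIs, {n_inflamed} inflamed segments), "
      f"{len(gt.de_genes)} planted DE genes, {len(gt.background_genes)} background genes")

_, gt_msi = generate_msi(grid_w=32, grid_h=32, n_species=25,
                         drift_ppm=(-10.0, 0.045), seed=SEED)
hram = generate_hram(gt_msi, ppm_error_sd=1.0, seed=SEED, n_decoys=20)
hram.to_csv(OUT / "hram_peaks.csv", index=False)
print(f"HRAM: {len(hram)} peaks ({int(hram.is_decoy.sum())} decoys) for "
      f"{len(gt_msi.lipid_species)} planted species")

ct, gt_ct = generate_ct_table(induced_fc=4.0, hk_noise_sd=0.15, seed=SEED)
ct.to_csv(OUT / "ct_table.csv", index=False)
print(f"qPCR: {ct.gene.nunique()} genes x {ct.condition.nunique()} conditions, "
      f"planted 4-fold induction of B2M")
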