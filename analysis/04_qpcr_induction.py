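#!/usr/bin/env python
"""ddCt analysis of the simulated qPCR table: fold changes per condition
with dual housekeeping normalization (HPRT1 + TBP) and a housekeeping
stability report.  Tables land in results/qpcr/."""

from pathlib import Path

from chordomics import io
from chordomics.qpcr import delta_delta_ct, housekeeping_stability

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "qpcr"
OUT.mkdir(parents=True, exist_ok=True)

ct = io.read_ct_table(ROOT / "simulated" / "ct_table.csv")
fc = delta_delta_ct(ct, housekeeping=["HPRT1", "TBP"], reference_condition="mock")
fc.to_csv(OUT / "fold_changes.csv", index=False)
stab = housekeeping_stability(ct)
stab.to_csv(OUT / "housekeeping_stability.csv", index=False)

print(stab.to_string(index=False))
for gene, grp in fc[fc.condition != "mock"].groupby("gene"):
    mean = grp["mean_fc"].mean()
    sd = grp["sd_fc"].mean()
    print(f"{gene:12s} mean FC across treated conditions = {mean:5.2f} "
          f"(housekeeping spread +-{sd:.2f})")
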