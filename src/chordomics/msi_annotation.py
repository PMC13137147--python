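"""Two-tier, adduct-aware chemical annotation of picked peaks.

Tier 1 (TOF): metabolite matching of the calibrated MALDI-TOF axis against
an HMDB-style table at +-30 ppm.  Tier 2 (HRAM): lipid matching of
high-resolution accurate-mass peak lists against an LMSD-style table at
+-3 ppm, restricted to the glycerophospholipid classes PA/PE/PI/PS/PG,
followed by transfer of the curated assignments onto the TOF axis at
+-40 ppm.  Both adducts [M-H]- and [M+Cl]- are considered throughout.

All tolerances are inclusive (a record exists iff |ppm| <= tol).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .references import ADDUCTS, adduct_mz, ppm_error

__all__ = [
    "match_metabolites",
    "match_lipids_hram",
    "transfer_annotations",
    "curate_unique",
]

RECORD_COLUMNS = [
    "peak_mz", "name", "adduct", "theoretical_mz", "ppm_error", "tier", "ambiguous",
]

HRAM_LIPID_CLASSES = ("PA", "PE", "PI", "PS", "PG")


def _match(peak_mzs, refs: pd.DataFrame, tol_ppm: float, tier: str) -> pd.DataFrame:
    """All (peak, compound, adduct) pairs within the inclusive ppm tolerance;
    peaks matching more than one distinct compound are flagged ambiguous."""
    peak_mzs = np.asarray(peak_mzs, dtype=float)
    if refs.empty:
        warnings.warn("empty reference table; no annotations produced")
        return pd.DataFrame(columns=RECORD_COLUMNS)
    rows = []
    for _, ref in refs.iterrows():
        for adduct in ADDUCTS:
            theo = adduct_mz(ref["monoisotopic_mass"], adduct)
            if theo <= 0:
                continue
            errs = (peak_mzs - theo) / theo * 1e6
            for i in np.flatnonzero(np.abs(errs) <= tol_ppm):
                rows.append(
                    dict(peak_mz=peak_mzs[i], name=ref["name"], adduct=adduct,
                         theoretical_mz=theo, ppm_error=errs[i], tier=tier,
                         ambiguous=False)
                )
    out = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if not out.empty:
        multi = out.groupby("peak_mz")["name"].transform("nunique") > 1
        out["ambiguous"] = multi.values
    return out


def match_metabolites(
    peak_mzs, refs: pd.DataFrame, tol_ppm: float = 30.0
) -> pd.DataFrame:
    """Tier-1 metabolite annotation of a calibrated TOF peak axis (+-30 ppm,
    both negative-mode adducts)."""
    return _match(peak_mzs, refs, tol_ppm, tier="TOF-metabolite")


def match_lipids_hram(
    hram_peak_mzs,
    refs: pd.DataFrame,
    tol_ppm: float = 3.0,
    classes=HRAM_LIPID_CLASSES,
) -> pd.DataFrame:
    """Tier-2 lipid annotation of HRAM peaks (+-3 ppm), restricted to the
    diacyl glycerophospholipid classes PA/PE/PI/PS/PG."""
    refs = refs[refs["class"].isin(classes)]
    return _match(hram_peak_mzs, refs, tol_ppm, tier="HRAM-lipid")


def curate_unique(records: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Deterministic surrogate for manual curation.

    Enforces the single-species contract: every peak carrying more than one
    candidate species is dropped entirely; when one species matches the same
    peak via both adducts, [M-H]- is preferred.  Returns the curated records
    (ambiguous = False throughout) and a curation log.
    """
    log: list[str] = []
    if records.empty:
        return records.copy(), log
    kept = []
    for peak, grp in records.groupby("peak_mz", sort=True):
        species = grp["name"].unique()
        if len(species) > 1:
            log.append(
                f"peak {peak:.4f}: dropped ({len(species)} candidate species: "
                + ", ".join(sorted(species)) + ")"
            )
            continue
        if len(grp) > 1:
            pref = grp[grp["adduct"] == "[M-H]-"]
            row = (pref if not pref.empty else grp).iloc[0]
            log.append(f"peak {peak:.4f}: kept {row['adduct']} of {row['name']}")
        else:
            row = grp.iloc[0]
        row = row.copy()
        row["ambiguous"] = False
        kept.append(row)
    out = pd.DataFrame(kept, columns=records.columns).reset_index(drop=True)
    return out, log


def transfer_annotations(
    tof_peak_mzs, hram_records: pd.DataFrame, tol_ppm: float = 40.0
) -> pd.DataFrame:
    """Transfer curated HRAM assignments to the lower-resolution TOF axis.

    A TOF peak within ``tol_ppm`` (inclusive) of exactly one annotated HRAM
    peak inherits its annotation with tier "transferred" and the TOF-vs-HRAM
    ppm offset as the error; TOF peaks within tolerance of two or more
    distinct annotated species are dropped as ambiguous.
    """
    tof_peak_mzs = np.asarray(tof_peak_mzs, dtype=float)
    rows = []
    if hram_records.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    hmz = hram_records["peak_mz"].values.astype(float)
    for p in tof_peak_mzs:
        errs = (p - hmz) / hmz * 1e6
        hits = hram_records[np.abs(errs) <= tol_ppm]
        if hits.empty:
            continue
        if hits["name"].nunique() > 1:
            continue  # ambiguous across species: dropped
        h = hits.iloc[0]
        rows.append(
            dict(peak_mz=p, name=h["name"], adduct=h["adduct"],
                 theoretical_mz=h["peak_mz"],
                 ppm_error=ppm_error(p, h["peak_mz"]),
                 tier="transferred", ambiguous=False)
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
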