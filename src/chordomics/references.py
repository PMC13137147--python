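"""Reference compounds, adducts, and exact-mass arithmetic.

Negative-ion MALDI with an NEDC matrix mostly yields deprotonated ([M-H]-)
and chloride-adducted ([M+Cl]-) singly charged ions; every m/z in this
package is the neutral monoisotopic mass shifted by one of those two adduct
deltas.  Monoisotopic masses are always derived from the molecular formula
(via :func:`pyteomics.mass.calculate_mass`), never typed by hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
from pyteomics import mass as _ptmass

# Adduct deltas in Da for singly charged negative ions: proton removal and
# 35Cl attachment.  Electron mass is neglected (<0.6 mDa, well below every
# tolerance used here).
PROTON_MASS = 1.00727646
CL35_MASS = 34.96885268

ADDUCTS: dict[str, float] = {
    "[M-H]-": -PROTON_MASS,
    "[M+Cl]-": +CL35_MASS,
}

#: NEDC, N-(1-naphthyl)ethylenediamine; its chloride adduct is the principal
#: matrix-derived ion in negative mode.
NEDC_FORMULA = "C12H14N2"


def formula_mass(formula: str) -> float:
    """Neutral monoisotopic mass (Da) of a Hill-notation molecular formula."""
    return float(_ptmass.calculate_mass(formula=formula))


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct ion of a neutral monoisotopic mass."""
    return neutral_mass + ADDUCTS[adduct]


def nedc_principal_mz() -> float:
    """m/z of [NEDC+Cl]-, the principal matrix peak."""
    return adduct_mz(formula_mass(NEDC_FORMULA), "[M+Cl]-")


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million.

    Raises
    ------
    ValueError
        If ``theoretical`` is not strictly positive.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be > 0, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# Glycerophospholipid formula arithmetic
# ---------------------------------------------------------------------------
# A diacyl glycerophospholipid of total acyl composition C:D is the glycerol-
# phosphate core esterified with two fatty acyl chains plus a class-specific
# head group.  Summing the blocks gives closed-form formulas; e.g.
# PA(34:1) = C37H71O8P, PI(38:4) = C47H83O13P, PS(36:1) = C42H80NO10P.

_LIPID_CLASS_FORMULA = {
    # class -> (dC, dH, dN, dO, dP) offsets relative to (C, 2C - 2D, 0, 0, 0)
    "PA": (3, 5, 0, 8, 1),
    "PE": (5, 10, 1, 8, 1),
    "PS": (6, 10, 1, 10, 1),
    "PG": (6, 11, 0, 10, 1),
    "PI": (9, 15, 0, 13, 1),
    "LPE": (5, 12, 1, 7, 1),  # monoacyl
}


def glycerophospholipid_formula(lipid_class: str, carbons: int, double_bonds: int) -> str:
    """Molecular formula of a (L)PX lipid with the given total acyl C:D."""
    try:
        dc, dh, dn, do, dp = _LIPID_CLASS_FORMULA[lipid_class]
    except KeyError:
        raise ValueError(f"unsupported lipid class {lipid_class!r}") from None
    c = carbons + dc
    h = 2 * carbons - 2 * double_bonds + dh
    if h <= 0:
        raise ValueError("double-bond count too large for the chain length")
    parts = [f"C{c}", f"H{h}"]
    if dn:
        parts.append("N" if dn == 1 else f"N{dn}")
    parts.append(f"O{do}")
    parts.append("P" if dp == 1 else f"P{dp}")
    return "".join(parts)


def lipid_name(lipid_class: str, carbons: int, double_bonds: int) -> str:
    return f"{lipid_class}({carbons}:{double_bonds})"


# ---------------------------------------------------------------------------
# Reference compound tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceCompound:
    """One entry of a compound reference table."""

    name: str
    formula: str | None
    monoisotopic_mass: float
    compound_class: str

    def mz(self, adduct: str) -> float:
        return adduct_mz(self.monoisotopic_mass, adduct)


def load_reference_table(path_or_buffer) -> pd.DataFrame:
    """Read a compound reference CSV into a normalized DataFrame.

    Expected columns: ``name``, ``class`` and at least one of ``formula`` /
    ``monoisotopic_mass``.  A missing mass is computed from the formula; a
    stored mass inconsistent with its formula (>1e-4 Da off) is rejected.
    """
    df = pd.read_csv(path_or_buffer)
    required = {"name", "class"}
    if missing := required - set(df.columns):
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    if "formula" not in df.columns:
        df["formula"] = None
    if "monoisotopic_mass" not in df.columns:
        df["monoisotopic_mass"] = float("nan")

    masses = []
    for row in df.itertuples(index=False):
        stored = getattr(row, "monoisotopic_mass")
        formula = getattr(row, "formula")
        has_formula = isinstance(formula, str) and formula.strip()
        if has_formula:
            derived = formula_mass(formula)
            if pd.notna(stored) and abs(stored - derived) > 1e-4:
                raise ValueError(
                    f"{row.name}: stored mass {stored} inconsistent with "
                    f"formula {formula} ({derived:.5f})"
                )
            masses.append(derived)
        elif pd.notna(stored):
            masses.append(float(stored))
        else:
            raise ValueError(f"{getattr(row, 'name')}: neither formula nor mass given")
    df = df.copy()
    df["monoisotopic_mass"] = masses
    if (df["monoisotopic_mass"] <= 0).any():
        raise ValueError("non-positive monoisotopic mass in reference table")
    return df


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("chordomics.data").joinpath(name).open() as fh:
        return load_reference_table(fh)


def load_lipid_references() -> pd.DataFrame:
    """Packaged mini lipid reference (synthetic LMSD-style snapshot)."""
    return _packaged("lipids_mini.csv")


def load_metabolite_references() -> pd.DataFrame:
    """Packaged mini metabolite reference (synthetic HMDB-style snapshot)."""
    return _packaged("metabolites_mini.csv")


def reference_records(df: pd.DataFrame) -> list[ReferenceCompound]:
    return [
        ReferenceCompound(
            name=r["name"],
            formula=r["formula"] if isinstance(r["formula"], str) else None,
            monoisotopic_mass=float(r["monoisotopic_mass"]),
            compound_class=r["class"],
        )
        for _, r in df.iterrows()
    ]
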