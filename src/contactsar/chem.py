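"""Ligand bookkeeping: molecular formulas, monoisotopic masses, potencies.

Everything here is exactly checkable arithmetic: Hill-notation formula
parsing, monoisotopic [M+H]+ masses (the "calcd" values of HRMS
characterization lines), pIC50 conversion and fold-potency ratios.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "MolecularFormula",
    "LigandRecord",
    "parse_formula",
    "monoisotopic_mass",
    "pic50",
    "ic50_from_pic50",
    "fold_ratio",
    "read_ligand_table",
    "augment_ligand_table",
]

#: Monoisotopic masses (Da) of the most abundant isotope, curated CHNOPS +
#: halogens + common salt counter-ions.  12C defines the mass scale exactly.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207069,
    "F": 18.99840316,
    "Cl": 34.96885271,
    "Br": 78.91833760,
    "I": 126.90447300,
    "Na": 22.98976928,
    "K": 38.96370649,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed molecular formula strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> count map for a neutral or protonated species.

    Counts are strictly positive; serialization follows Hill order
    (C first, then H, then remaining elements alphabetically).
    """

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for elem, count in self.element_counts.items():
            if count < 1:
                raise FormulaError(f"count for element {elem!r} must be >= 1, got {count}")
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.element_counts)
        for elem, count in other.element_counts.items():
            merged[elem] = merged.get(elem, 0) + count
        return MolecularFormula(merged)

    def hill(self) -> str:
        """Serialize in Hill order: C, H, then alphabetical."""
        counts = self.element_counts
        order = [e for e in ("C", "H") if e in counts]
        order += sorted(e for e in counts if e not in ("C", "H"))
        return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C27H35N4O6S2"``.

    Element symbols are one capital letter optionally followed by one
    lowercase letter, each followed by an optional positive integer count
    (absent = 1).  Unknown elements (not in the bundled mass table) and
    explicit zero counts are rejected, with the offending position named.
    """
    if not text:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        elem, digits = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element {elem!r} at position {pos} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for element {elem!r} at position {pos} in {text!r}")
        counts[elem] = counts.get(elem, 0) + count
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Monoisotopic mass in Da: sum of count x atomic monoisotopic mass.

    For an already-protonated formula (as printed in "[M+H]+ calcd for"
    lines) this is the calcd value itself; the electron mass is ignored,
    matching standard organic-chemistry practice.
    """
    total = 0.0
    for elem, count in formula.element_counts.items():
        try:
            total += count * MONOISOTOPIC_MASS[elem]
        except KeyError:
            raise FormulaError(f"element {elem!r} missing from monoisotopic mass table") from None
    return total


def pic50(ic50_nM: float) -> float:
    """pIC50 = -log10(IC50 in mol/L) for an IC50 given in nM."""
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return -math.log10(ic50_nM * 1e-9)


def ic50_from_pic50(p: float) -> float:
    """Inverse of :func:`pic50`: IC50 in nM for a given pIC50."""
    return 10.0 ** (9.0 - p)


def fold_ratio(a_nM: float, b_nM: float) -> int:
    """Nearest-integer fold change a/b, rounding half away from zero.

    This is the conventional reading of "n-fold higher": 906/64 = 14.16
    prints as 14-fold, 2950/64 = 46.09 as 46-fold.
    """
    if not (a_nM > 0 and b_nM > 0):
        raise ValueError(f"concentrations must be positive, got {a_nM}, {b_nM}")
    return int(math.floor(a_nM / b_nM + 0.5))


@dataclass
class LigandRecord:
    """One compound: identifier, optional formula and potency.

    pIC50 is derived from IC50 (nM) at construction and is present iff the
    IC50 is.
    """

    ligand_id: str
    formula: Optional[MolecularFormula] = None
    ic50_nM: Optional[float] = None
    pic50: Optional[float] = field(default=None, init=False)

    def __post_init__(self) -> None:
        if self.ic50_nM is not None:
            self.pic50 = pic50(self.ic50_nM)


def read_ligand_table(path) -> list[LigandRecord]:
    """Read a ligand CSV with header ``ligand_id,formula,ic50_nM``.

    Empty formula / IC50 cells yield records with those fields absent.
    """
    df = pd.read_csv(path, dtype={"ligand_id": str, "formula": str})
    missing = {"ligand_id", "formula", "ic50_nM"} - set(df.columns)
    if missing:
        raise ValueError(f"ligand table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        formula = None
        if isinstance(row.formula, str) and row.formula.strip():
            formula = parse_formula(row.formula.strip())
        ic50 = None if pd.isna(row.ic50_nM) else float(row.ic50_nM)
        records.append(LigandRecord(str(row.ligand_id), formula, ic50))
    return records


def augment_ligand_table(records: list[LigandRecord]) -> pd.DataFrame:
    """Tabulate records with derived pIC50 and monoisotopic [M+H]+ mass.

    The mass column assumes the stored formula is the protonated species,
    as in HRMS characterization lines.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "ligand_id": rec.ligand_id,
                "formula": rec.formula.hill() if rec.formula else "",
                "ic50_nM": rec.ic50_nM,
                "pic50": rec.pic50,
                "monoisotopic_mass_mplus_h": (
                    monoisotopic_mass(rec.formula) if rec.formula else None
                ),
            }
        )
    return pd.DataFrame(rows)
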