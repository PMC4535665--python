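"""Combinatorial lipid library and feature annotation.

Species are named at the sum-composition level, ``CLASS(C:DB)`` — total
acyl carbons and total double bonds — which is the resolution a direct
infusion experiment can deliver (isomers are not separable without
fragmentation). Neutral formulas are generated from per-class anchor
formulas: each extra acyl carbon adds CH2, each double bond removes H2.

Annotation is two-stage: exact-mass search of theoretical adduct m/z
within a ppm window, then homologous-series inference via the referenced
Kendrick mass defect, which extends annotations along a CH2 ladder from an
exact-mass anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .formula_mass import (
    ADDUCTS,
    AdductSpec,
    ElementCounts,
    FormulaError,
    add_formulas,
    adduct_mz,
    hill_formula,
    kendrick,
    parse_formula,
    referenced_kmd,
    subtract_formulas,
)

__all__ = [
    "LIPIDMAPS_CODES",
    "ClassTemplate",
    "CLASS_TEMPLATES",
    "LipidLibraryEntry",
    "ClassSpec",
    "Annotation",
    "species_formula",
    "species_name",
    "build_library",
    "annotate_exact_mass",
    "assign_kmd_series",
    "class_counts",
    "library_to_frame",
    "library_from_frame",
]

#: LipidMaps category codes for the classes the panel covers.
LIPIDMAPS_CODES: Dict[str, str] = {
    "TAG": "LMGL03",
    "DAG": "LMGL02",
    "PC": "LMGP01",
    "PS": "LMGP03",
    "PI": "LMGP06",
    "SM": "LMSP",
    "CE": "LMST",
}


@dataclass(frozen=True)
class ClassTemplate:
    """Anchor-based formula rule for one lipid class.

    ``anchor_formula`` is the neutral formula at ``(anchor_carbons,
    anchor_db)``; other sum compositions follow by CH2 / H2 arithmetic.
    Anchors are chosen so that published reference formulas reproduce
    exactly.
    """

    name: str
    anchor_carbons: int
    anchor_db: int
    anchor_formula: ElementCounts
    default_adducts: Tuple[str, ...] = ("[M+H]+",)


CLASS_TEMPLATES: Dict[str, ClassTemplate] = {
    # TAG(52:2) = C55H102O6  =>  52:0 anchor C55H106O6
    "TAG": ClassTemplate("TAG", 52, 0, parse_formula("C55H106O6"),
                         ("[M+NH4]+", "[M+H]+", "[M+Na]+")),
    # DAG(34:0) = C37H72O5 (glycerol + 2 acyls - 2 H2O)
    "DAG": ClassTemplate("DAG", 34, 0, parse_formula("C37H72O5"),
                         ("[M+NH4]+", "[M+Na]+")),
    # PC(36:4) = C44H80NO8P  =>  36:0 anchor C44H88NO8P
    "PC": ClassTemplate("PC", 36, 0, parse_formula("C44H88NO8P"),
                        ("[M+H]+", "[M+Na]+")),
    # PS(34:0) = C40H78NO10P
    "PS": ClassTemplate("PS", 34, 0, parse_formula("C40H78NO10P"),
                        ("[M+H]+", "[M+Na]+")),
    # PI(34:0) = C43H83O13P
    "PI": ClassTemplate("PI", 34, 0, parse_formula("C43H83O13P"),
                        ("[M+NH4]+", "[M+Na]+")),
    # SM(36:1) = C41H83N2O6P (total carbons counted over base + acyl chains)
    "SM": ClassTemplate("SM", 36, 1, parse_formula("C41H83N2O6P"),
                        ("[M+H]+", "[M+Na]+")),
    # cholesteryl esters; CE(18:2) = C45H76O2 (carbons count the acyl chain)
    "CE": ClassTemplate("CE", 18, 2, parse_formula("C45H76O2"),
                        ("[M+NH4]+", "[M+H-H2O]+")),
}

_CH2: ElementCounts = {"C": 1, "H": 2}
_H2: ElementCounts = {"H": 2}


def species_formula(lipid_class: str, carbons: int, double_bonds: int) -> ElementCounts:
    """Neutral formula of ``CLASS(carbons:double_bonds)``.

    Raises :class:`FormulaError` for an unregistered class or a composition
    whose hydrogen count would go negative.
    """
    try:
        t = CLASS_TEMPLATES[lipid_class]
    except KeyError:
        raise FormulaError(f"unregistered lipid class {lipid_class!r}") from None
    f = dict(t.anchor_formula)
    dc = carbons - t.anchor_carbons
    ddb = double_bonds - t.anchor_db
    if dc >= 0:
        f = add_formulas(f, {"C": dc, "H": 2 * dc})
    else:
        f = subtract_formulas(f, {"C": -dc, "H": -2 * dc})
    if ddb >= 0:
        f = subtract_formulas(f, {"H": 2 * ddb})
    else:
        f = add_formulas(f, {"H": -2 * ddb})
    return f


def species_name(lipid_class: str, carbons: int, double_bonds: int) -> str:
    return f"{lipid_class}({carbons}:{double_bonds})"


@dataclass(frozen=True)
class LipidLibraryEntry:
    lipid_class: str
    carbons: int
    double_bonds: int
    neutral_formula: ElementCounts
    adduct_mzs: Tuple[Tuple[str, float], ...]

    @property
    def name(self) -> str:
        return species_name(self.lipid_class, self.carbons, self.double_bonds)

    @property
    def lipidmaps_code(self) -> str:
        return LIPIDMAPS_CODES.get(self.lipid_class, "?")

    def mz(self, adduct: str) -> float:
        for a, mz in self.adduct_mzs:
            if a == adduct:
                return mz
        raise KeyError(adduct)


@dataclass(frozen=True)
class ClassSpec:
    """Carbon / double-bond ranges (inclusive) for one class in a library."""

    lipid_class: str
    carbons: Tuple[int, int]
    double_bonds: Tuple[int, int]
    adducts: Optional[Tuple[str, ...]] = None


def build_library(specs: Sequence[ClassSpec]) -> List[LipidLibraryEntry]:
    """One entry per (class, carbons, double_bonds) triple, all integer
    carbon numbers included (odd-carbon species occur in plasma). Sorted by
    class then first adduct m/z. Duplicate (class, C, DB) triples across
    specs are rejected."""
    entries: List[LipidLibraryEntry] = []
    seen = set()
    for spec in specs:
        t = CLASS_TEMPLATES[spec.lipid_class]  # KeyError for unknown class
        adducts = spec.adducts or t.default_adducts
        c_lo, c_hi = spec.carbons
        d_lo, d_hi = spec.double_bonds
        if c_hi < c_lo or d_hi < d_lo:
            raise ValueError(f"empty range in {spec}")
        for c in range(c_lo, c_hi + 1):
            for db in range(d_lo, d_hi + 1):
                key = (spec.lipid_class, c, db)
                if key in seen:
                    raise ValueError(f"duplicate species spec {key}")
                seen.add(key)
                f = species_formula(spec.lipid_class, c, db)
                mzs = tuple((a, adduct_mz(f, a)) for a in adducts)
                entries.append(LipidLibraryEntry(spec.lipid_class, c, db, f, mzs))
    entries.sort(key=lambda e: (e.lipid_class, e.adduct_mzs[0][1] if e.adduct_mzs else 0.0))
    return entries


@dataclass
class Annotation:
    """One candidate identity for one observed feature m/z."""

    feature_mz: float
    entry: LipidLibraryEntry
    adduct: str
    ppm_error: float
    method: str = "exact_mass"  # or "kmd_series"


def annotate_exact_mass(
    features: Iterable[float],
    library: Sequence[LipidLibraryEntry],
    ppm_tol: float = 5.0,
) -> List[Annotation]:
    """Exact-mass search: every library adduct m/z within ``ppm_tol`` of a
    feature yields an annotation; candidates for one feature are ranked by
    absolute ppm error."""
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    out: List[Annotation] = []
    for mz in features:
        hits: List[Annotation] = []
        for entry in library:
            for adduct, theo in entry.adduct_mzs:
                ppm = (mz - theo) / theo * 1e6
                if abs(ppm) <= ppm_tol:
                    hits.append(Annotation(mz, entry, adduct, ppm))
        hits.sort(key=lambda a: abs(a.ppm_error))
        out.extend(hits)
    return out


def assign_kmd_series(
    annotations: List[Annotation],
    features: Iterable[float],
    kmd_tol: float = 0.0015,
) -> List[Annotation]:
    """Extend exact-mass annotations along CH2 homologous series.

    Each exact-mass annotation anchors a (class, double_bonds, adduct)
    series; an unannotated feature whose referenced Kendrick mass defect
    relative to an anchor has residual <= ``kmd_tol`` is annotated with
    carbons = anchor carbons + series offset. Returns the augmented list
    (input annotations first)."""
    annotated_mzs = {a.feature_mz for a in annotations}
    out = list(annotations)
    anchors = [a for a in annotations if a.method == "exact_mass"]
    for mz in features:
        if mz in annotated_mzs:
            continue
        best: Optional[Annotation] = None
        for anchor in anchors:
            offset, residual = referenced_kmd(mz, anchor.feature_mz)
            if residual > kmd_tol or offset == 0:
                continue
            # guard against kmd aliasing: masses differing by an integer
            # that is NOT a multiple of the repeat unit share a kmd but sit
            # off the CH2 ladder
            dkm = kendrick(mz).kendrick_mass - kendrick(anchor.feature_mz).kendrick_mass
            if abs(dkm - 14 * offset) > 0.5:
                continue
            carbons = anchor.entry.carbons + offset
            try:
                f = species_formula(anchor.entry.lipid_class, carbons,
                                    anchor.entry.double_bonds)
            except FormulaError:
                continue
            theo = adduct_mz(f, anchor.adduct)
            ppm = (mz - theo) / theo * 1e6
            cand = Annotation(
                mz,
                LipidLibraryEntry(
                    anchor.entry.lipid_class, carbons, anchor.entry.double_bonds,
                    f, ((anchor.adduct, theo),),
                ),
                anchor.adduct,
                ppm,
                method="kmd_series",
            )
            if best is None or abs(cand.ppm_error) < abs(best.ppm_error):
                best = cand
        if best is not None:
            out.append(best)
            annotated_mzs.add(mz)
    return out


def class_counts(annotations: Iterable[Annotation]) -> Dict[str, int]:
    """Distinct annotated species per LipidMaps class code; a species seen
    under several adducts counts once."""
    species = {(a.entry.lipid_class, a.entry.carbons, a.entry.double_bonds)
               for a in annotations}
    counts: Dict[str, int] = {code: 0 for code in LIPIDMAPS_CODES.values()}
    for cls, _, _ in species:
        code = LIPIDMAPS_CODES.get(cls, cls)
        counts[code] = counts.get(code, 0) + 1
    return counts


def library_to_frame(library: Sequence[LipidLibraryEntry]) -> pd.DataFrame:
    rows = []
    for e in library:
        for adduct, mz in e.adduct_mzs:
            rows.append({
                "class": e.lipid_class, "carbons": e.carbons,
                "double_bonds": e.double_bonds,
                "formula": hill_formula(e.neutral_formula),
                "adduct": adduct, "mz": mz,
            })
    return pd.DataFrame(rows)


def library_from_frame(df: pd.DataFrame) -> List[LipidLibraryEntry]:
    entries = []
    for (cls, c, db), grp in df.groupby(["class", "carbons", "double_bonds"],
                                        sort=False):
        f = parse_formula(grp["formula"].iloc[0])
        mzs = tuple(zip(grp["adduct"], grp["mz"].astype(float)))
        entries.append(LipidLibraryEntry(str(cls), int(c), int(db), f, mzs))
    entries.sort(key=lambda e: (e.lipid_class, e.adduct_mzs[0][1]))
    return entries
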