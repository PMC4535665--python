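"""Elemental-formula arithmetic for high-resolution lipid mass spectrometry.

Monoisotopic masses, adduct m/z values, and (referenced) Kendrick mass
defects. All masses are in Da; m/z values are charged-species values, i.e.
the electron mass is subtracted once per positive elementary charge (added
per negative charge).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MONOISOTOPIC",
    "AdductSpec",
    "ADDUCTS",
    "KendrickValue",
    "FormulaError",
    "parse_formula",
    "hill_formula",
    "add_formulas",
    "subtract_formulas",
    "monoisotopic_mass",
    "adduct_mz",
    "kendrick",
    "referenced_kmd",
    "CH2",
]

# IUPAC 2013 monoisotopic atomic masses (Da), most-abundant isotope.
MONOISOTOPIC: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "S": 31.97207100,
}

ELECTRON_MASS = 0.000548579909  # Da
PROTON_MASS = MONOISOTOPIC["H"] - ELECTRON_MASS

ElementCounts = Dict[str, int]

CH2: ElementCounts = {"C": 1, "H": 2}
_H2O: ElementCounts = {"H": 2, "O": 1}


class FormulaError(ValueError):
    """Malformed formula string or unsupported element."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-style formula string into element counts.

    Tolerates underscores and whitespace (markup leftovers such as
    ``C_55_H_102_O_6``). Raises :class:`FormulaError` on unknown element
    symbols or stray characters, naming the offending token.
    """
    cleaned = text.replace("_", "").replace(" ", "")
    counts: ElementCounts = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if m is None or m.end() == pos:
            raise FormulaError(f"malformed formula near {cleaned[pos:]!r} in {text!r}")
        sym, num = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(num) if num else 1
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return {k: v for k, v in counts.items() if v != 0}


def hill_formula(f: Mapping[str, int]) -> str:
    """Canonical Hill-order string: C, H first, then alphabetical."""
    parts = []
    rest = sorted(k for k in f if k not in ("C", "H"))
    order = [e for e in ("C", "H") if e in f] + rest
    for el in order:
        n = f[el]
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def add_formulas(a: Mapping[str, int], b: Mapping[str, int]) -> ElementCounts:
    out = dict(a)
    for k, v in b.items():
        out[k] = out.get(k, 0) + v
    return {k: v for k, v in out.items() if v != 0}


def subtract_formulas(a: Mapping[str, int], b: Mapping[str, int]) -> ElementCounts:
    out = dict(a)
    for k, v in b.items():
        out[k] = out.get(k, 0) - v
    if any(v < 0 for v in out.values()):
        raise FormulaError(f"subtraction removes more atoms than present: {a} - {b}")
    return {k: v for k, v in out.items() if v != 0}


def monoisotopic_mass(f: Mapping[str, int]) -> float:
    """Sum of monoisotopic atomic masses. Additive by construction."""
    total = 0.0
    for el, n in f.items():
        if el not in MONOISOTOPIC:
            raise FormulaError(f"unsupported element {el!r}")
        if n < 0:
            raise FormulaError(f"negative count for {el!r}")
        total += MONOISOTOPIC[el] * n
    return total


@dataclass(frozen=True)
class AdductSpec:
    """A named ionisation adduct: element delta plus signed charge.

    ``delta_add`` atoms are gained and ``delta_remove`` atoms lost when the
    neutral forms the ion; the electron correction is applied once per
    elementary charge.
    """

    name: str
    delta_add: ElementCounts = field(default_factory=dict)
    delta_remove: ElementCounts = field(default_factory=dict)
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")

    def mz(self, neutral: Mapping[str, int]) -> float:
        ion = add_formulas(neutral, self.delta_add)
        ion = subtract_formulas(ion, self.delta_remove)
        mass = monoisotopic_mass(ion) - self.charge * ELECTRON_MASS
        return mass / abs(self.charge)


#: Default adduct registry: the ion forms seen in ammonium-acetate positive-mode
#: infusion (H+, NH4+, Na+, in-source water loss) plus deprotonation.
ADDUCTS: Dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", {"H": 1}, {}, +1),
    "[M+NH4]+": AdductSpec("[M+NH4]+", {"N": 1, "H": 4}, {}, +1),
    "[M+Na]+": AdductSpec("[M+Na]+", {"Na": 1}, {}, +1),
    "[M+H-H2O]+": AdductSpec("[M+H-H2O]+", {"H": 1}, dict(_H2O), +1),
    "[M-H]-": AdductSpec("[M-H]-", {}, {"H": 1}, -1),
}


def adduct_mz(f: Mapping[str, int], adduct: AdductSpec | str) -> float:
    """m/z of the ion formed from neutral ``f`` by ``adduct``.

    ``adduct`` may be an :class:`AdductSpec` or a registered name like
    ``"[M+NH4]+"``.
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise FormulaError(f"unregistered adduct {adduct!r}") from None
    return adduct.mz(f)


@dataclass(frozen=True)
class KendrickValue:
    """Kendrick-rescaled mass and its defect for one m/z value.

    ``kendrick_mass`` is m/z rescaled so the repeat unit (default CH2) has
    exactly its nominal integer mass; ``kmd`` is the signed distance to the
    nearest integer, in [-0.5, 0.5). Members of one homologous series (same
    class and saturation, chain lengths differing by whole repeat units)
    share the same kmd.
    """

    kendrick_mass: float
    kmd: float
    base_unit: Tuple[Tuple[str, int], ...]


def _nominal_mass(f: Mapping[str, int]) -> int:
    return sum(round(MONOISOTOPIC[el]) * n for el, n in f.items())


def kendrick(mz: float, base: Mapping[str, int] = CH2) -> KendrickValue:
    """Kendrick mass and mass defect of ``mz`` for repeat unit ``base``."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    exact = monoisotopic_mass(base)
    if exact == 0:
        raise FormulaError("Kendrick base unit has zero exact mass")
    km = mz * _nominal_mass(base) / exact
    kmd = round(km) - km
    if kmd >= 0.5:  # round() boundary: fold into [-0.5, 0.5)
        kmd -= 1.0
    return KendrickValue(km, kmd, tuple(sorted(base.items())))


def referenced_kmd(
    mz: float, ref_mz: float, base: Mapping[str, int] = CH2
) -> Tuple[int, float]:
    """Position of ``mz`` relative to a series anchor at ``ref_mz``.

    Returns ``(series_offset, residual)``: the nearest integer number of
    base units separating the two masses in Kendrick space, and the
    absolute difference of their Kendrick mass defects. A residual at or
    below ~0.0015 Kendrick units marks membership in the anchor's
    homologous series (a double-bond H2 shift is ~0.0134, well separated).
    """
    kv = kendrick(mz, base)
    kv_ref = kendrick(ref_mz, base)
    offset = round((kv.kendrick_mass - kv_ref.kendrick_mass) / _nominal_mass(base))
    residual = abs(kv.kmd - kv_ref.kmd)
    return offset, residual
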