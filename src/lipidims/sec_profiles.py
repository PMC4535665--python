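"""Size-exclusion-chromatography lipoprotein fraction profiling.

Plasma lipoproteins elute from an SEC column in size order — VLDL first,
then LDL, then HDL — and mass spectra collected per fraction let each
lipid's signal be traced across the particle classes. A lipid whose
normalized elution profile concentrates in the VLDL window is being
exported by the liver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .spectra_processing import PeakList

__all__ = [
    "FractionSeries",
    "FractionWindow",
    "default_windows",
    "extract_fraction_profile",
    "normalize_profile",
    "window_enrichment",
    "specificity_call",
]


@dataclass(frozen=True)
class FractionWindow:
    """Named contiguous interval of fraction indices, inclusive."""

    name: str
    first: int
    last: int

    def contains(self, idx: int) -> bool:
        return self.first <= idx <= self.last


def default_windows(n_fractions: int) -> Tuple[FractionWindow, ...]:
    """Three contiguous windows in elution order VLDL, LDL, HDL, splitting
    the fraction range in equal thirds (boundaries are assay-specific and
    should be configured per column)."""
    edges = np.linspace(0, n_fractions, 4).astype(int)
    names = ("VLDL", "LDL", "HDL")
    return tuple(FractionWindow(nm, int(edges[i]) + 1, int(edges[i + 1]))
                 for i, nm in enumerate(names))


@dataclass
class FractionSeries:
    """Ordered per-fraction peak lists of one SEC run."""

    fractions: Dict[int, PeakList]
    windows: Tuple[FractionWindow, ...] = ()

    def __post_init__(self) -> None:
        idx = list(self.fractions)
        if idx != sorted(idx):
            self.fractions = {i: self.fractions[i] for i in sorted(idx)}
        for a, b in zip(self.windows, self.windows[1:]):
            if b.first <= a.last:
                raise ValueError(f"overlapping fraction windows {a} / {b}")

    @property
    def indices(self) -> List[int]:
        return list(self.fractions)


def extract_fraction_profile(
    fs: FractionSeries, mz: float, ppm_tol: float = 5.0
) -> pd.Series:
    """Extracted-ion trace across fractions: per fraction, the summed
    intensity of peaks within ``mz`` +/- ``ppm_tol``; zero where absent."""
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    tol = mz * ppm_tol / 1e6
    vals = {}
    for idx, peaks in fs.fractions.items():
        lo = np.searchsorted(peaks.mz, mz - tol)
        hi = np.searchsorted(peaks.mz, mz + tol)
        vals[idx] = float(peaks.intensity[lo:hi].sum())
    return pd.Series(vals, name=f"mz_{mz:.4f}")


def normalize_profile(series: pd.Series) -> pd.Series:
    """Normalize an extracted trace to a distribution summing to 1."""
    total = float(series.sum())
    if total <= 0:
        raise ValueError("all-zero fraction profile cannot be normalized")
    return series / total


def window_enrichment(
    distribution: pd.Series, windows: Sequence[FractionWindow]
) -> Dict[str, float]:
    """Share of a normalized distribution inside each named window.

    Every profiled fraction must belong to exactly one window.
    """
    shares = {w.name: 0.0 for w in windows}
    for idx, val in distribution.items():
        hits = [w for w in windows if w.contains(int(idx))]
        if not hits:
            raise ValueError(f"fraction {idx} outside every window")
        shares[hits[0].name] += float(val)
    return shares


def specificity_call(
    shares: Mapping[str, float], threshold: float = 0.8
) -> Optional[str]:
    """Name of the window holding >= ``threshold`` of the mass, else None.

    The 0.8 default operationalizes "specific for" one lipoprotein class.
    """
    top = max(shares, key=lambda k: shares[k])
    return top if shares[top] >= threshold else None
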