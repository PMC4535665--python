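"""Seeded generators of synthetic lipidomics cohorts with known ground truth.

The generators emulate the statistical structure of a direct-infusion
plasma lipidomics study: log-normally distributed species abundances with
group-specific multiplicative effects, ion peaks at theoretical adduct
m/z with ppm-scale mass error, 13C isotopologues, spiked internal
standards, plasticizer-like contaminants, SEC fraction series and qPCR Ct
tables. Every generator is a pure function of its design and seed.

Two scenario builders ship as defaults:

* a human cohort of 27 controls, 14 lipodystrophy (LD) and 7 insulin-
  receptoropathy (INSR) samples, where LD raises shorter/saturated TAGs
  and lowers longer polyunsaturated ones while INSR leaves the TAG pool
  untouched;
* a mouse de-novo-lipogenesis 2x2 design (wild-type / ob-ob x chow / high
  fat), n = 9 per group, with TAG(50:1) planted at 2.1x (ob-ob chow vs
  wt chow) and 4.2x (ob-ob chow vs wt high-fat).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .formula_mass import adduct_mz, monoisotopic_mass
from .lipid_library import (
    CLASS_TEMPLATES,
    LipidLibraryEntry,
    species_formula,
    species_name,
)
from .sec_profiles import FractionSeries, FractionWindow
from .spectra_processing import (
    C13_ABUNDANCE,
    C13_C12_DELTA,
    DEFAULT_STANDARDS,
    InternalStandard,
    PeakList,
    Scan,
)

__all__ = [
    "PanelSpecies",
    "GroupSpec",
    "ContaminantPeak",
    "CohortDesign",
    "GroundTruth",
    "DEFAULT_CONTAMINANTS",
    "default_human_design",
    "generate_mouse_design",
    "generate_cohort",
    "simulate_spectrum",
    "generate_sec_series",
    "generate_ct_table",
    "write_fixture_set",
    "DNL_GENES",
]


@dataclass(frozen=True)
class PanelSpecies:
    """One lipid species in the simulated panel with its control-group
    geometric-mean intensity and the adducts it ionizes under."""

    lipid_class: str
    carbons: int
    double_bonds: int
    base_abundance: float
    adducts: Tuple[Tuple[str, float], ...] = ()  # (adduct, relative yield)
    sec_profile: Tuple[float, ...] = ()          # per-window mass shares

    @property
    def name(self) -> str:
        return species_name(self.lipid_class, self.carbons, self.double_bonds)


@dataclass(frozen=True)
class GroupSpec:
    name: str
    size: int
    effects: Tuple[Tuple[str, float], ...] = ()  # species name -> fold effect

    def effect(self, species: str) -> float:
        for s, f in self.effects:
            if s == species:
                return f
        return 1.0


@dataclass(frozen=True)
class ContaminantPeak:
    name: str
    mz: float
    intensity: float


#: Plasticizer-like background ions (phthalate family) planted in every
#: simulated sample; their mass defects sit in the 0.25-0.33 band that the
#: default defect filter targets.
DEFAULT_CONTAMINANTS: Tuple[ContaminantPeak, ...] = (
    ContaminantPeak("DiOP [M+H]+", 391.2843, 80000.0),
    ContaminantPeak("DiOP [M+Na]+", 413.2662, 30000.0),
    ContaminantPeak("DBP-related", 363.2530, 25000.0),
)


@dataclass(frozen=True)
class CohortDesign:
    """Complete recipe for one synthetic cohort; the seed fully determines
    every generated number."""

    groups: Tuple[GroupSpec, ...]
    panel: Tuple[PanelSpecies, ...]
    cv: float = 0.30                  # biological coefficient of variation
    ppm_bias: float = 0.0             # per-cohort systematic mass error
    ppm_bias_sd: float = 2.0          # sample-to-sample calibration spread
    ppm_jitter: float = 1.0           # per-peak mass error
    scan_intensity_cv: float = 0.05   # per-scan multiplicative jitter
    n_scans: int = 75                 # scan indices 1..n_scans
    standards: Tuple[InternalStandard, ...] = DEFAULT_STANDARDS
    standard_intensity_per_uM: float = 60000.0
    contaminants: Tuple[ContaminantPeak, ...] = DEFAULT_CONTAMINANTS
    sec_windows: Tuple[FractionWindow, ...] = (
        FractionWindow("VLDL", 1, 3),
        FractionWindow("LDL", 4, 6),
        FractionWindow("HDL", 7, 9),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g.size < 1 for g in self.groups):
            raise ValueError("group sizes must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    @property
    def sample_ids(self) -> List[str]:
        out = []
        for g in self.groups:
            out.extend(f"{g.name}_{i + 1:02d}" for i in range(g.size))
        return out

    @property
    def group_of(self) -> pd.Series:
        labels = {}
        for g in self.groups:
            for i in range(g.size):
                labels[f"{g.name}_{i + 1:02d}"] = g.name
        return pd.Series(labels, name="group")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    design: CohortDesign
    abundances: pd.DataFrame              # samples x species, true values
    fold_changes: pd.DataFrame            # species x group, planted effects
    contaminant_mzs: List[float]
    isotopologue_mzs: Dict[str, List[float]]   # species -> planted M+1 m/z
    sec_window: Dict[str, Optional[str]]       # species -> dominant window

    def planted_effects(self, group: str, direction: str = "up") -> List[str]:
        col = self.fold_changes[group]
        if direction == "up":
            return list(col.index[col > 1.0])
        return list(col.index[col < 1.0])


# ---------------------------------------------------------------------------
# Default scenario designs

def _tag(c: int, db: int, base: float, sec: Tuple[float, ...] = ()) -> PanelSpecies:
    return PanelSpecies("TAG", c, db, base,
                        (("[M+NH4]+", 1.0), ("[M+Na]+", 0.15), ("[M+H]+", 0.08)),
                        sec)


_VLDL_ONLY = (0.92, 0.06, 0.02)
_VLDL_LDL = (0.55, 0.40, 0.05)
_SPREAD = (0.40, 0.35, 0.25)

#: LD-vs-control effect pattern: shorter, more saturated TAGs up in LD,
#: longer polyunsaturated TAGs relatively down.
LD_UP = ("TAG(50:1)", "TAG(48:1)", "TAG(48:0)", "TAG(46:1)")
LD_DOWN = ("TAG(52:3)", "TAG(54:4)", "TAG(52:4)")


def _human_panel() -> Tuple[PanelSpecies, ...]:
    tag_comps = [
        (46, 0), (46, 1), (48, 0), (48, 1), (48, 2),
        (50, 1), (50, 2), (50, 3), (51, 3),
        (52, 2), (52, 3), (52, 4), (52, 5), (53, 3),
        (54, 3), (54, 4), (54, 5), (54, 6), (54, 7),
        (56, 3), (56, 8), (58, 6),
    ]
    tags = []
    for c, db in tag_comps:
        base = 4e5 * float(np.exp(-((c - 52) / 5.0) ** 2) * np.exp(-db / 4.0)) + 2e4
        if c <= 50 and db <= 1:
            sec = _VLDL_ONLY
        elif c >= 52:
            sec = _VLDL_LDL
        else:
            sec = (0.75, 0.20, 0.05)
        tags.append(_tag(c, db, base, sec))
    others = (
        PanelSpecies("PC", 36, 4, 6e5, (("[M+H]+", 1.0), ("[M+Na]+", 0.1)), _SPREAD),
        PanelSpecies("PC", 34, 1, 8e5, (("[M+H]+", 1.0), ("[M+Na]+", 0.1)), _SPREAD),
        PanelSpecies("SM", 36, 1, 3e5, (("[M+H]+", 1.0),), _SPREAD),
        PanelSpecies("SM", 36, 2, 2e5, (("[M+H]+", 1.0),), _SPREAD),
        PanelSpecies("CE", 18, 2, 7e5, (("[M+NH4]+", 1.0), ("[M+H-H2O]+", 0.3)),
                     _SPREAD),
        PanelSpecies("DAG", 34, 1, 1e5, (("[M+NH4]+", 1.0),), _SPREAD),
    )
    return tuple(tags) + others


def default_human_design(seed: int = 0) -> CohortDesign:
    """Control / LD / INSR cohort (27 / 14 / 7) with the LD short-saturated
    TAG shift planted and no TAG effects in INSR.

    Effect sizes (1.7x up, 0.6x down) are scaled so the LD-vs-control TAG
    model lands at a cross-validated Q2 in the 0.5-0.85 range at these
    group sizes with 30 % biological CV — a clear but not trivial
    separation.
    """
    ld_effects = tuple((s, 1.7) for s in LD_UP) + tuple((s, 0.6) for s in LD_DOWN)
    insr_effects = (("SM(36:1)", 1.4), ("SM(36:2)", 1.3), ("PC(36:4)", 1.3))
    groups = (
        GroupSpec("control", 27),
        GroupSpec("LD", 14, ld_effects),
        GroupSpec("INSR", 7, insr_effects),
    )
    return CohortDesign(groups=groups, panel=_human_panel(), seed=seed)


def _mouse_panel() -> Tuple[PanelSpecies, ...]:
    comps = [(48, 1), (50, 1), (50, 2), (52, 2), (52, 3), (52, 4), (52, 5),
             (52, 6), (54, 3), (54, 5), (54, 6), (54, 7), (56, 3), (56, 8)]
    return tuple(
        _tag(c, db, 3e5 * float(np.exp(-((c - 52) / 5.0) ** 2) * np.exp(-db / 4.0)) + 2e4)
        for c, db in comps
    )


def generate_mouse_design(seed: int = 0, n_per_group: int = 9) -> CohortDesign:
    """Mouse DNL scenario: wild-type / ob-ob x chow / high-fat, n = 9.

    Planted TAG(50:1) effects relative to the wt-chow baseline: 2.1x in
    ob-ob chow and 0.5x in wt high-fat, so the ob-ob-chow : wt-HFD ratio
    is 4.2. Shorter saturated TAGs rise with de novo lipogenesis (ob-ob
    chow); polyunsaturated TAGs rise when it is suppressed (high fat).
    """
    ob_chow = (("TAG(50:1)", 2.1), ("TAG(52:2)", 1.8), ("TAG(54:3)", 1.6),
               ("TAG(56:3)", 1.5), ("TAG(50:2)", 1.6),
               ("TAG(52:5)", 0.7), ("TAG(52:4)", 0.75), ("TAG(54:7)", 0.7),
               ("TAG(52:6)", 0.7), ("TAG(56:8)", 0.75))
    wt_hfd = (("TAG(50:1)", 0.5), ("TAG(50:2)", 0.7), ("TAG(52:2)", 0.8),
              ("TAG(52:4)", 1.3), ("TAG(54:6)", 1.3), ("TAG(54:7)", 1.3),
              ("TAG(56:8)", 1.25))
    ob_hfd = (("TAG(50:1)", 1.2), ("TAG(52:2)", 1.2), ("TAG(52:4)", 1.1))
    groups = (
        GroupSpec("wt_chow", n_per_group),
        GroupSpec("ob_chow", n_per_group, ob_chow),
        GroupSpec("wt_hfd", n_per_group, wt_hfd),
        GroupSpec("ob_hfd", n_per_group, ob_hfd),
    )
    return CohortDesign(groups=groups, panel=_mouse_panel(), seed=seed)


# ---------------------------------------------------------------------------
# Generators

def _rng(design: CohortDesign, stream: str) -> np.random.Generator:
    # crc32, not hash(): the latter is salted per process
    return np.random.default_rng([design.seed, zlib.crc32(stream.encode())])


def generate_cohort(design: CohortDesign) -> Tuple[pd.DataFrame, GroundTruth]:
    """Draw per-sample species abundances.

    Abundances are log-normal around the group geometric mean
    (base abundance x group effect) with the design CV; the same seed
    always reproduces the same table.
    """
    rng = _rng(design, "abundances")
    sigma = float(np.sqrt(np.log(1.0 + design.cv ** 2)))
    species = [sp.name for sp in design.panel]
    rows = {}
    for g in design.groups:
        for i in range(g.size):
            sid = f"{g.name}_{i + 1:02d}"
            noise = rng.normal(0.0, sigma, size=len(species))
            rows[sid] = [
                sp.base_abundance * g.effect(sp.name) * float(np.exp(z))
                for sp, z in zip(design.panel, noise)
            ]
    abund = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    abund.index.name = "sample_id"

    fc = pd.DataFrame(
        {g.name: [g.effect(s) for s in species] for g in design.groups},
        index=species,
    )
    iso = {}
    for sp in design.panel:
        f = species_formula(sp.lipid_class, sp.carbons, sp.double_bonds)
        iso[sp.name] = [adduct_mz(f, a) + C13_C12_DELTA for a, _ in sp.adducts]
    sec = {}
    for sp in design.panel:
        if sp.sec_profile:
            k = int(np.argmax(sp.sec_profile))
            sec[sp.name] = design.sec_windows[k].name
        else:
            sec[sp.name] = None
    truth = GroundTruth(design, abund, fc,
                        [c.mz for c in design.contaminants], iso, sec)
    return abund, truth


def _base_peaks(composition: Mapping[str, float], design: CohortDesign,
                rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Theoretical peak set of one sample: species adduct ions with mass
    error, their M+1 isotopologues, internal standards and contaminants."""
    mzs: List[float] = []
    ints: List[float] = []

    def mass_error(theo: float) -> float:
        ppm = design.ppm_bias + rng.normal(0.0, design.ppm_jitter)
        return theo * (1.0 + ppm / 1e6)

    for sp in design.panel:
        ab = composition[sp.name]
        f = species_formula(sp.lipid_class, sp.carbons, sp.double_bonds)
        n_carbon = f.get("C", 0)
        for adduct, yield_ in sp.adducts:
            theo = adduct_mz(f, adduct)
            inten = ab * yield_
            mzs.append(mass_error(theo))
            ints.append(inten)
            ratio = n_carbon * C13_ABUNDANCE  # binomial M+1/M for z=1
            mzs.append(mass_error(theo + C13_C12_DELTA))
            ints.append(inten * ratio)
    for std in design.standards:
        mzs.append(mass_error(std.expected_mz))
        ints.append(std.concentration_uM * design.standard_intensity_per_uM)
    for cont in design.contaminants:
        mzs.append(mass_error(cont.mz))
        ints.append(cont.intensity)
    return np.array(mzs), np.array(ints)


def simulate_spectrum(
    composition: Mapping[str, float],
    design: CohortDesign,
    sample_id: str = "sample",
) -> List[Scan]:
    """Simulate the repeat centroid scans of one infused sample.

    Peak m/z values carry the design's ppm bias and jitter (fixed within a
    sample — the drift is per-acquisition, which is what per-sample
    recalibration corrects); intensities get independent multiplicative
    jitter per scan. Scan indices run 1..n_scans so the default processing
    window (20-70) is interior.
    """
    rng = _rng(design, f"spectrum:{sample_id}")
    mz, inten = _base_peaks(composition, design, rng)
    scans = []
    for k in range(1, design.n_scans + 1):
        jitter = rng.lognormal(0.0, design.scan_intensity_cv, size=len(inten))
        scans.append(Scan(k, PeakList(mz.copy(), inten * jitter)))
    return scans


def generate_sec_series(
    design: CohortDesign,
    composition: Optional[Mapping[str, float]] = None,
    n_fractions: int = 9,
) -> FractionSeries:
    """Fraction-resolved peak lists for one SEC run of a pooled sample.

    Each species' total signal is spread over fractions according to its
    designed per-window shares (triangular within each window), with the
    design's mass error applied per fraction.
    """
    rng = _rng(design, "sec")
    if composition is None:
        composition = {sp.name: sp.base_abundance for sp in design.panel}
    windows = design.sec_windows
    per_fraction: Dict[int, List[Tuple[float, float]]] = {
        i: [] for i in range(1, n_fractions + 1)
    }
    for sp in design.panel:
        if not sp.sec_profile:
            continue
        f = species_formula(sp.lipid_class, sp.carbons, sp.double_bonds)
        main_adduct = sp.adducts[0][0]
        theo = adduct_mz(f, main_adduct)
        total = composition[sp.name]
        for share, w in zip(sp.sec_profile, windows):
            frs = [i for i in range(w.first, min(w.last, n_fractions) + 1)]
            if not frs or share <= 0:
                continue
            weights = np.bartlett(len(frs) + 2)[1:-1]
            weights = weights / weights.sum()
            for fr, wt in zip(frs, weights):
                ppm = design.ppm_bias + rng.normal(0.0, design.ppm_jitter)
                per_fraction[fr].append((theo * (1 + ppm / 1e6),
                                         total * share * wt))
    fractions = {
        i: PeakList(np.array([p[0] for p in peaks]),
                    np.array([p[1] for p in peaks]))
        for i, peaks in per_fraction.items()
    }
    return FractionSeries(fractions, windows)


#: Liver DNL transcriptional programme read out by qPCR in the mouse arm.
DNL_GENES = ("FASN", "ACACA", "SREBP1F", "SCD1", "GPAM")


def generate_ct_table(
    genes: Sequence[str] = DNL_GENES,
    groups: Mapping[str, int] = None,
    planted_ddct: Mapping[Tuple[str, str], float] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_gene: str = "18S",
    reference_group: str = "wt",
) -> pd.DataFrame:
    """Tidy Ct table with planted ddCt values.

    ``planted_ddct[(group, gene)]`` is added to that group's Ct for the
    gene, so a planted value of -2 yields a 4-fold relative expression
    against the reference group. Gaussian noise (``noise_sd`` cycles) is
    added independently to every well; the reference gene is measured in
    every sample.
    """
    if groups is None:
        groups = {"wt": 6, "ob": 6}
    if planted_ddct is None:
        planted_ddct = {}
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in groups")
    rng = np.random.default_rng(seed)
    base_ct = {g: 24.0 for g in genes}
    ref_ct = 11.0
    rows = []
    for group, size in groups.items():
        for i in range(size):
            sid = f"{group}_{i + 1:02d}"
            rows.append({"sample_id": sid, "group": group, "gene": reference_gene,
                         "ct": ref_ct + rng.normal(0.0, noise_sd)})
            for gene in genes:
                ct = base_ct[gene] + planted_ddct.get((group, gene), 0.0)
                rows.append({"sample_id": sid, "group": group, "gene": gene,
                             "ct": ct + rng.normal(0.0, noise_sd)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixture export

def write_fixture_set(design: CohortDesign, out_dir: str | Path) -> Dict[str, Path]:
    """Write a complete text fixture tree: one peak-table CSV per sample,
    the design as YAML, and the ground truth as CSV. Re-running with the
    same design and seed reproduces byte-identical files."""
    out = Path(out_dir)
    spectra_dir = out / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    abund, truth = generate_cohort(design)
    paths: Dict[str, Path] = {}
    for sid in abund.index:
        scans = simulate_spectrum(abund.loc[sid], design, sample_id=sid)
        rows = []
        for scan in scans:
            for mz, inten in zip(scan.peaks.mz, scan.peaks.intensity):
                rows.append((sid, scan.index, f"{mz:.6f}", f"{inten:.2f}"))
        df = pd.DataFrame(rows, columns=["sample_id", "scan", "mz", "intensity"])
        p = spectra_dir / f"{sid}.csv"
        df.to_csv(p, index=False)
        paths[sid] = p
    truth_path = out / "ground_truth.csv"
    truth.abundances.to_csv(truth_path, float_format="%.4f")
    fc_path = out / "planted_fold_changes.csv"
    truth.fold_changes.to_csv(fc_path, float_format="%.4f")
    design_path = out / "design.yaml"
    design_path.write_text(yaml.safe_dump({
        "seed": design.seed,
        "cv": design.cv,
        "groups": {g.name: g.size for g in design.groups},
        "n_species": len(design.panel),
        "ppm_bias": design.ppm_bias,
        "ppm_jitter": design.ppm_jitter,
    }, sort_keys=True))
    paths["ground_truth"] = truth_path
    paths["fold_changes"] = fc_path
    paths["design"] = design_path
    return paths
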