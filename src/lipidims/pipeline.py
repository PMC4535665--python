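"""Config-driven orchestration of the full DIMS analysis.

Stage order is fixed: average scans -> recalibrate -> remove contaminants
-> align across samples -> annotate isotopes -> annotate lipids (exact
mass + Kendrick series) -> build the species matrix -> TAG-pool
normalization -> chemometric models and univariate tables. Every stage
logs peak counts, and a run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from .lipid_library import (
    Annotation,
    ClassSpec,
    LipidLibraryEntry,
    annotate_exact_mass,
    assign_kmd_series,
    build_library,
    class_counts,
)
from .spectra_processing import (
    DEFAULT_STANDARDS,
    FeatureMatrix,
    InternalStandard,
    PeakList,
    ProcessingParams,
    Scan,
    align_samples,
    annotate_isotopes,
    average_scans,
    filter_contaminants,
    read_peak_table,
    recalibrate,
    write_feature_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "DEFAULT_LIBRARY_SPECS",
    "DEFAULT_REJECTION_LIST",
    "DEFAULT_DEFECT_WINDOWS",
    "process_samples",
    "annotate_features",
    "species_matrix",
    "run_pipeline",
]

#: Default annotation panel: the lipid classes this assay reads out in
#: positive mode, over plasma-typical sum-composition ranges.
DEFAULT_LIBRARY_SPECS: Tuple[ClassSpec, ...] = (
    ClassSpec("TAG", (44, 60), (0, 10)),
    ClassSpec("DAG", (28, 40), (0, 6)),
    ClassSpec("PC", (30, 42), (0, 8)),
    ClassSpec("SM", (30, 42), (0, 3)),
    ClassSpec("CE", (14, 22), (0, 6)),
)

#: Known background ions (phthalate plasticizers), removed by exact match.
DEFAULT_REJECTION_LIST: Tuple[Tuple[float, float], ...] = (
    (391.2843, 0.01), (413.2662, 0.01), (363.2530, 0.01),
)

#: Mass-defect region where phthalate-family ions cluster and lipids do not.
DEFAULT_DEFECT_WINDOWS: Tuple[Tuple[Tuple[float, float], Tuple[float, float]], ...] = (
    ((340.0, 460.0), (0.24, 0.33)),
)


@dataclass
class PipelineConfig:
    input_dir: Path
    out_dir: Path
    params: ProcessingParams = field(default_factory=ProcessingParams)
    standards: Tuple[InternalStandard, ...] = DEFAULT_STANDARDS
    recalibration_model: str = "constant"
    rejection_list: Tuple[Tuple[float, float], ...] = DEFAULT_REJECTION_LIST
    defect_windows: Tuple = DEFAULT_DEFECT_WINDOWS
    library_specs: Tuple[ClassSpec, ...] = DEFAULT_LIBRARY_SPECS
    annotate_ppm: float = 5.0
    scaling: str = "uv"
    folds: int = 7
    n_orth: int = 1
    alpha: float = 0.05
    comparisons: Tuple[Tuple[str, str], ...] = ()
    groups: Optional[Mapping[str, str]] = None  # sample_id -> group
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: Dict = {
            "input_dir": Path(raw["input_dir"]),
            "out_dir": Path(raw["out_dir"]),
        }
        if "params" in raw:
            p = dict(raw["params"])
            iso = p.pop("isotope", None)
            params = ProcessingParams(**{k: tuple(v) if k == "scan_range" else v
                                         for k, v in p.items()})
            if iso:
                for k, v in iso.items():
                    setattr(params.isotope, k, v)
            kwargs["params"] = params
        for key in ("recalibration_model", "annotate_ppm", "scaling", "folds",
                    "n_orth", "alpha", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "comparisons" in raw:
            kwargs["comparisons"] = tuple(tuple(c) for c in raw["comparisons"])
        if "groups" in raw:
            kwargs["groups"] = dict(raw["groups"])
        if "library_specs" in raw:
            kwargs["library_specs"] = tuple(
                ClassSpec(s["class"], tuple(s["carbons"]), tuple(s["double_bonds"]))
                for s in raw["library_specs"])
        if "rejection_list" in raw:
            kwargs["rejection_list"] = tuple(tuple(r) for r in raw["rejection_list"])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    feature_matrix: FeatureMatrix
    annotations: List[Annotation]
    species: pd.DataFrame                  # samples x annotated species
    tag_proportions: Optional[pd.DataFrame]
    model_reports: Dict[str, Dict]
    univariate: Dict[str, pd.DataFrame]
    stage_log: List[Dict]


def _infer_groups(sample_ids: Sequence[str]) -> Dict[str, str]:
    return {s: s.rsplit("_", 1)[0] for s in sample_ids}


def process_samples(
    scans_by_sample: Mapping[str, Sequence[Scan]],
    cfg: PipelineConfig,
) -> Tuple[FeatureMatrix, List[Dict]]:
    """Per-sample averaging, recalibration and contaminant removal, then
    cross-sample alignment and isotope annotation."""
    stage_log: List[Dict] = []
    cleaned: Dict[str, PeakList] = {}
    for sid, scans in scans_by_sample.items():
        avg = average_scans(scans, cfg.params)
        recal, model = recalibrate(avg, cfg.standards, cfg.recalibration_model)
        filt, removed = filter_contaminants(recal, cfg.rejection_list,
                                            cfg.defect_windows)
        cleaned[sid] = filt
        stage_log.append({
            "sample": sid, "scans": len(scans), "averaged_peaks": len(avg),
            "recal_offset_ppm": round(model.intercept, 3),
            "contaminants_removed": len(removed), "final_peaks": len(filt),
        })
    groups = dict(cfg.groups) if cfg.groups else _infer_groups(list(cleaned))
    fm = align_samples(cleaned, cfg.params, groups)
    fm = annotate_isotopes(fm, cfg.params)
    stage_log.append({
        "stage": "alignment", "n_samples": fm.n_samples,
        "n_features": fm.n_features,
        "n_isotope_flagged": int(fm.features["is_isotope"].sum()),
    })
    return fm, stage_log


def annotate_features(
    fm: FeatureMatrix, cfg: PipelineConfig
) -> Tuple[List[Annotation], List[LipidLibraryEntry]]:
    """Exact-mass then Kendrick-series annotation of non-isotope features."""
    library = build_library(cfg.library_specs)
    main = fm.drop_isotopes()
    mzs = main.features["mz"].tolist()
    ann = annotate_exact_mass(mzs, library, cfg.annotate_ppm)
    ann = assign_kmd_series(ann, mzs)
    return ann, library


def species_matrix(
    fm: FeatureMatrix,
    annotations: Sequence[Annotation],
    exclude_mzs: Sequence[float] = (),
    exclude_ppm: float = 10.0,
) -> pd.DataFrame:
    """Samples x species intensity table.

    Non-isotope features are mapped to their best (lowest |ppm|)
    annotation; intensities of all ionisation products of one species are
    summed per sample, missing values counted as zero. Features within
    ``exclude_ppm`` of an ``exclude_mzs`` entry (spiked internal
    standards) are left out — they are calibrants, not analytes.
    """
    main = fm.drop_isotopes()
    best: Dict[float, Annotation] = {}
    for a in annotations:
        cur = best.get(a.feature_mz)
        if cur is None or abs(a.ppm_error) < abs(cur.ppm_error):
            best[a.feature_mz] = a
    cols: Dict[str, np.ndarray] = {}
    X = main.intensities.fillna(0.0)
    excl = np.asarray(exclude_mzs, dtype=float)
    for fid, row in main.features.iterrows():
        mz = row["mz"]
        if excl.size and np.any(np.abs(excl - mz) / mz * 1e6 <= exclude_ppm):
            continue
        a = best.get(mz)
        if a is None:
            continue
        name = a.entry.name
        col = X[fid].to_numpy()
        cols[name] = cols.get(name, 0.0) + col
    out = pd.DataFrame(cols, index=X.index)
    return out.reindex(sorted(out.columns), axis=1)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full analysis on a directory of peak-table CSVs.

    ``cfg.input_dir`` may be a directory of one-CSV-per-sample peak tables
    (sample_id, scan, mz, intensity) or a single such CSV holding all
    samples. Writes features.csv, feature_meta.csv, annotations.csv,
    model_report.json, univariate_<pair>.csv and run.log to
    ``cfg.out_dir``; partial outputs survive a stage failure.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inp = Path(cfg.input_dir)
    scans_by_sample: Dict[str, List[Scan]] = {}
    csvs = sorted(inp.glob("*.csv")) if inp.is_dir() else [inp]
    if not csvs:
        raise FileNotFoundError(f"no peak-table CSVs under {inp}")
    for path in csvs:
        scans_by_sample.update(read_peak_table(path))

    fm, stage_log = process_samples(scans_by_sample, cfg)
    write_feature_matrix(fm, out / "features.csv", out / "feature_meta.csv")

    annotations, _ = annotate_features(fm, cfg)
    ann_df = pd.DataFrame([
        {"feature_mz": a.feature_mz, "species": a.entry.name,
         "class": a.entry.lipidmaps_code, "adduct": a.adduct,
         "ppm_error": a.ppm_error, "method": a.method}
        for a in annotations
    ])
    ann_df.to_csv(out / "annotations.csv", index=False, float_format="%.6f")

    species = species_matrix(fm, annotations,
                             exclude_mzs=[s.expected_mz for s in cfg.standards])
    species.to_csv(out / "species.csv", float_format="%.4f")
    groups = fm.groups

    tag_cols = [c for c in species.columns if c.startswith("TAG(")]
    tag_prop = None
    if tag_cols:
        tag_prop = chem.normalize_tag_pool(species, tag_cols)
        tag_prop.to_csv(out / "tag_proportions.csv", float_format="%.6f")

    model_reports: Dict[str, Dict] = {}
    univariate: Dict[str, pd.DataFrame] = {}
    comparisons = cfg.comparisons
    if not comparisons and groups is not None:
        levels = list(pd.unique(groups))
        comparisons = tuple((a, b) for i, a in enumerate(levels)
                            for b in levels[i + 1:])
    for a_label, b_label in comparisons:
        key = f"{a_label}_vs_{b_label}"
        sel = groups.isin([a_label, b_label])
        X = (tag_prop if tag_prop is not None else species).loc[sel.index[sel]]
        y = (groups[sel] == a_label).astype(int)
        try:
            model = chem.fit_o2plsda(X, y, n_orth=cfg.n_orth, scaling=cfg.scaling,
                                     folds=cfg.folds, cv_seed=cfg.seed)
        except ValueError as exc:
            model_reports[key] = {"error": str(exc)}
            continue
        splot = chem.s_plot(model, X)
        splot.to_csv(out / f"splot_{key}.csv", float_format="%.6f")
        report = model.summary()
        report["predicted_y"] = {s: round(float(v), 4)
                                 for s, v in model.predicted_y.items()}
        report["cv_anova_significant"] = bool(model.cv_anova_p < cfg.alpha)
        model_reports[key] = report
        uni = chem.ttest_bonferroni(X, groups[sel], (a_label, b_label), cfg.alpha)
        uni.to_csv(out / f"univariate_{key}.csv", float_format="%.6g")
        univariate[key] = uni

    (out / "model_report.json").write_text(json.dumps(model_reports, indent=2))
    log_lines = [json.dumps(entry, sort_keys=True) for entry in stage_log]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(fm, annotations, species, tag_prop,
                          model_reports, univariate, stage_log)
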