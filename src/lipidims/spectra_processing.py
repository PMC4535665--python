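"""Per-sample processing of direct-infusion centroid scans.

Fixed stage order: average scans -> internal-standard recalibration ->
contaminant removal -> cross-sample alignment -> isotope annotation. Each
stage logs peak counts in and out, and no stage ever increases the total
peak count.

There is no chromatographic dimension: a sample is a set of repeat scans
of the same infusate, so averaging over a scan window is the first and
only within-sample aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formula_mass import adduct_mz, parse_formula

logger = logging.getLogger(__name__)

__all__ = [
    "Scan",
    "PeakList",
    "ProcessingParams",
    "IsotopeParams",
    "InternalStandard",
    "DEFAULT_STANDARDS",
    "RecalibrationModel",
    "RecalibrationError",
    "FeatureMatrix",
    "average_scans",
    "recalibrate",
    "filter_contaminants",
    "align_samples",
    "annotate_isotopes",
    "ppm_group",
    "read_mzml",
    "read_mzxml",
    "read_peak_table",
    "write_feature_matrix",
    "read_feature_matrix",
]

C13_C12_DELTA = 1.00336  # Da, one 13C substitution at z=1
C13_ABUNDANCE = 0.0107


@dataclass
class PeakList:
    """Centroided peaks of one sample, sorted by m/z."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Scan:
    index: int
    peaks: PeakList
    polarity: str = "positive"


@dataclass
class IsotopeParams:
    """CAMERA-style isotope annotation settings (singly charged only)."""

    maxcharge: int = 1
    ppm: float = 5.0
    mzabs: float = 0.001
    minfrac: float = 0.25


@dataclass
class ProcessingParams:
    """Pipeline settings; the defaults are the published processing values
    for this assay (50 averaged scans 20-70, intensity cutoff 2000, 22 ppm
    grouping window, 60 % minimum coverage)."""

    scan_range: Tuple[int, int] = (20, 70)
    intensity_cutoff: float = 2000.0
    align_ppm: float = 22.0
    min_coverage: float = 0.60
    isotope: IsotopeParams = field(default_factory=IsotopeParams)

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")
        if self.align_ppm <= 0 or self.isotope.ppm <= 0:
            raise ValueError("ppm windows must be positive")


@dataclass(frozen=True)
class InternalStandard:
    """Spiked compound of known formula and concentration used for
    per-sample mass recalibration."""

    name: str
    formula: str
    adduct: str
    concentration_uM: float

    @property
    def expected_mz(self) -> float:
        return adduct_mz(parse_formula(self.formula), self.adduct)


#: The six-spike standard mix of the assay (ether lipids and odd-chain
#: species absent from plasma), with the positive-mode ion each is read at.
DEFAULT_STANDARDS: Tuple[InternalStandard, ...] = (
    InternalStandard("PC(O-18:0/O-18:0)", "C44H92NO6P", "[M+H]+", 0.6),
    InternalStandard("PE(O-20:0/O-20:0)-phytanyl", "C45H94NO6P", "[M+H]+", 1.2),
    InternalStandard("Cer(d18:1/8:0)", "C26H51NO3", "[M+H]+", 0.6),
    InternalStandard("SM(d18:1/17:0)", "C40H81N2O6P", "[M+H]+", 0.6),
    InternalStandard("undecanoic acid", "C11H22O2", "[M+H]+", 6.2),
    InternalStandard("trilaurin", "C39H74O6", "[M+NH4]+", 0.6),
)


class RecalibrationError(RuntimeError):
    """Fewer than two internal standards located; carries the per-standard
    search report in ``report``."""

    def __init__(self, message: str, report: pd.DataFrame):
        super().__init__(message)
        self.report = report


@dataclass
class RecalibrationModel:
    """Fitted ppm-error model: observed = expected * (1 + ppm(mz)/1e6).

    ``kind`` is "constant" (single robust offset) or "linear" (offset
    drifting linearly with m/z). Correction divides the drift back out.
    """

    kind: str
    intercept: float
    slope: float = 0.0
    residuals_ppm: Optional[pd.DataFrame] = None

    def ppm_error(self, mz: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(mz, dtype=float)

    def apply(self, peaks: PeakList) -> PeakList:
        corrected = peaks.mz / (1.0 + self.ppm_error(peaks.mz) / 1e6)
        return PeakList(corrected, peaks.intensity.copy())


def ppm_group(mz_sorted: np.ndarray, window_ppm: float) -> List[np.ndarray]:
    """Group sorted m/z values so that no two members of a group differ by
    more than ``window_ppm`` (relative to the smaller value).

    Single-linkage components in 1-D are runs of consecutive gaps within
    the window; a component whose total span still exceeds the window is
    split recursively at its largest internal gap (deterministic for
    sorted input).
    """
    n = len(mz_sorted)
    if n == 0:
        return []
    gaps_ppm = np.diff(mz_sorted) / mz_sorted[:-1] * 1e6
    breaks = np.flatnonzero(gaps_ppm > window_ppm)
    bounds = np.concatenate(([0], breaks + 1, [n]))
    groups: List[np.ndarray] = []
    stack = [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]
    while stack:
        lo, hi = stack.pop(0)
        seg = mz_sorted[lo:hi]
        if len(seg) > 1 and (seg[-1] - seg[0]) / seg[0] * 1e6 > window_ppm:
            cut = int(np.argmax(np.diff(seg))) + 1
            stack.insert(0, (lo + cut, hi))
            stack.insert(0, (lo, lo + cut))
        else:
            groups.append(np.arange(lo, hi))
    groups.sort(key=lambda idx: idx[0])
    return groups


def average_scans(scans: Sequence[Scan], params: ProcessingParams) -> PeakList:
    """Average the in-range scans of one sample into a single peak list.

    Peaks are pooled over scans in ``scan_range``, grouped by m/z proximity
    with the alignment ppm window, and each group is averaged over the
    number of in-range scans (a peak absent from a scan counts as zero).
    Groups whose averaged intensity falls strictly below the cutoff are
    discarded. Consensus m/z is the intensity-weighted mean.
    """
    lo, hi = params.scan_range
    in_range = [s for s in scans if lo <= s.index <= hi]
    if not in_range:
        raise ValueError(f"no scans inside range {params.scan_range}")
    n_scans = len(in_range)
    mz = np.concatenate([s.peaks.mz for s in in_range]) if in_range else np.array([])
    inten = np.concatenate([s.peaks.intensity for s in in_range])
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    out_mz, out_int = [], []
    for idx in ppm_group(mz, params.align_ppm):
        avg = inten[idx].sum() / n_scans
        if avg < params.intensity_cutoff:
            continue
        w = inten[idx]
        out_mz.append(float(np.average(mz[idx], weights=w)) if w.sum() > 0
                      else float(mz[idx].mean()))
        out_int.append(float(avg))
    logger.info("average_scans: %d scans, %d pooled peaks -> %d averaged peaks",
                n_scans, len(mz), len(out_mz))
    return PeakList(np.array(out_mz), np.array(out_int))


def _locate_standard(peaks: PeakList, expected: float, window_ppm: float) -> Optional[int]:
    tol = expected * window_ppm / 1e6
    lo = np.searchsorted(peaks.mz, expected - tol)
    hi = np.searchsorted(peaks.mz, expected + tol)
    if hi <= lo:
        return None
    return int(lo + np.argmax(peaks.intensity[lo:hi]))


def recalibrate(
    peaks: PeakList,
    standards: Sequence[InternalStandard] = DEFAULT_STANDARDS,
    model: str = "constant",
    search_ppm: float = 20.0,
) -> Tuple[PeakList, RecalibrationModel]:
    """Sample-specific mass recalibration against spiked standards.

    Each standard is searched within ``search_ppm`` of its expected m/z
    (most intense candidate wins). The observed ppm errors are fitted
    robustly — median offset for the constant model, least-absolute-
    deviation line for the linear model — and the fitted drift divided out
    of every peak.
    """
    rows = []
    for std in standards:
        exp = std.expected_mz
        i = _locate_standard(peaks, exp, search_ppm)
        obs = float(peaks.mz[i]) if i is not None else np.nan
        rows.append({"standard": std.name, "expected_mz": exp, "observed_mz": obs,
                     "found": i is not None,
                     "ppm_error": (obs - exp) / exp * 1e6 if i is not None else np.nan})
    report = pd.DataFrame(rows)
    found = report[report["found"]]
    if len(found) < 2:
        raise RecalibrationError(
            f"only {len(found)} of {len(standards)} internal standards located "
            f"within {search_ppm} ppm", report)
    exp = found["expected_mz"].to_numpy()
    err = found["ppm_error"].to_numpy()
    if model == "constant":
        fitted = RecalibrationModel("constant", float(np.median(err)))
    elif model == "linear":
        import statsmodels.api as sm  # LAD via median regression

        X = sm.add_constant(exp)
        res = sm.QuantReg(err, X).fit(q=0.5)
        fitted = RecalibrationModel("linear", float(res.params[0]), float(res.params[1]))
    else:
        raise ValueError(f"unknown recalibration model {model!r}")
    corrected = fitted.apply(peaks)
    post = report.copy()
    corr_obs = report["observed_mz"] / (1.0 + fitted.ppm_error(report["observed_mz"].to_numpy()) / 1e6)
    post["residual_ppm"] = (corr_obs - report["expected_mz"]) / report["expected_mz"] * 1e6
    fitted.residuals_ppm = post
    logger.info("recalibrate: %d/%d standards, %s model, offset %.2f ppm",
                len(found), len(standards), model, fitted.intercept)
    return corrected, fitted


def filter_contaminants(
    peaks: PeakList,
    rejection_list: Sequence[Tuple[float, float]] = (),
    defect_windows: Sequence[Tuple[Tuple[float, float], Tuple[float, float]]] = (),
) -> Tuple[PeakList, pd.DataFrame]:
    """Remove known contaminant ions (plasticizers and friends).

    ``rejection_list`` holds (m/z, absolute tolerance) entries; a peak
    within tolerance of any entry is removed. ``defect_windows`` holds
    ((nominal_lo, nominal_hi), (defect_lo, defect_hi)) rules: a peak whose
    nominal mass is in range and whose fractional mass falls inside the
    defect interval is removed. Returns the filtered list and a removal log.
    """
    keep = np.ones(len(peaks), dtype=bool)
    reasons: Dict[int, str] = {}
    for target, tol in rejection_list:
        hit = np.abs(peaks.mz - target) <= tol
        for i in np.flatnonzero(hit & keep):
            reasons[int(i)] = f"rejection list {target:.4f}"
        keep &= ~hit
    nominal = np.round(peaks.mz)
    defect = peaks.mz - np.floor(peaks.mz)
    for (n_lo, n_hi), (d_lo, d_hi) in defect_windows:
        hit = (nominal >= n_lo) & (nominal <= n_hi) & (defect >= d_lo) & (defect <= d_hi)
        for i in np.flatnonzero(hit & keep):
            reasons[int(i)] = f"mass-defect window [{d_lo},{d_hi}] at {n_lo}-{n_hi}"
        keep &= ~hit
    log = pd.DataFrame(
        {"mz": peaks.mz[~keep], "intensity": peaks.intensity[~keep],
         "reason": [reasons.get(int(i), "?") for i in np.flatnonzero(~keep)]})
    logger.info("filter_contaminants: %d -> %d peaks", len(peaks), int(keep.sum()))
    return PeakList(peaks.mz[keep], peaks.intensity[keep]), log


@dataclass
class FeatureMatrix:
    """Samples x aligned-features intensity table.

    ``intensities``: DataFrame indexed by sample id, one column per
    feature id. ``features``: per-feature metadata (consensus m/z, coverage,
    isotope flags). ``groups``: optional per-sample class labels.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    groups: Optional[pd.Series] = None

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def drop_isotopes(self) -> "FeatureMatrix":
        keep = ~self.features["is_isotope"].astype(bool)
        cols = self.features.index[keep]
        return FeatureMatrix(self.intensities[cols], self.features.loc[cols].copy(),
                             self.groups)


def align_samples(
    samples: Mapping[str, PeakList],
    params: ProcessingParams,
    groups: Optional[Mapping[str, str]] = None,
) -> FeatureMatrix:
    """Align peak lists across samples into a feature matrix.

    Pools all peaks, groups them with the 22 ppm single-linkage window
    (see :func:`ppm_group`), drops groups seen in fewer than
    ``min_coverage`` of the samples, and keeps one intensity per sample
    per feature (the maximum, if a sample contributed several peaks).
    """
    if len(samples) < 2:
        raise ValueError("alignment needs at least two samples")
    sample_ids = list(samples)
    mz = np.concatenate([samples[s].mz for s in sample_ids])
    inten = np.concatenate([samples[s].intensity for s in sample_ids])
    origin = np.concatenate([np.full(len(samples[s]), k, dtype=int)
                             for k, s in enumerate(sample_ids)])
    order = np.argsort(mz, kind="stable")
    mz, inten, origin = mz[order], inten[order], origin[order]

    n = len(sample_ids)
    feat_rows = []
    columns: Dict[str, np.ndarray] = {}
    for idx in ppm_group(mz, params.align_ppm):
        members = np.unique(origin[idx])
        coverage = len(members) / n
        if coverage < params.min_coverage:
            continue
        w = inten[idx]
        cons = float(np.average(mz[idx], weights=w)) if w.sum() > 0 else float(mz[idx].mean())
        col = np.full(n, np.nan)
        for k in members:
            sel = idx[origin[idx] == k]
            col[k] = inten[sel].max()
        fid = f"F{len(feat_rows):04d}"
        feat_rows.append({"feature_id": fid, "mz": cons, "coverage": coverage,
                          "is_isotope": False, "isotope_of": ""})
        columns[fid] = col
    features = pd.DataFrame(feat_rows).set_index("feature_id") if feat_rows else \
        pd.DataFrame(columns=["mz", "coverage", "is_isotope", "isotope_of"])
    intensities = pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample_id"))
    grp = None
    if groups is not None:
        grp = pd.Series({s: groups[s] for s in sample_ids}, name="group")
    logger.info("align_samples: %d samples, %d pooled peaks -> %d features",
                n, len(mz), len(feat_rows))
    return FeatureMatrix(intensities, features, grp)


def annotate_isotopes(fm: FeatureMatrix, params: ProcessingParams) -> FeatureMatrix:
    """Flag M+1 (13C) isotopologue features (singly charged only).

    A heavier feature is flagged as the isotope of a lighter one when their
    spacing matches the 13C-12C delta within max(ppm, mzabs) tolerance,
    they co-occur in at least ``minfrac`` of the samples, and the median
    M+1/M intensity ratio is plausible for the carbon count implied by the
    m/z (ratio <= 1.2 * 0.0107 * mz/12).
    """
    iso = params.isotope
    feats = fm.features.sort_values("mz")
    ids = feats.index.to_numpy()
    mzs = feats["mz"].to_numpy()
    flagged = dict.fromkeys(fm.features.index, "")
    X = fm.intensities
    for i in range(len(ids)):
        if flagged[ids[i]]:
            continue
        target = mzs[i] + C13_C12_DELTA
        tol = max(mzs[i] * iso.ppm / 1e6, iso.mzabs)
        for j in range(i + 1, len(ids)):
            if mzs[j] > target + tol:
                break
            if abs(mzs[j] - target) > tol or flagged[ids[j]]:
                continue
            a, b = X[ids[i]], X[ids[j]]
            both = a.notna() & b.notna()
            if both.sum() / len(X) < iso.minfrac:
                continue
            ratio = float((b[both] / a[both]).median())
            c_max = mzs[i] / 12.0
            if not (0 < ratio <= 1.2 * C13_ABUNDANCE * c_max):
                continue
            flagged[ids[j]] = ids[i]
    features = fm.features.copy()
    features["isotope_of"] = pd.Series(flagged)
    features["is_isotope"] = features["isotope_of"] != ""
    logger.info("annotate_isotopes: %d of %d features flagged",
                int(features["is_isotope"].sum()), len(features))
    return FeatureMatrix(fm.intensities, features, fm.groups)


# ---------------------------------------------------------------------------
# Readers / writers

def _decode_binary(text: str, precision: int, compressed: bool,
                   byte_order: str = "<") -> np.ndarray:
    import base64
    import zlib

    raw = base64.b64decode(text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    dtype = np.dtype(f"{byte_order}f{precision // 8}")
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> List[Scan]:
    """Read centroided scans from an mzML file.

    Minimal centroid reader covering the standard encodings (32/64-bit
    float, optional zlib compression); array roles and polarity are taken
    from the PSI-MS cvParam accessions.
    """
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    scans: List[Scan] = []
    for _, spectrum in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        accessions = {cv.get("accession")
                      for cv in spectrum.iter(f"{ns}cvParam")}
        polarity = "negative" if "MS:1000129" in accessions else "positive"
        arrays: Dict[str, np.ndarray] = {}
        for bda in spectrum.iter(f"{ns}binaryDataArray"):
            acc = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
            precision = 32 if "MS:1000521" in acc else 64
            compressed = "MS:1000574" in acc
            role = ("mz" if "MS:1000514" in acc
                    else "intensity" if "MS:1000515" in acc else None)
            binary = bda.find(f"{ns}binary")
            if role and binary is not None and binary.text:
                arrays[role] = _decode_binary(binary.text, precision, compressed)
        if "mz" in arrays and "intensity" in arrays:
            scans.append(Scan(int(spectrum.get("index", len(scans))) + 1,
                              PeakList(arrays["mz"], arrays["intensity"]),
                              polarity))
        spectrum.clear()
    return scans


def read_mzxml(path: str | Path) -> List[Scan]:
    """Read centroided scans from an mzXML file (network-order m/z,
    intensity pairs, optional zlib compression)."""
    from lxml import etree

    scans: List[Scan] = []
    for _, scan in etree.iterparse(
            str(path), tag="{http://sashimi.sourceforge.net/schema_revision/mzXML_3.2}scan"):
        nsmap = scan.tag.rsplit("}", 1)[0] + "}"
        polarity = "negative" if scan.get("polarity") == "-" else "positive"
        peaks_el = scan.find(f"{nsmap}peaks")
        if peaks_el is None or not peaks_el.text:
            continue
        precision = int(peaks_el.get("precision", "32"))
        compressed = peaks_el.get("compressionType", "none") == "zlib"
        order = "<" if peaks_el.get("byteOrder") == "little" else ">"
        data = _decode_binary(peaks_el.text, precision, compressed, order)
        scans.append(Scan(int(scan.get("num", len(scans) + 1)),
                          PeakList(data[0::2], data[1::2]), polarity))
        scan.clear()
    return scans


def read_peak_table(path: str | Path) -> Dict[str, List[Scan]]:
    """Read the plain-text peak-table dialect: CSV with columns
    sample_id, scan, mz, intensity. Returns scans grouped by sample."""
    df = pd.read_csv(path)
    required = {"sample_id", "scan", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    out: Dict[str, List[Scan]] = {}
    for sid, sample_df in df.groupby("sample_id", sort=False):
        scans = [Scan(int(scan), PeakList(g["mz"].to_numpy(), g["intensity"].to_numpy()))
                 for scan, g in sample_df.groupby("scan", sort=True)]
        out[str(sid)] = scans
    return out


def write_feature_matrix(fm: FeatureMatrix, intensities_path: str | Path,
                         features_path: str | Path) -> None:
    fm.intensities.to_csv(intensities_path, float_format="%.6f")
    fm.features.to_csv(features_path, float_format="%.6f")


def read_feature_matrix(intensities_path: str | Path,
                        features_path: str | Path) -> FeatureMatrix:
    intensities = pd.read_csv(intensities_path, index_col=0)
    features = pd.read_csv(features_path, index_col=0)
    features["isotope_of"] = features.get("isotope_of", "").fillna("")
    features["is_isotope"] = features["isotope_of"] != ""
    return FeatureMatrix(intensities, features)
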