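# Methods

This note documents the models, parameter choices and numerical
conventions behind `lipidims`, and what the synthetic experiments do and
do not demonstrate.

## Mass arithmetic and annotation

Monoisotopic masses use IUPAC atomic masses to ≥ 6 decimals for C, H, N,
O, P, Na, S; ion m/z applies the electron mass (5.48580 × 10⁻⁴ Da) once
per elementary charge, because published ion values are charged-species
masses — at m/z 876 the electron is 0.6 ppm, comparable to the
instrument accuracy being modelled. Charge states |z| > 1 are out of
scope (the isotope annotator enforces z = 1).

Lipid formulas come from per-class anchor compositions (e.g. TAG 52:0 =
C₅₅H₁₀₆O₆, PC 36:0 = C₄₄H₈₈NO₈P, SM 36:1 = C₄₁H₈₃N₂O₆P, CE 18:2 =
C₄₅H₇₆O₂) with CH₂ added per acyl carbon and H₂ removed per double bond.
Anchoring on published reference formulas, rather than building acyl
chains from structural first principles, guarantees exact agreement with
the reference compositions; the cost is that each class template must be
seeded with one verified formula. Carbon ranges iterate all integers —
odd-carbon TAGs occur in plasma and are kept.

The default adduct registry covers [M+H]⁺, [M+NH₄]⁺, [M+Na]⁺ (the forms
seen with ammonium-acetate infusion in positive mode), in-source water
loss [M+H−H₂O]⁺ (sterols), and [M−H]⁻.

### Kendrick series inference

The Kendrick mass defect (KMD) convention is round-to-nearest, mapped to
[−0.5, 0.5) — symmetric and stable for lipid masses whose fractional
part sits near 0.8. Series membership requires the KMD residual against
an exact-mass anchor to be ≤ 0.0015 Kendrick units: the nearest
competing shift, a double bond (H₂), moves KMD by ≈ 0.0134 at TAG
masses, so the default tolerance separates the two by roughly 9×.

One subtlety the KMD residual alone does not catch: KMD is a mod-1
quantity, so any two masses whose Kendrick masses differ by an *integer*
share a KMD, including pairs separated by, say, 74 Da, which is not a
multiple of CH₂ (14 in Kendrick scale). Series assignment therefore
additionally requires the Kendrick-mass difference to be within 0.5 of
`14 × offset`. Without this guard, a phosphoethanolamine-ether internal
standard at m/z 776.69 is mis-assigned to a TAG series in the default
simulation.

The "referenced" KMD primitive returns (offset in repeat units, KMD
residual) against a named anchor rather than a global series table; this
reference-point reading is this package's operationalization, and the
inferred composition of a series hit is always re-expressed as a theoretical
m/z so downstream consumers can see the implied ppm error.

## Spectral processing

Stage order is fixed — average → recalibrate → filter → align → isotope
annotation — and each stage logs counts in/out; no stage increases the
peak count.

* **Averaging.** Scans 20–70 (inclusive) are pooled and grouped with the
  same ppm window used for alignment; group intensity is the sum divided
  by the number of in-range scans, i.e. a peak absent from a scan counts
  as zero. The 2000-count cutoff applies to this *averaged* intensity,
  with strictly-below removal; applying it post-average rather than
  per scan keeps intermittent low peaks whose duty cycle is high enough
  to matter and is stable against per-scan jitter.
* **Recalibration.** Standards are located within 20 ppm of their
  expected m/z (most intense candidate). The ppm-error model is robust:
  the constant model is the exact median of the standard errors; the
  linear-in-m/z model is a least-absolute-deviation line (median
  regression). Robustness matters because one mis-picked standard peak
  must not drag the whole mass axis. At least two located standards are
  required; failure raises an error carrying the per-standard search
  report.
* **Contaminant removal.** Exact rejection entries (m/z ± absolute
  tolerance) plus mass-defect windows: phthalate-family plasticizer ions
  cluster at fractional masses 0.24–0.33 in the 340–460 nominal range,
  where no common lipid ion sits (the closest, the cholesterol fragment
  at 369.3516, has defect 0.35). Both lists ship as editable defaults —
  the real instrument-specific lists are facility property.
* **Alignment.** Pooled peaks are grouped by single-linkage in relative
  ppm distance; in one dimension this is exactly "split at consecutive
  gaps > 22 ppm", which is what the implementation does (and what the
  exhaustive pairwise-oracle test verifies). A chained group whose total
  span exceeds the window is split at its largest internal gap,
  deterministically. Features covering < 60 % of samples are dropped;
  when one sample contributes several peaks to a feature the maximum
  intensity is kept; consensus m/z is the intensity-weighted mean.
* **Isotopes.** A feature pair is an M/M+1 candidate at spacing
  1.00336 Da (z = 1 only) within max(5 ppm, 0.001 Da). The M+1/M ratio
  must be ≤ 1.2 × 0.0107 × C_max with C_max = m/z / 12 — a deliberately
  coarse carbon-count cap (no formula is assumed at this stage) that
  still rejects ratios no plausible lipid can produce — and the pair
  must co-occur in ≥ 25 % of samples.

Readers: a minimal centroid mzML/mzXML reader (base64 / zlib decoding,
array roles and polarity from PSI-MS cvParam accessions and mzXML
attributes), plus a plain CSV peak-table dialect
(sample_id, scan, mz, intensity) used by the fixture generator.
Polarity is processed separately end to end; defaults are positive mode.

## Chemometrics

Class membership is coded y ∈ {0, 1} and variables are unit-variance
scaled by default (pareto and none selectable) — UV is the convention of
the chemometrics software this analysis style comes from, and the
TAG-proportion variables span two orders of magnitude, so centring alone
would let the abundant species dominate.

The O2PLS-DA fit is the orthogonal-signal-correction decomposition for
a single response: the predictive weight w ∝ X'y is computed once, each
orthogonal component is the part of the X loading orthogonal to w
(removed by deflation), and the final predictive component is fitted on
the deflated matrix. One predictive component is used for two-class
problems; the orthogonal count is user-set, with a helper that adds
components while Q² improves by > 1 percentage point. With n_orth = k
the cross-validated predictions coincide exactly with a (k+1)-component
PLS regression — the known single-y equivalence — which the test suite
exploits as an independent oracle (scikit-learn's NIPALS PLS).

Q² = 100·(1 − PRESS/SS) under 7-fold cross-validation; folds are
venetian-blind over a seeded shuffle of sample order, and the *entire*
pipeline (centring, scaling, orthogonal filtering) is re-estimated
inside each training fold. CV-ANOVA is the F-test of
((SS − PRESS)/d₁) / (PRESS/d₂) with d₁ = number of fitted components and
d₂ = N − 1 − d₁; when PRESS ≥ SS the model explains nothing and p = 1 is
returned. This is a published formulation of the test; proprietary
details of the commercial implementation (exact fold assignment,
degrees-of-freedom bookkeeping) differ in unspecified ways, so numeric
p-values should be compared between runs of *this* package only.

S-plot values are cov(t, x) and corr(t, x) against the predictive score,
computed on the scaled matrix; variables are ranked by |corr| then
|cov|, and zero-variance variables report a missing correlation rather
than a crash.

Univariate testing defaults to Welch (unequal variances — group
variances in patient cohorts are routinely unequal; the pooled Student
variant is selectable). Bonferroni significance is declared iff
p ≤ α/m with m the number of variables tested; both the raw p and the
threshold are reported. Fold changes are ratios of group arithmetic
means. ΔΔCt: ΔCt = Ct(gene) − Ct(reference gene) per sample, ΔΔCt =
group-mean difference against the reference group, relative expression
2^(−ΔΔCt). PCA is a centred SVD with the deterministic sign convention
that each component's largest-magnitude loading is positive.

TAG-pool normalization divides each TAG variable by the sample's summed
TAG signal, so models see pool *composition*, not total TAG load — the
lipodystrophy phenotype includes gross hypertriglyceridaemia, and
without this step every TAG would separate the groups for the trivial
reason.

## SEC fraction profiling

Lipoprotein classes elute in size order VLDL → LDL → HDL. Extracted-ion
traces sum peak intensity within m/z ± 5 ppm per fraction; profiles are
normalized to unit mass and scored as shares inside named, non-overlapping
fraction windows. A lipid is called window-specific when its top share is
≥ 0.8 — an operationalization of "specific for" one particle class; the
threshold is configurable. Window boundaries are user configuration
(they depend on column and flow rate); the defaults are three contiguous
windows over nine fractions.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with every draw a pure function of (design, seed):

* **Abundances** are log-normal per species around group geometric means
  with a 30 % coefficient of variation — multiplicative noise is the
  norm for electrospray intensities; group effects are multiplicative.
* **The human design** is 27 controls / 14 lipodystrophy / 7 insulin
  receptoropathy over a 28-species panel (22 TAGs, PCs, SMs, CE, DAG).
  Lipodystrophy raises TAG(50:1), TAG(48:1), TAG(48:0), TAG(46:1) by
  1.7× and lowers TAG(52:3), TAG(54:4), TAG(52:4) to 0.6×; the insulin-
  receptoropathy group carries sphingomyelin/PC effects but *no* TAG
  effects. The effect magnitudes were scaled once so that the LD-vs-
  control TAG model cross-validates at Q² ≈ 0.55–0.85 across seeds at
  these group sizes — a clear but non-trivial separation; smaller
  effects made the separation fail entirely on some seeds, which would
  defeat the scenario's purpose.
* **The mouse design** is wild-type / ob-ob × chow / high-fat, n = 9 per
  group, 14 TAG species, with TAG(50:1) planted at 2.1× (ob-ob chow vs
  wt chow) and 0.5× (wt high-fat vs wt chow), hence 4.2× for ob-ob chow
  vs wt high-fat; shorter saturated TAGs rise with de novo lipogenesis
  and polyunsaturated TAGs rise when it is suppressed.
* **Spectra**: each species contributes its adduct ions at theoretical
  m/z with a per-sample ppm bias (the drift recalibration corrects;
  default spread 2 ppm between samples) plus 1 ppm per-peak jitter,
  an M+1 isotopologue at the binomial ratio 0.0107 × C, the six
  internal standards at spike-proportional intensity, and three
  plasticizer contaminants. 75 scans are emitted (indices 1–75) with
  5 % per-scan log-normal intensity jitter so the default 20–70
  averaging window is interior.
* **SEC series**: designed per-window shares (e.g. short saturated TAGs
  92 % VLDL; long TAGs 55/40 VLDL/LDL; CE spread everywhere) spread
  triangularly within windows over nine fractions.
* **Ct tables** plant ΔΔCt shifts on a five-gene lipogenesis panel
  (FASN, ACACA, SREBP1F, SCD1, GPAM) against an 18S reference with
  per-well Gaussian noise.

What passing tests on these fixtures shows: that the pipeline recovers
planted mass errors, contaminants, isotopologues, species identities,
fold changes and group structure under realistic noise magnitudes. What
it does not show: behaviour under ion suppression, correlated biological
covariance between lipids, missing-not-at-random dropout, chimeric
peaks, or full-plasma spectral complexity (hundreds of co-occurring
species) — real-data performance claims need real data.

## Numerical conventions and degenerate inputs

Ties in alignment splitting go to the largest internal gap, first
occurrence; zero-variance columns receive a unit scaling divisor (they
are centred to zero and carry no weight); a fold whose training half
loses a class raises rather than silently refitting; zero total TAG
signal in a sample is an error naming the sample; all-zero SEC profiles
cannot be normalized and say so. Cross-validation fold assignment,
cohort generation and spectrum simulation take explicit seeds; fixture
CSVs are written at fixed precision so identical seeds give identical
bytes.

## Problem sizes

Default analyses run the full 48-sample human cohort and 36-sample mouse
cohort (≈ 130 peaks × 75 scans per sample); the alignment-oracle checks
use 50 instances of ≤ 200 pooled peaks, and the multi-seed recovery
checks average 5 seeds (10 for null-behaviour frequencies) — sizes at
which every claim in the test suite recomputes in seconds while keeping
the cohort structure at the scale the scenarios describe.

## Known limitations

Two-class models only (the three-group comparisons in this analysis
style are run pairwise); no MS/MS identity confirmation — annotation is
exact-mass plus series inference, and near-isobars (e.g. TAG(58:0)
[M+Na]⁺ vs TAG(60:3) [M+H]⁺ at 2.5 ppm) are returned as ranked
alternatives rather than resolved; no profile-mode centroiding or vendor
raw-file reading; no retention-time dimension (direct infusion has
none); CV-ANOVA p-values are formulation-specific as noted above.
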