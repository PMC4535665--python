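#!/usr/bin/env python
"""TAG-pool chemometrics on the human cohort.

Normalizes TAG intensities to within-sample proportions and fits
two-class O2PLS-DA models: lipodystrophy (LD) vs control separates
(Q2 > 50 %), with shorter saturated TAGs at one S-plot extreme and
polyunsaturated TAGs at the other, while insulin receptoropathy (INSR)
vs control does not cross-validate — the headline contrast of the
human scenario.
Bonferroni-controlled Welch t-tests give the univariate view.

Run from the repository root: python analysis/03_tag_chemometrics.py
(expects nothing on disk; simulates and processes in memory, ~5 s)
"""

import json
from pathlib import Path

import pandas as pd

from lipidims import chemometrics as chem
from lipidims.pipeline import (
    PipelineConfig,
    annotate_features,
    process_samples,
    species_matrix,
)
from lipidims.synthetic_data import (
    default_human_design,
    generate_cohort,
    simulate_spectrum,
)

SEED = 1
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    design = default_human_design(SEED)
    abund, truth = generate_cohort(design)
    scans = {sid: simulate_spectrum(abund.loc[sid], design, sid)
             for sid in abund.index}
    cfg = PipelineConfig(input_dir=Path("."), out_dir=Path("."),
                         groups=design.group_of.to_dict(), seed=SEED)
    fm, _ = process_samples(scans, cfg)
    annotations, _ = annotate_features(fm, cfg)
    species = species_matrix(
        fm, annotations, exclude_mzs=[s.expected_mz for s in cfg.standards])
    tags = [c for c in species.columns if c.startswith("TAG(")]
    prop = chem.normalize_tag_pool(species, tags)
    groups = fm.groups

    reports = {}
    for pair, n_orth in [(("control", "LD"), 1), (("control", "INSR"), 0)]:
        key = f"{pair[1]}_vs_{pair[0]}"
        sel = groups.isin(pair)
        X = prop.loc[sel.index[sel]]
        y = (groups[sel] == "control").astype(int)
        model = chem.fit_o2plsda(X, y, n_orth=n_orth, cv_seed=SEED)
        reports[key] = model.summary()
        print(f"{key}: R2X={model.r2x:.1f}% R2Y={model.r2y:.1f}% "
              f"Q2={model.q2:.1f}% CV-ANOVA p={model.cv_anova_p:.2g}")
        if pair[1] == "LD":
            splot = chem.s_plot(model, X)
            splot.to_csv(RESULTS / "03_splot_LD_vs_control.csv",
                         float_format="%.4f")
            extremes = splot["p_corr"].sort_values()
            print("  S-plot LD extreme:", list(extremes.index[:4]))
            print("  S-plot control extreme:", list(extremes.index[-4:]))
            uni = chem.ttest_bonferroni(X, groups[sel], ("LD", "control"))
            uni.to_csv(RESULTS / "03_univariate_LD_vs_control.csv",
                       float_format="%.4g")
            n_bonf = int(uni["significant"].sum())
            n_raw = int((uni["p"] <= 0.05).sum())
            print(f"  TAG species different LD vs control: {n_bonf} after "
                  f"Bonferroni ({n_raw} at raw p<=0.05) of {len(uni)}")

    (RESULTS / "03_model_reports.json").write_text(
        json.dumps(reports, indent=2))


if __name__ == "__main__":
    main()
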