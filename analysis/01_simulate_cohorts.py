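#!/usr/bin/env python
"""Write the synthetic study fixtures to disk.

Generates the human cohort (27 controls, 14 lipodystrophy, 7 insulin
receptoropathy; 48 samples, with the plasma lipid panel of the human
scenario) and the
mouse de-novo-lipogenesis cohort (wild-type / ob-ob x chow / high fat,
n = 9 per group) as per-sample peak-table CSVs plus ground-truth tables,
under scratch/fixtures/. A small design summary goes to results/.

Run from the repository root: python analysis/01_simulate_cohorts.py
"""

from pathlib import Path

import pandas as pd

from lipidims.synthetic_data import (
    default_human_design,
    generate_mouse_design,
    write_fixture_set,
)

SEED = 1
SCRATCH = Path("scratch/fixtures")
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, design in [("human", default_human_design(SEED)),
                         ("mouse", generate_mouse_design(SEED))]:
        out = SCRATCH / name
        write_fixture_set(design, out)
        n_files = len(list((out / "spectra").glob("*.csv")))
        print(f"{name}: {n_files} sample spectra -> {out}")
        for g in design.groups:
            effects = {s: f for s, f in g.effects}
            rows.append({
                "cohort": name, "group": g.name, "n": g.size,
                "n_planted_effects": len(effects),
                "planted_effects": "; ".join(f"{s}x{f}" for s, f
                                             in sorted(effects.items())),
            })
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "01_design_summary.csv", index=False)
    print(summary.to_string(index=False, max_colwidth=60))


if __name__ == "__main__":
    main()
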