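import numpy as np
import pandas as pd
import pytest

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


@pytest.fixture(scope="session")
def human_run():
    """Default human cohort (27 control / 14 LD / 7 INSR) simulated and
    pushed through the full processing chain once per session."""
    design = default_human_design(seed=7)
    abund, truth = generate_cohort(design)
    scans = {sid: simulate_spectrum(abund.loc[sid], design, sid)
             for sid in abund.index}
    cfg = PipelineConfig(input_dir=".", out_dir=".",
                         groups=design.group_of.to_dict())
    fm, stage_log = process_samples(scans, cfg)
    annotations, _ = annotate_features(fm, cfg)
    species = species_matrix(fm, annotations,
                             exclude_mzs=[s.expected_mz for s in cfg.standards])
    tag_cols = [c for c in species.columns if c.startswith("TAG(")]
    tag_prop = chem.normalize_tag_pool(species, tag_cols)
    return {
        "design": design, "truth": truth, "fm": fm, "stage_log": stage_log,
        "annotations": annotations, "species": species, "tag_prop": tag_prop,
        "groups": fm.groups,
    }


@pytest.fixture()
def two_class_fixture():
    """Well-separated two-class Gaussian data: 3 of 50 variables carry a
    5-sigma mean shift, 10 samples per class."""
    rng = np.random.default_rng(42)
    n, p = 20, 50
    X = rng.normal(size=(n, p))
    y = np.repeat([0, 1], n // 2)
    X[y == 1, :3] += 5.0
    return (pd.DataFrame(X, columns=[f"v{i}" for i in range(p)]),
            pd.Series(y))
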