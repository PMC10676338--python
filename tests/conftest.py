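import numpy as np
import pandas as pd
import pytest

from combatcv import SyntheticConfig, generate_cohort, generate_feature_matrix


def toy_phenotypes(rows: list[dict]) -> pd.DataFrame:
    """Build a phenotype table from partial row dicts with sane defaults."""
    defaults = {
        "site": "siteA", "diagnosis": "TD", "age": 12.0, "sex": "M",
        "eye_status": "open", "fiq": 100.0, "mean_fd": 0.1,
        "struct_ok": True, "func_ok": True,
    }
    out = []
    for i, row in enumerate(rows):
        r = {"subject_id": f"sub-{i + 1:04d}", **defaults, **row}
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-site cohort with features, shared by read-only tests."""
    cfg = SyntheticConfig(
        n_sites=3, subjects_per_site=40, n_features=20,
        fd_outlier_rate=0.0, struct_success_rate=1.0, func_success_rate=1.0,
    )
    pheno = generate_cohort(cfg, seed=42)
    feats, truth = generate_feature_matrix(pheno, cfg, seed=42)
    return cfg, pheno, feats, truth
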