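import numpy as np
import pytest

import refmine as rm
from refmine import aging, cleaning


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized cohort under the default generative conditions."""
    cfg = rm.CohortConfig(n_total=10_000, seed=7)
    records, truth = rm.generate_cohort(cfg)
    return records, truth


@pytest.fixture(scope="session")
def aging_fit():
    """Track-2 style fit shared by the age-model acceptance checks:
    default 15k cohort -> covariate cascade -> sex-grouped iterative
    Tukey -> 70/30 split -> BCCG fits per sex selected by SBC."""
    cfg = rm.CohortConfig(n_total=15_000, seed=11)
    records, truth = rm.generate_cohort(cfg)
    filtered, _ = cleaning.apply_filter_cascade(
        records, cleaning.default_filter_rules())
    ds2, _ = cleaning.iterative_tukey_filter(filtered, ["sex"])
    train, valid = aging.split_train_validation(ds2, seed=2)
    best = {}
    for sex in (0, 1):
        models = aging.fit_age_model(train, sex,
                                     candidate_dfs=(2, 3, 4, 5, 6, 7, 8))
        best[sex] = aging.select_model(models)
    return {"truth": truth, "train": train, "valid": valid, "models": best}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
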