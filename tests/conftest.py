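"""Shared fixtures: one medium synthetic dataset and its fitted measurement model.

The expensive diffusion-IRT fit is computed once per session and reused by
the unit tests and the acceptance suite.
"""
import numpy as np
import pytest

from emadiff import data_model, diffirt, synthetic


@pytest.fixture(scope="session")
def synth_medium():
    """~2,200 scheduled occasions with known item/person truth."""
    cfg = synthetic.SyntheticConfig(seed=11, n_persons=70)
    records, truth = synthetic.generate_dataset(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def affect_occasions(synth_medium):
    cfg, records, _ = synth_medium
    occ, accounting = data_model.preprocess(records, synthetic.affect_item_set(cfg))
    return occ, accounting


@pytest.fixture(scope="session")
def affect_fit(synth_medium, affect_occasions):
    cfg, _, _ = synth_medium
    occ, _ = affect_occasions
    return diffirt.fit_item_parameters(
        occ, item_ids=list(synthetic.affect_item_set(cfg).items)
    )


@pytest.fixture(scope="session")
def affect_scores(affect_occasions, affect_fit):
    occ, _ = affect_occasions
    return diffirt.score_occasions(occ, affect_fit)


@pytest.fixture(scope="session")
def scores_with_truth(synth_medium, affect_scores):
    """Scored occasions joined with the generator's per-occasion truth."""
    _, _, truth = synth_medium
    sdf = diffirt.scores_to_frame(affect_scores)
    tocc = truth.occasions[
        ["person_id", "occasion_id", "theta", "log_gamma", "ter", "work", "recovery"]
    ].rename(columns={"theta": "theta_true", "log_gamma": "log_gamma_true",
                      "ter": "ter_true"})
    return sdf.merge(tocc, on=["person_id", "occasion_id"], how="left")
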