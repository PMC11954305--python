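"""Shared fixtures: generated once per session, certified ground truth.

The scorer metric matrix is computed lazily and cached so that the score
trainability and noise-recovery tests share one tuning/training run per
(seed, noise) cell.
"""

import pytest
from hypothesis import settings

from insynth.fixtures import (
    FixtureSpec,
    gen_reaction_universe,
    gen_solvable,
    gen_triage_fixture,
    gen_unsolvable,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec0():
    return FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def universe(spec0):
    """(templates, stock, stock_records) for the seed-0 fixture universe."""
    return gen_reaction_universe(spec0)


@pytest.fixture(scope="session")
def solvable_set(spec0, universe):
    templates, stock, stock_records = universe
    return gen_solvable(spec0, templates, stock, stock_records)


@pytest.fixture(scope="session")
def unsolvable_set(spec0, solvable_set, universe):
    templates, stock, _ = universe
    return gen_unsolvable(spec0, solvable_set, templates, stock)


@pytest.fixture(scope="session")
def triage_fixture():
    return gen_triage_fixture(seed=0)


@pytest.fixture(scope="session")
def scorer_matrix():
    """Memoized (seed, eps) -> held-out metrics for the planted-rule fixture.

    Pipeline per cell: 20% stratified holdout -> seeded random-search CV
    tuning (10 rounds) -> final fit -> held-out evaluation.  Shared by the
    trainability and noise-recovery acceptance tests.
    """
    from insynth.fixtures import gen_planted_dataset
    from insynth.scorer import (
        LabeledDataset,
        evaluate,
        stratified_holdout,
        train_final,
        tune_hyperparameters,
    )

    cache = {}

    def compute(seed: int, eps: float):
        key = (seed, round(eps, 3))
        if key not in cache:
            records, noisy, _true = gen_planted_dataset(seed, 500, eps)
            dataset = LabeledDataset(records=records, labels=noisy)
            train, test = stratified_holdout(dataset, test_fraction=0.2, seed=seed)
            params, _log = tune_hyperparameters(train, n_rounds=10, seed=seed)
            model = train_final(train, params, seed=seed)
            cache[key] = evaluate(model, test)
        return cache[key]

    return compute
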