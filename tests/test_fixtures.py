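"""Fixture generators: certification, determinism and statistical structure."""

import json
import os

import numpy as np
import pytest
from rdkit import Chem

from insynth.fixtures import (
    FixtureSpec,
    gen_activity_table,
    gen_planted_dataset,
    gen_reaction_universe,
    make_templates,
    template_compatibility,
    write_fixture_set,
)
from insynth.planner import bfs_oracle, validate_route


def test_universe_every_stock_member_compatible(universe):
    templates, stock, stock_records = universe
    assert stock.size == len(stock_records) == 30
    for record in stock_records:
        assert template_compatibility(record, templates) >= 2, record.smiles_canonical


def test_template_priors_vary_with_seed():
    p0 = [t.prior for t in make_templates(0)]
    p1 = [t.prior for t in make_templates(1)]
    assert p0 != p1
    assert [t.id for t in make_templates(0)] == [t.id for t in make_templates(1)]


def test_solvable_molecules_certified(universe, solvable_set):
    templates, stock, _ = universe
    assert len(solvable_set) == 50
    for solv in solvable_set:
        assert solv.oracle.solved
        assert solv.oracle.min_steps <= solv.built_steps
        assert validate_route(solv.witness_route, stock, templates)


def test_unsolvable_molecules_certified(universe, unsolvable_set):
    cf3 = Chem.MolFromSmarts("C(F)(F)F")
    assert len(unsolvable_set) == 20
    for unsolv in unsolvable_set:
        assert unsolv.oracle.feasible and not unsolv.oracle.solved
        assert unsolv.record.mol is not None  # parse-valid
        assert unsolv.record.mol.HasSubstructMatch(cf3)


def test_unsolvable_certification_reproducible(universe, unsolvable_set):
    templates, stock, _ = universe
    oracle = bfs_oracle(unsolvable_set[0].record, stock, templates, max_depth=4)
    assert oracle.feasible and not oracle.solved


def test_planted_dataset_balance_and_rule():
    records, noisy, true = gen_planted_dataset(0, 500, 0.0)
    assert len(records) == 500
    assert abs(int(true.sum()) - 250) <= 1
    np.testing.assert_array_equal(noisy, true)  # eps=0: no flips
    patt = Chem.MolFromSmarts("c1ccncc1")
    for record, label in zip(records[:100], true[:100]):
        assert int(record.mol.HasSubstructMatch(patt)) == label


def test_planted_dataset_noise_nested_and_calibrated():
    records, n1, true = gen_planted_dataset(0, 500, 0.1)
    _, n2, _ = gen_planted_dataset(0, 500, 0.2)
    flips1 = set(np.flatnonzero(n1 != true))
    flips2 = set(np.flatnonzero(n2 != true))
    assert flips1 <= flips2  # nested corruption
    assert abs(len(flips2) / 500 - 0.2) <= 0.04


def test_activity_table_eps0_recovers_planted_rule():
    records, _, _ = gen_planted_dataset(0, 500, 0.0)
    spec = FixtureSpec(seed=0, label_noise=0.0)
    table = gen_activity_table(spec, records)
    observed = (table["pchembl"] > spec.pchembl_threshold).astype(int)
    mismatch = (observed != table["planted"]).mean()
    assert mismatch < 0.02  # Gaussian tail crossings only


def test_activity_table_flip_rate_calibrated():
    records, _, _ = gen_planted_dataset(0, 500, 0.0)
    spec = FixtureSpec(seed=0, label_noise=0.2)
    table = gen_activity_table(spec, records)
    observed = (table["pchembl"] > spec.pchembl_threshold).astype(int)
    flip_rate = (observed != table["planted"]).mean()
    assert abs(flip_rate - 0.2) <= 0.04


def test_activity_table_deterministic():
    records, _, _ = gen_planted_dataset(0, 500, 0.0)
    spec = FixtureSpec(seed=0)
    a = gen_activity_table(spec, records[:50]).to_csv(index=False)
    b = gen_activity_table(spec, records[:50]).to_csv(index=False)
    assert a == b


def test_activity_table_years_in_range():
    records, _, _ = gen_planted_dataset(0, 500, 0.0)
    spec = FixtureSpec(seed=0)
    table = gen_activity_table(spec, records[:100])
    lo, hi = spec.year_range
    assert table["year"].between(lo, hi).all()


def test_write_fixture_set_deterministic_and_text_sized(tmp_path):
    spec = FixtureSpec(seed=0, n_solvable=10, n_unsolvable=5)
    d1, d2 = str(tmp_path / "a"), str(tmp_path / "b")
    paths1 = write_fixture_set(spec, d1)
    paths2 = write_fixture_set(spec, d2)
    assert set(paths1) == {
        "templates",
        "stock",
        "solvable",
        "unsolvable",
        "ligands",
        "ground_truth",
    }
    for key in paths1:
        with open(paths1[key], "rb") as fa, open(paths2[key], "rb") as fb:
            assert fa.read() == fb.read(), key
        assert os.path.getsize(paths1[key]) < 64 * 1024
    truth = json.load(open(paths1["ground_truth"]))
    assert truth["spec"]["seed"] == 0


def test_triage_fixture_certified_in_generation(triage_fixture):
    fx = triage_fixture
    assert len(fx.candidates) == 20
    assert fx.expected_survivors[0] == 15
    assert fx.expected_survivors[-1] == 8
    assert set(fx.expected_first_fail) == {c.id for c in fx.candidates}
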