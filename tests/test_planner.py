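"""MCTS planner, exhaustive oracle, route validation and batch planning."""

import pytest

from insynth.chem import canonicalize
from insynth.planner import (
    RouteTree,
    SearchConfig,
    batch_plan,
    batch_summary,
    bfs_oracle,
    mcts_search,
    rank_expansions,
    validate_route,
)
from insynth.reactions import apply_forward


SEARCH = SearchConfig(iteration_limit=300, max_depth=4, seed=0)


def test_in_stock_target_is_a_zero_step_route(universe):
    templates, stock, stock_records = universe
    result = mcts_search(stock_records[0], stock, templates, SEARCH)
    assert result.solved
    assert result.shortest_route_length == 0
    assert result.routes[0].n_steps == 0


def test_one_step_product_found_and_validated(universe):
    from rdkit import Chem

    templates, stock, stock_records = universe
    by_id = {t.id: t for t in templates}
    acid_patt = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
    amine_patt = Chem.MolFromSmarts("[NX3;H2;!$(NC=O)]")
    acid = next(r for r in stock_records if r.mol.HasSubstructMatch(acid_patt))
    amine = next(r for r in stock_records if r.mol.HasSubstructMatch(amine_patt))
    product = apply_forward(by_id["amide_coupling"], [acid, amine])[0]
    result = mcts_search(product, stock, templates, SEARCH)
    assert result.solved
    assert result.shortest_route_length == 1
    for route in result.routes:
        assert validate_route(route, stock, templates)


def test_unsolvable_molecule_not_solved(universe, unsolvable_set):
    templates, stock, _ = universe
    result = mcts_search(unsolvable_set[0].record, stock, templates, SEARCH)
    assert not result.solved
    assert result.shortest_route_length is None
    assert result.routes == []


def test_route_signatures_unique(universe, solvable_set):
    templates, stock, _ = universe
    target = next(s for s in solvable_set if s.built_steps >= 2)
    result = mcts_search(target.record, stock, templates, SEARCH)
    signatures = [r.signature() for r in result.routes]
    assert len(signatures) == len(set(signatures))


def test_search_never_undercuts_oracle(universe, solvable_set):
    templates, stock, _ = universe
    for solv in solvable_set[:10]:
        result = mcts_search(solv.record, stock, templates, SEARCH)
        oracle = bfs_oracle(solv.record, stock, templates, max_depth=4)
        assert oracle.feasible
        if result.solved:
            assert result.shortest_route_length >= oracle.min_steps


def test_oracle_certifies_witness_bound(universe, solvable_set):
    templates, stock, _ = universe
    for solv in solvable_set[:10]:
        oracle = bfs_oracle(solv.record, stock, templates, max_depth=4)
        assert oracle.solved
        assert oracle.min_steps <= solv.built_steps


def test_oracle_budget_refusal_is_explicit(universe, solvable_set):
    templates, stock, _ = universe
    target = next(s for s in solvable_set if s.built_steps >= 2)
    oracle = bfs_oracle(target.record, stock, templates, max_depth=4, node_budget=1)
    assert not oracle.feasible
    assert oracle.solved is None


def test_search_is_deterministic(universe, solvable_set):
    templates, stock, _ = universe
    target = solvable_set[0].record
    r1 = mcts_search(target, stock, templates, SEARCH)
    r2 = mcts_search(target, stock, templates, SEARCH)
    assert r1.solved == r2.solved
    assert r1.iterations_used == r2.iterations_used
    assert [r.to_json() for r in r1.routes] == [r.to_json() for r in r2.routes]


def test_route_json_roundtrip(universe, solvable_set):
    templates, stock, _ = universe
    result = mcts_search(solvable_set[0].record, stock, templates, SEARCH)
    route = result.routes[0]
    back = RouteTree.from_json(route.to_json())
    assert back.to_json() == route.to_json()
    assert back.n_steps == route.n_steps


def test_rank_expansions_orders_by_prior_then_id(universe):
    templates, _, _ = universe
    product = canonicalize("CC(=O)NCc1ccccc1")
    ranked = rank_expansions(product, templates, width=50)
    assert ranked
    priors = [t.prior for t, _ in ranked]
    assert priors == sorted(priors, reverse=True)


def test_search_config_validation():
    with pytest.raises(ValueError):
        SearchConfig(iteration_limit=0).validate()
    with pytest.raises(ValueError):
        SearchConfig(max_depth=0).validate()
    assert len(SearchConfig().digest()) == 16


def test_batch_plan_table_and_journal_resume(universe, solvable_set, unsolvable_set, tmp_path):
    templates, stock, _ = universe
    molecules = [s.record for s in solvable_set[:4]] + [u.record for u in unsolvable_set[:2]]
    journal = str(tmp_path / "journal.csv")
    table = batch_plan(molecules, stock, templates, SEARCH, journal_path=journal)
    assert list(table["id"]) == [m.id for m in molecules]
    assert "wall_time_s" not in table.columns  # byte-reproducible by default
    assert table["solved"].iloc[:4].all()
    assert not table["solved"].iloc[4:].any()

    # a rerun with the journal present resumes and reproduces the table
    resumed = batch_plan(molecules, stock, templates, SEARCH, journal_path=journal)
    assert resumed.drop(columns=["from_journal"], errors="ignore").equals(
        table.drop(columns=["from_journal"], errors="ignore")
    )

    summary = batch_summary(table)
    assert summary["n"] == 6
    assert summary["n_solved"] == 4


def test_batch_plan_rejects_empty_input(universe):
    templates, stock, _ = universe
    with pytest.raises(ValueError):
        batch_plan([], stock, templates, SEARCH)
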