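"""Five-stage candidate triage cascade."""

import json

import pytest

from insynth.chem import canonicalize
from insynth.planner import SearchConfig
from insynth.triage import (
    STAGE_NAMES,
    TriageConfig,
    lipinski_pass,
    novelty_score,
    run_cascade,
)


def test_lipinski_clean_druglike_passes():
    ok, violations = lipinski_pass(canonicalize("CC(=O)Oc1ccccc1C(=O)O"))
    assert ok and violations == []


def test_lipinski_classic_tolerates_one_violation():
    # hexadecane: only cLogP exceeds 5 (no HBD/HBA, MW 226)
    mol = canonicalize("CCCCCCCCCCCCCCCC")
    ok_classic, violations = lipinski_pass(mol, mode="classic")
    ok_strict, _ = lipinski_pass(mol, mode="strict")
    assert violations == ["clogp"]
    assert ok_classic and not ok_strict


def test_lipinski_multiple_violations_fail_both_modes():
    greasy = canonicalize("CCCCCCCCCCCCCCCCN(CCCCCCCCCCCCCCCC)C(=O)c1ccncc1")
    ok, violations = lipinski_pass(greasy, mode="classic")
    assert not ok and len(violations) >= 2


def test_novelty_score_argmax_and_empty_error():
    known = [
        canonicalize("CC(=O)Oc1ccccc1C(=O)O", mol_id="aspirin"),
        canonicalize("CCO", mol_id="ethanol"),
    ]
    sim, best = novelty_score(canonicalize("CC(=O)Oc1ccccc1C(=O)O"), known)
    assert sim == 1.0 and best == "aspirin"
    with pytest.raises(ValueError):
        novelty_score(canonicalize("CCO"), [])


def test_triage_config_validation():
    with pytest.raises(ValueError):
        TriageConfig(ro5_mode="lenient")
    with pytest.raises(ValueError):
        TriageConfig(p_active_min=1.5)
    with pytest.raises(ValueError):
        TriageConfig(max_route_steps=-1)


def test_cascade_funnel_matches_engineered_truth(triage_fixture):
    fx = triage_fixture
    report = run_cascade(
        fx.candidates,
        fx.qsar_model,
        fx.score_model,
        fx.stock,
        fx.templates,
        SearchConfig(**fx.search_config),
        fx.known_ligands,
        TriageConfig(**fx.config),
    )
    assert report.stage_names == STAGE_NAMES
    assert report.survivors == fx.expected_survivors
    # monotone funnel
    assert all(a >= b for a, b in zip(report.survivors, report.survivors[1:]))
    # route economy: the planner runs only for probability-stage survivors
    assert report.planner_calls == report.survivors[0]
    # per-candidate first failing stage matches the construction
    for cid, expected in fx.expected_first_fail.items():
        assert report.trace[cid] == expected, cid
    # survivors carry validated routes within the step budget
    shortlist_ids = list(report.shortlist["id"])
    assert len(shortlist_ids) == report.survivors[-1]
    max_steps = TriageConfig(**fx.config).max_route_steps
    for cid in shortlist_ids:
        assert report.routes[cid].n_steps <= max_steps


def test_cascade_shortlist_ranked(triage_fixture):
    fx = triage_fixture
    report = run_cascade(
        fx.candidates,
        fx.qsar_model,
        fx.score_model,
        fx.stock,
        fx.templates,
        SearchConfig(**fx.search_config),
        fx.known_ligands,
        TriageConfig(**fx.config),
    )
    ranks = list(report.shortlist["rank_score"])
    assert ranks == sorted(ranks, reverse=True)


def test_cascade_report_json_stable(triage_fixture):
    fx = triage_fixture
    args = (
        fx.candidates,
        fx.qsar_model,
        fx.score_model,
        fx.stock,
        fx.templates,
        SearchConfig(**fx.search_config),
        fx.known_ligands,
        TriageConfig(**fx.config),
    )
    r1 = run_cascade(*args)
    r2 = run_cascade(*args)
    assert r1.to_json() == r2.to_json()
    payload = json.loads(r1.to_json())
    assert payload["stages"] == list(STAGE_NAMES)


def test_cascade_empty_candidates(triage_fixture):
    fx = triage_fixture
    report = run_cascade(
        [],
        fx.qsar_model,
        fx.score_model,
        fx.stock,
        fx.templates,
        SearchConfig(**fx.search_config),
        fx.known_ligands,
        TriageConfig(**fx.config),
    )
    assert report.survivors == [0] * len(STAGE_NAMES)
    assert len(report.shortlist) == 0
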