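"""Activity objectives: splits, QSAR, complexity heuristic, Pareto front."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from insynth.chem import canonicalize
from insynth.fixtures import FixtureSpec, gen_activity_table, gen_planted_dataset
from insynth.objectives import (
    DesirabilityTransform,
    FragmentFrequencyTable,
    LigandRecord,
    ObjectivePoint,
    apply_desirability,
    heuristic_complexity_score,
    load_ligands,
    murcko_scaffold,
    pareto_front,
    scaffold_split,
    time_split,
    train_qsar,
)


from tests._references import reference_pareto


@pytest.fixture(scope="module")
def ligands(tmp_path_factory):
    records, _, _ = gen_planted_dataset(0, 500, 0.0)
    spec = FixtureSpec(seed=0, label_noise=0.0)
    table = gen_activity_table(spec, records[:160])
    path = tmp_path_factory.mktemp("ligands") / "ligands.csv"
    table.to_csv(path, index=False)
    return load_ligands(str(path))


def test_load_ligands_and_activity_threshold(ligands):
    assert len(ligands) == 160
    for lig in ligands:
        assert lig.active(6.5) == (lig.pchembl > 6.5)


def test_scaffold_split_no_scaffold_overlap(ligands):
    train, test = scaffold_split(ligands, test_fraction=0.2, seed=0)
    assert len(train) + len(test) == len(ligands)
    train_scaffolds = {murcko_scaffold(l.record) for l in train}
    test_scaffolds = {murcko_scaffold(l.record) for l in test}
    assert not (train_scaffolds & test_scaffolds)
    assert 0.05 <= len(test) / len(ligands)  # greedy split still holds some out


def test_time_split_boundary(ligands):
    train, test = time_split(ligands, cutoff_year=2018)
    assert len(train) + len(test) == len(ligands)
    assert all(l.year < 2018 for l in train)
    assert all(l.year >= 2018 for l in test)


def test_train_qsar_recovers_planted_rule(ligands):
    model = train_qsar(ligands, threshold=6.5, seed=0)
    assert model.family in ("xgboost", "random_forest", "knn")
    assert {"split", "family"}.issubset(model.report.columns)
    proba = model.predict_proba_records([l.record for l in ligands[:50]])
    pred = (proba > 0.5).astype(int)
    truth = np.array([int(l.record.mol.HasSubstructMatch(model_patt())) for l in ligands[:50]])
    assert (pred == truth).mean() >= 0.9


def model_patt():
    from rdkit import Chem

    return Chem.MolFromSmarts("c1ccncc1")


def test_complexity_score_bounds_and_ordering():
    simple = heuristic_complexity_score(canonicalize("CCO"))
    complex_ = heuristic_complexity_score(
        canonicalize("CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O")
    )
    assert 1.0 <= simple <= 10.0
    assert 1.0 <= complex_ <= 10.0
    assert simple < complex_


def test_fragment_table_contributions_and_floor(tmp_path):
    table = FragmentFrequencyTable.from_smiles(["CCO", "CCN", "c1ccccc1"])
    assert table.contrib
    # the most common fragment has log-relative-frequency 0; unseen
    # fragments fall back to the floor
    assert max(table.contrib.values()) == pytest.approx(0.0)
    assert table.score(123456789) == table.floor

    path = tmp_path / "frags.csv"
    path.write_text(
        "fragment,count\n"
        + "\n".join(f"{frag},{10}" for frag in list(table.contrib)[:3])
    )
    back = FragmentFrequencyTable.from_file(str(path))
    assert all(back.score(f) == pytest.approx(0.0) for f in list(table.contrib)[:3])


def test_desirability_monotone_and_bounded():
    t = DesirabilityTransform(midpoint=4.5, steepness=1.0, direction="lower_is_better")
    values = [1.0, 3.0, 4.5, 6.0, 9.0]
    out = [apply_desirability(v, t) for v in values]
    assert all(0.0 < d < 1.0 for d in out)
    assert out == sorted(out, reverse=True)  # lower input -> more desirable
    assert apply_desirability(4.5, t) == pytest.approx(0.5)
    t_up = DesirabilityTransform(midpoint=4.5, steepness=1.0, direction="higher_is_better")
    assert apply_desirability(6.0, t_up) > 0.5


def test_objective_point_rejects_nonfinite():
    with pytest.raises(ValueError):
        ObjectivePoint("x", (1.0, float("nan")))


@given(
    st.lists(
        st.tuples(
            st.integers(min_value=-3, max_value=3),
            st.integers(min_value=-3, max_value=3),
        ),
        min_size=1,
        max_size=40,
    )
)
def test_pareto_matches_reference_with_ties(int_points):
    points = [
        ObjectivePoint(str(i), (float(a), float(b))) for i, (a, b) in enumerate(int_points)
    ]
    values = [p.values for p in points]
    assert sorted(pareto_front(points)) == sorted(reference_pareto(values))


def test_pareto_front_is_mutually_nondominated():
    rng = np.random.default_rng(0)
    points = [
        ObjectivePoint(str(i), tuple(v)) for i, v in enumerate(rng.normal(size=(100, 3)))
    ]
    front = pareto_front(points)
    for i in front:
        for j in front:
            if i == j:
                continue
            vi, vj = points[i].values, points[j].values
            assert not (
                all(a >= b for a, b in zip(vj, vi)) and any(a > b for a, b in zip(vj, vi))
            )
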