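"""Library cleaning and Butina sphere-exclusion clustering.

The clustering reference implementation here is written independently of
the package's own (plain double loops over an explicit distance matrix) so
the equivalence check is a genuine oracle, not a mirror of the code under
test.
"""

import numpy as np
import pytest

from insynth.chem import CLUSTERING_FP_PARAMS, canonicalize, morgan_fingerprint, tanimoto
from insynth.curation import (
    CleaningConfig,
    butina_cluster,
    clean_library,
    remove_stock_members,
    select_centroid_subset,
)
from insynth.fixtures import gen_planted_dataset
from insynth.reactions import stock_from_records


from tests._references import reference_butina


@pytest.fixture(scope="module")
def molecule_pool():
    records, _, _ = gen_planted_dataset(0, 500, 0.0)
    return records


def test_butina_matches_independent_reference_small(molecule_pool):
    rng = np.random.default_rng(7)
    for cutoff in (0.4, 0.6):
        idx = rng.choice(len(molecule_pool), size=60, replace=False)
        fps = [morgan_fingerprint(molecule_pool[i], *CLUSTERING_FP_PARAMS) for i in idx]
        ours = butina_cluster(fps, cutoff)
        assert ours.clusters == reference_butina(fps, cutoff)


def test_butina_is_a_partition_within_cutoff(molecule_pool):
    fps = [morgan_fingerprint(r, *CLUSTERING_FP_PARAMS) for r in molecule_pool[:120]]
    cutoff = 0.6
    assignment = butina_cluster(fps, cutoff)
    seen = []
    for centroid, members in assignment.clusters:
        assert centroid in members
        for m in members:
            assert 1.0 - tanimoto(fps[centroid], fps[m]) <= cutoff + 1e-12
        seen.extend(members)
    assert sorted(seen) == list(range(len(fps)))
    labels = assignment.labels(len(fps))
    assert -1 not in labels
    sizes = [len(m) for _, m in assignment.clusters]
    assert sizes == sorted(sizes, reverse=True)


def test_butina_identical_fingerprints_single_cluster():
    mol = canonicalize("c1ccccc1CCN")
    fps = [morgan_fingerprint(mol, *CLUSTERING_FP_PARAMS)] * 5
    assignment = butina_cluster(fps, 0.3)
    assert assignment.n_clusters == 1
    assert assignment.clusters[0][1] == [0, 1, 2, 3, 4]


def test_clean_library_salt_stripping_and_uncharging():
    records = [canonicalize("[Na+].[O-]C(=O)c1ccccc1", mol_id="salt")]
    cleaned, log = clean_library(records, CleaningConfig())
    assert len(cleaned) == 1
    assert cleaned[0].inchikey == canonicalize("OC(=O)c1ccccc1").inchikey


def test_clean_library_rejection_reasons():
    records = [
        canonicalize("CC(=O)O[Hg]c1ccccc1", mol_id="metal"),  # element whitelist
        canonicalize("CCO", mol_id="tiny"),  # below heavy-atom floor
        canonicalize("c1ccc(cc1)C(=O)NCc1ccccc1", mol_id="ok"),
        canonicalize("c1ccc(cc1)C(=O)NCc1ccccc1", mol_id="dup"),
    ]
    cleaned, log = clean_library(records, CleaningConfig())
    assert [r.id for r in cleaned] == ["ok"]
    assert log.counts["element_whitelist"] == 1
    assert log.counts["heavy_atom_range"] == 1
    assert log.counts["duplicate"] == 1


def test_remove_stock_members():
    keep = canonicalize("c1ccc(cc1)C(=O)NCc1ccccc1", mol_id="keep")
    drop = canonicalize("CC(C)Cc1ccc(cc1)C(C)C(=O)O", mol_id="drop")
    stock = stock_from_records([drop])
    filtered, removed = remove_stock_members([keep, drop], [stock])
    assert [r.id for r in filtered] == ["keep"]
    assert removed == 1


def test_select_centroid_subset_counts(molecule_pool):
    records = molecule_pool[:80]
    fps = [morgan_fingerprint(r, *CLUSTERING_FP_PARAMS) for r in records]
    assignment = butina_cluster(fps, 0.6)
    n = min(3, assignment.n_clusters)
    centroids, covered = select_centroid_subset(records, assignment, n)
    assert len(centroids) == n
    assert covered == sum(len(m) for _, m in assignment.clusters[:n])


def test_select_centroid_subset_caps_at_available(molecule_pool):
    records = molecule_pool[:10]
    fps = [morgan_fingerprint(r, *CLUSTERING_FP_PARAMS) for r in records]
    assignment = butina_cluster(fps, 0.6)
    centroids, _ = select_centroid_subset(records, assignment, 10_000)
    assert len(centroids) == assignment.n_clusters
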