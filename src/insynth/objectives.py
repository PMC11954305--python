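"""Activity objective construction and multi-objective utilities.

Covers the QSAR side of candidate generation: ligand tables with pChEMBL
activity labels, scaffold- and time-based train/test splits, model-family
selection by grid search, a fragment-frequency synthetic-complexity
heuristic with a smoothed-clipped desirability transform, and Pareto-front
extraction for multi-objective ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from xgboost import XGBClassifier

from .chem import MoleculeRecord, canonicalize
from .scorer import featurize

DEFAULT_PCHEMBL_THRESHOLD = 6.5
DEFAULT_CUTOFF_YEAR = 2018


@dataclass
class LigandRecord:
    """A molecule with measured bioactivity (pChEMBL) and assay year."""

    record: MoleculeRecord
    pchembl: float
    year: int

    def active(self, threshold: float = DEFAULT_PCHEMBL_THRESHOLD) -> bool:
        return self.pchembl >= threshold


def load_ligands(path: str) -> List[LigandRecord]:
    """Read a ligand CSV with columns smiles, pchembl, year[, id]."""
    df = pd.read_csv(path)
    missing = {"smiles", "pchembl", "year"} - set(df.columns)
    if missing:
        raise ValueError(f"ligand table {path} missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        mol_id = str(row["id"]) if "id" in df.columns else f"lig_{i}"
        out.append(
            LigandRecord(
                record=canonicalize(str(row["smiles"]), mol_id),
                pchembl=float(row["pchembl"]),
                year=int(row["year"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def murcko_scaffold(record: MoleculeRecord) -> str:
    return MurckoScaffold.MurckoScaffoldSmiles(mol=record.mol)


def scaffold_split(
    ligands: Sequence[LigandRecord], test_fraction: float = 0.20, seed: int = 0
) -> Tuple[List[LigandRecord], List[LigandRecord]]:
    """Murcko-scaffold-disjoint split: whole scaffold groups, largest first
    to train until the train capacity is reached, remainder to test."""
    groups: Dict[str, List[int]] = {}
    for i, lig in enumerate(ligands):
        groups.setdefault(murcko_scaffold(lig.record), []).append(i)
    if len(groups) < 2:
        raise ValueError("scaffold split requires at least 2 distinct Murcko scaffolds")
    rng = np.random.default_rng(seed)
    keys = list(groups)
    order = rng.permutation(len(keys))
    shuffled = [keys[i] for i in order]
    shuffled.sort(key=lambda k: -len(groups[k]))  # stable: seed decides ties
    n = len(ligands)
    capacity = int(round((1.0 - test_fraction) * n))
    train_idx: List[int] = []
    test_idx: List[int] = []
    for key in shuffled:
        if len(train_idx) < capacity:
            train_idx.extend(groups[key])
        else:
            test_idx.extend(groups[key])
    return [ligands[i] for i in sorted(train_idx)], [ligands[i] for i in sorted(test_idx)]


def time_split(
    ligands: Sequence[LigandRecord], cutoff_year: int = DEFAULT_CUTOFF_YEAR
) -> Tuple[List[LigandRecord], List[LigandRecord]]:
    """Temporal split: strictly pre-cutoff to train, cutoff year onward to test."""
    import logging

    missing = [lig.record.id for lig in ligands if lig.year is None]
    if missing:
        raise ValueError(f"ligands missing year: {missing}")
    train = [lig for lig in ligands if lig.year < cutoff_year]
    test = [lig for lig in ligands if lig.year >= cutoff_year]
    if not test:
        logging.getLogger(__name__).warning("time split produced an empty test set")
    return train, test


# ---------------------------------------------------------------------------
# QSAR training
# ---------------------------------------------------------------------------


def default_model_grid() -> Dict[str, Tuple[object, Dict[str, list]]]:
    """Three model families with small grids; extensible by the caller."""
    return {
        "xgboost": (
            XGBClassifier(random_state=0, n_jobs=1, tree_method="hist", eval_metric="logloss"),
            {"n_estimators": [50, 150], "max_depth": [3, 6], "learning_rate": [0.1, 0.3]},
        ),
        "random_forest": (
            RandomForestClassifier(random_state=0, n_jobs=1),
            {"n_estimators": [100, 300], "max_depth": [None, 10]},
        ),
        "knn": (
            KNeighborsClassifier(),
            {"n_neighbors": [1, 3, 5]},
        ),
    }


@dataclass
class QSARModel:
    """The refit activity classifier with its selection report."""

    classifier: object
    family: str
    params: Dict[str, object]
    threshold: float
    report: pd.DataFrame

    def predict_proba_records(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        X = featurize(records)
        return self.classifier.predict_proba(X)[:, 1]


def train_qsar(
    ligands: Sequence[LigandRecord],
    threshold: float = DEFAULT_PCHEMBL_THRESHOLD,
    split_specs: Sequence[str] = ("scaffold", "time"),
    model_grid: Optional[Dict[str, Tuple[object, Dict[str, list]]]] = None,
    seed: int = 0,
    cutoff_year: int = DEFAULT_CUTOFF_YEAR,
) -> QSARModel:
    """Grid-search model families under scaffold and time splits, refit the winner.

    Each family is tuned by 5-fold cross-validated grid search on the train
    side of each split and scored by balanced accuracy on that split's test
    side; the family with the best mean test score across split strategies
    wins and is refit on all data (its best parameters taken from the
    scaffold split, which generalizes structure rather than time).
    """
    model_grid = model_grid or default_model_grid()
    y_all = np.array([int(lig.active(threshold)) for lig in ligands])
    if len(set(y_all)) < 2:
        raise ValueError("both classes must be present under the activity threshold")

    splits: Dict[str, Tuple[List[LigandRecord], List[LigandRecord]]] = {}
    for name in split_specs:
        if name == "scaffold":
            splits[name] = scaffold_split(ligands, seed=seed)
        elif name == "time":
            splits[name] = time_split(ligands, cutoff_year=cutoff_year)
        else:
            raise ValueError(f"unknown split spec: {name}")
    for name, (tr, te) in splits.items():
        y_tr = [int(l.active(threshold)) for l in tr]
        if len(set(y_tr)) < 2 or not te:
            raise ValueError(f"degenerate class balance or empty test in split {name!r}")

    rows = []
    best_params_by_family: Dict[str, Dict[str, Dict[str, object]]] = {}
    for split_name, (train, test) in splits.items():
        X_tr = featurize([l.record for l in train])
        y_tr = np.array([int(l.active(threshold)) for l in train])
        X_te = featurize([l.record for l in test])
        y_te = np.array([int(l.active(threshold)) for l in test])
        for family, (estimator, grid) in model_grid.items():
            cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
            search = GridSearchCV(estimator, grid, scoring="balanced_accuracy", cv=cv, n_jobs=1)
            search.fit(X_tr, y_tr)
            pred = search.best_estimator_.predict(X_te)
            test_score = balanced_accuracy_score(y_te, pred)
            rows.append(
                {
                    "split": split_name,
                    "family": family,
                    "cv_score": float(search.best_score_),
                    "test_score": float(test_score),
                    "best_params": str(search.best_params_),
                }
            )
            best_params_by_family.setdefault(family, {})[split_name] = search.best_params_
    report = pd.DataFrame(rows)
    mean_test = report.groupby("family")["test_score"].mean().sort_values(ascending=False)
    winner = str(mean_test.index[0])

    params_split = "scaffold" if "scaffold" in splits else list(splits)[0]
    best_params = best_params_by_family[winner][params_split]
    estimator, _ = model_grid[winner]
    final = estimator.__class__(**{**estimator.get_params(), **best_params})
    X_all = featurize([l.record for l in ligands])
    final.fit(X_all, y_all)
    return QSARModel(
        classifier=final,
        family=winner,
        params=dict(best_params),
        threshold=threshold,
        report=report,
    )


# ---------------------------------------------------------------------------
# synthetic-complexity heuristic
# ---------------------------------------------------------------------------

#: small drug-like reference corpus used to build the default fragment
#: frequency table (synthetic stand-in assembled for this package; the
#: published frequency table for this score family can be dropped in via
#: ``FragmentFrequencyTable.from_file``)
DEFAULT_CORPUS: Tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",
    "CC(=O)Nc1ccc(O)cc1",
    "CN1CCC[C@H]1c1cccnc1",
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "OC(=O)c1ccccc1O",
    "NCCc1ccc(O)c(O)c1",
    "CCOC(=O)c1ccccc1N",
    "CC(N)Cc1ccccc1",
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
    "Clc1ccccc1-c1ccccc1",
    "Nc1ccc(S(N)(=O)=O)cc1",
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",
    "OCC(O)CO",
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
    "CN(C)CCCN1c2ccccc2CCc2ccccc21",
    "COc1cc2c(cc1OC)CN(C)CC2",
    "O=C(O)Cc1ccccc1",
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",
    "Cc1ccccc1NC(=O)c1ccccc1",
    "O=c1[nH]cnc2[nH]cnc12",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",
    "CC1CCC(C(C)C)C(O)C1",
    "c1ccc2[nH]ccc2c1",
    "OCCN1CCNCC1",
    "CC(O)c1ccccc1",
    "CCCCN",
    "CCOCC",
    "CNC(=O)c1ccccc1",
    "COc1ccccc1OC",
    "CC(C)=CCCC(C)=CCO",
    "Oc1ccc(Cl)cc1",
    "NC(=O)c1ccc[nH]1",
    "CN1CCN(C)CC1",
    "O=S(=O)(c1ccccc1)N1CCCC1",
    "CC(=O)c1ccc(C)cc1",
    "NC(Cc1ccccc1)C(=O)O",
    "OC1CCCCC1O",
    "Cc1ncc(CO)c(C=O)c1O",
    "CCOC(=O)CC(C)=O",
)


class FragmentFrequencyTable:
    """Log-frequency contributions of circular fragments in a reference corpus."""

    def __init__(self, counts: Dict[int, int], radius: int = 2, floor: float = -4.0):
        self.radius = radius
        self.floor = floor
        self.contrib: Dict[int, float] = {}
        if counts:
            max_count = max(counts.values())
            for frag, count in counts.items():
                self.contrib[frag] = math.log10(count / max_count)

    @classmethod
    def from_smiles(cls, smiles: Sequence[str], radius: int = 2) -> "FragmentFrequencyTable":
        counts: Dict[int, int] = {}
        for smi in smiles:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            fp = rdMolDescriptors.GetMorganFingerprint(mol, radius)
            for frag, count in fp.GetNonzeroElements().items():
                counts[frag] = counts.get(frag, 0) + count
        return cls(counts, radius=radius)

    @classmethod
    def from_file(cls, path: str, radius: int = 2) -> "FragmentFrequencyTable":
        """Load a two-column (fragment id, count) CSV frequency table."""
        df = pd.read_csv(path)
        counts = dict(zip(df.iloc[:, 0].astype(int), df.iloc[:, 1].astype(int)))
        return cls(counts, radius=radius)

    def score(self, value: int) -> float:
        return max(self.contrib.get(value, self.floor), self.floor)


_default_table: Optional[FragmentFrequencyTable] = None


def _get_default_table() -> FragmentFrequencyTable:
    global _default_table
    if _default_table is None:
        _default_table = FragmentFrequencyTable.from_smiles(DEFAULT_CORPUS)
    return _default_table


def heuristic_complexity_score(
    mol: MoleculeRecord, table: Optional[FragmentFrequencyTable] = None
) -> float:
    """Synthetic-complexity heuristic on a 1 (easy) to 10 (hard) scale.

    A fragment-familiarity term (mean log-frequency of the molecule's
    circular fragments in the reference corpus) is reduced by topological
    complexity penalties — molecular size, stereocenters, spiro and
    bridgehead atoms, macrocycles — plus a small symmetry bonus for
    repeated fragments, then affinely mapped and clamped to [1, 10].
    Fragment environments ignore chirality, so adding a stereocenter can
    only raise the score (via the stereo penalty), never lower it.
    """
    table = table or _get_default_table()
    m = mol.mol
    fp = rdMolDescriptors.GetMorganFingerprint(m, table.radius)
    elements = fp.GetNonzeroElements()
    total = sum(elements.values())
    if total == 0:
        frag_score = 0.0
    else:
        frag_score = sum(count * table.score(frag) for frag, count in elements.items()) / total

    n_atoms = m.GetNumHeavyAtoms()
    n_stereo = len(Chem.FindMolChiralCenters(m, includeUnassigned=True, useLegacyImplementation=False))
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(m)
    n_bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(m)
    has_macrocycle = any(len(ring) > 8 for ring in m.GetRingInfo().AtomRings())

    size_penalty = n_atoms**1.005 - n_atoms
    stereo_penalty = math.log10(n_stereo + 1)
    spiro_penalty = math.log10(n_spiro + 1)
    bridge_penalty = math.log10(n_bridge + 1)
    macro_penalty = math.log10(2) if has_macrocycle else 0.0
    penalty = size_penalty + stereo_penalty + spiro_penalty + bridge_penalty + macro_penalty

    n_unique = len(elements)
    symmetry_bonus = 0.0
    if n_atoms > n_unique:
        symmetry_bonus = 0.5 * math.log(n_atoms / n_unique)

    raw = frag_score - penalty + symmetry_bonus
    # affine map: familiar/simple (raw ~ 0.5) -> 1, unfamiliar/complex (raw ~ -6) -> 10
    lo, hi = -6.0, 0.5
    score = 11.0 - ((raw - lo) / (hi - lo) * 9.0 + 1.0)
    return float(min(10.0, max(1.0, score)))


# ---------------------------------------------------------------------------
# desirability and Pareto utilities
# ---------------------------------------------------------------------------


@dataclass
class DesirabilityTransform:
    """Smoothed-clipped (logistic) mapping of a raw score onto [0, 1].

    The midpoint maps to 0.5; steepness controls how sharply the transform
    saturates; direction states whether small raw values are desirable
    (e.g. complexity scores) or large ones (e.g. probabilities).
    """

    midpoint: float = 4.5
    steepness: float = 1.0
    direction: str = "lower_is_better"

    def __post_init__(self):
        if self.direction not in ("lower_is_better", "higher_is_better"):
            raise ValueError("direction must be lower_is_better or higher_is_better")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def __call__(self, value: float) -> float:
        return apply_desirability(value, self)


def apply_desirability(value: float, t: DesirabilityTransform) -> float:
    """Logistic desirability 1/(1+exp(±s·(x−m))), monotone and in [0, 1]."""
    sign = 1.0 if t.direction == "lower_is_better" else -1.0
    z = sign * t.steepness * (value - t.midpoint)
    if z >= 0:
        return float(math.exp(-z) / (1.0 + math.exp(-z)))
    return float(1.0 / (1.0 + math.exp(z)))


@dataclass
class ObjectivePoint:
    """A candidate's objective vector, all coordinates to be maximized."""

    candidate_id: str
    values: Tuple[float, ...]

    def __post_init__(self):
        self.values = tuple(float(v) for v in self.values)
        if any(not math.isfinite(v) for v in self.values):
            raise ValueError(f"non-finite objective values for {self.candidate_id}")


def pareto_front(points: Sequence[ObjectivePoint]) -> List[int]:
    """Indices of non-dominated points (maximization in every coordinate).

    A point is dominated iff some other point is >= in all coordinates and
    > in at least one; exact duplicates of a front member are kept.
    """
    if not points:
        return []
    dims = {len(p.values) for p in points}
    if len(dims) != 1:
        raise ValueError("inconsistent objective dimensionality")
    V = np.array([p.values for p in points])
    n = len(points)
    front = []
    for i in range(n):
        geq = (V >= V[i]).all(axis=1)
        gt = (V > V[i]).any(axis=1)
        if not (geq & gt).any():
            front.append(i)
    return front
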