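"""CASP-based synthesizability classifier.

The scorer learns to predict whether retrosynthetic planning with a given
stock would find a route for a molecule, replacing a planner call (seconds
to minutes) with a model call (microseconds).  Labels come from the planner
itself (:func:`label_by_planning`); features are a 2048-bit Morgan
fingerprint (radius 3) concatenated with a 12-descriptor physicochemical
block; the model is a gradient-boosted tree classifier tuned by seeded
random search over a bounded hyperparameter space with stratified 5-fold
cross-validated F1 as the selection criterion.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, f1_score, matthews_corrcoef
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .chem import DESCRIPTOR_NAMES, SCORING_FP_PARAMS, MoleculeRecord, compute_descriptors, morgan_fingerprint
from .planner import SearchConfig, batch_plan
from .reactions import ReactionTemplate, Stock

# ---------------------------------------------------------------------------
# datasets and featurization
# ---------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """Molecules with planner-derived binary labels (1 = route found).

    ``search_config_digest`` ties the labels to the exact planner settings
    and stock that produced them, so a retrained score is traceable to its
    planning conditions.
    """

    records: List[MoleculeRecord]
    labels: np.ndarray
    stock_name: str = ""
    search_config_digest: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.records) != len(self.labels):
            raise ValueError("one label per record required")

    def __len__(self) -> int:
        return len(self.records)

    def digest(self) -> str:
        payload = json.dumps(
            [[r.inchikey for r in self.records], self.labels.tolist(), self.stock_name],
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[i] for i in indices],
            labels=self.labels[list(indices)],
            stock_name=self.stock_name,
            search_config_digest=self.search_config_digest,
        )


def label_by_planning(
    records: Sequence[MoleculeRecord],
    stock: Stock,
    templates: Sequence[ReactionTemplate],
    config: Optional[SearchConfig] = None,
    journal_path: Optional[str] = None,
) -> LabeledDataset:
    """Run batch planning and label each molecule 1 iff a route was found."""
    config = config or SearchConfig()
    if len(records) == 0:
        return LabeledDataset(records=[], labels=np.array([], dtype=int), stock_name=stock.name)
    table = batch_plan(records, stock, templates, config, journal_path=journal_path)
    solved_by_id = dict(zip(table["id"].astype(str), table["solved"].astype(bool)))
    labels = np.array([int(solved_by_id[r.id]) for r in records])
    return LabeledDataset(
        records=list(records),
        labels=labels,
        stock_name=stock.name,
        search_config_digest=config.digest(),
    )


def feature_names(fp_params: Tuple[int, int] = SCORING_FP_PARAMS) -> List[str]:
    radius, nbits = fp_params
    return [f"fp_r{radius}_{i}" for i in range(nbits)] + list(DESCRIPTOR_NAMES)


def featurize(
    records: Sequence[MoleculeRecord], fp_params: Tuple[int, int] = SCORING_FP_PARAMS
) -> np.ndarray:
    """Feature matrix: fingerprint bits then descriptors, fixed column order."""
    radius, nbits = fp_params
    n = len(records)
    X = np.zeros((n, nbits + len(DESCRIPTOR_NAMES)), dtype=np.float32)
    for i, rec in enumerate(records):
        fp = morgan_fingerprint(rec, radius, nbits)
        X[i, list(fp.bits)] = 1.0
        try:
            desc = compute_descriptors(rec)
        except Exception as exc:
            raise ValueError(f"descriptor failure for molecule {rec.id!r}: {exc}") from exc
        X[i, nbits:] = [desc[name] for name in DESCRIPTOR_NAMES]
    return X


def stratified_holdout(
    dataset: LabeledDataset, test_fraction: float = 0.10, seed: int = 0, stratify: bool = True
) -> Tuple[LabeledDataset, LabeledDataset]:
    """Split away a stratified test set (class balance preserved ±1 sample)."""
    n = len(dataset)
    classes = np.unique(dataset.labels)
    if stratify and len(classes) < 2:
        raise ValueError(
            "single-class dataset cannot be stratified; rerun with stratify=False"
        )
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=dataset.labels if stratify else None,
        shuffle=True,
    )
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


# ---------------------------------------------------------------------------
# hyperparameters and tuning
# ---------------------------------------------------------------------------


@dataclass
class HyperparameterSpace:
    """Bounded search ranges for the gradient-boosted tree classifier."""

    learning_rate: Tuple[float, float] = (0.05, 0.4)
    max_tree_depth: Tuple[int, int] = (1, 50)
    min_split_loss: Tuple[float, float] = (0.0, 10.0)
    n_trees: Tuple[int, int] = (5, 250)

    def sample(self, rng: np.random.Generator) -> Dict[str, float]:
        return {
            "learning_rate": float(rng.uniform(*self.learning_rate)),
            "max_depth": int(rng.integers(self.max_tree_depth[0], self.max_tree_depth[1] + 1)),
            "gamma": float(rng.uniform(*self.min_split_loss)),
            "n_estimators": int(rng.integers(self.n_trees[0], self.n_trees[1] + 1)),
        }


DEFAULT_PARAMS: Dict[str, float] = {
    "learning_rate": 0.3,
    "max_depth": 6,
    "gamma": 0.0,
    "n_estimators": 100,
}


def _make_classifier(params: Dict[str, float], seed: int) -> XGBClassifier:
    clf = XGBClassifier(
        learning_rate=params["learning_rate"],
        max_depth=int(params["max_depth"]),
        gamma=params["gamma"],
        n_estimators=int(params["n_estimators"]),
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    # xgboost's save_model/load_model still reads the pre-1.6 scikit-learn
    # `_estimator_type` marker, which newer scikit-learn no longer sets
    if not hasattr(clf, "_estimator_type"):
        clf._estimator_type = "classifier"
    return clf


def tune_hyperparameters(
    train: LabeledDataset,
    space: Optional[HyperparameterSpace] = None,
    n_rounds: int = 25,
    folds: int = 5,
    seed: int = 0,
    X: Optional[np.ndarray] = None,
) -> Tuple[Dict[str, float], pd.DataFrame]:
    """Seeded random search over the space, scored by mean CV F1.

    Returns the argmax setting and the full trial log; ties on the mean F1
    break toward the earliest trial.  A Bayesian-optimization tuner can be
    slotted in by replacing this function — the contract is only
    (train, space, budget, seed) → (params, trial log).
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    space = space or HyperparameterSpace()
    rng = np.random.default_rng(seed)
    if X is None:
        X = featurize(train.records)
    y = train.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    trials = []
    for round_idx in range(n_rounds):
        params = space.sample(rng)
        scores = []
        for fold_train, fold_val in skf.split(X, y):
            clf = _make_classifier(params, seed)
            clf.fit(X[fold_train], y[fold_train])
            pred = clf.predict(X[fold_val])
            scores.append(f1_score(y[fold_val], pred, zero_division=0))
        trials.append({**params, "trial": round_idx, "cv_f1_mean": float(np.mean(scores))})
    log = pd.DataFrame(trials)
    best_idx = int(log["cv_f1_mean"].idxmax())  # idxmax returns the earliest max
    best = {
        k: log.loc[best_idx, k] for k in ("learning_rate", "max_depth", "gamma", "n_estimators")
    }
    best["max_depth"] = int(best["max_depth"])
    best["n_estimators"] = int(best["n_estimators"])
    return best, log


# ---------------------------------------------------------------------------
# final model
# ---------------------------------------------------------------------------


@dataclass
class ScoreModel:
    """A trained synthesizability classifier with its feature schema."""

    classifier: XGBClassifier
    fp_params: Tuple[int, int] = SCORING_FP_PARAMS
    params: Dict[str, float] = field(default_factory=dict)
    metadata: Dict[str, str] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.fp_params[1] + len(DESCRIPTOR_NAMES)

    def _check_schema(self, X: np.ndarray) -> None:
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature schema mismatch: expected {self.n_features} columns, got {X.shape}"
            )

    def predict_proba_records(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        X = featurize(records, self.fp_params)
        return self.predict_proba(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check_schema(X)
        return self.classifier.predict_proba(X)[:, 1]

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        self.classifier.save_model(os.path.join(directory, "model.json"))
        with open(os.path.join(directory, "schema.json"), "w") as fh:
            json.dump(
                {
                    "fp_radius": self.fp_params[0],
                    "fp_nbits": self.fp_params[1],
                    "descriptors": list(DESCRIPTOR_NAMES),
                },
                fh,
                indent=2,
            )
        with open(os.path.join(directory, "metadata.json"), "w") as fh:
            json.dump({"params": self.params, **self.metadata}, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory: str) -> "ScoreModel":
        clf = XGBClassifier()
        if not hasattr(clf, "_estimator_type"):
            clf._estimator_type = "classifier"
        clf.load_model(os.path.join(directory, "model.json"))
        with open(os.path.join(directory, "schema.json")) as fh:
            schema = json.load(fh)
        with open(os.path.join(directory, "metadata.json")) as fh:
            meta = json.load(fh)
        params = meta.pop("params", {})
        return cls(
            classifier=clf,
            fp_params=(schema["fp_radius"], schema["fp_nbits"]),
            params=params,
            metadata=meta,
        )


def train_final(
    train: LabeledDataset,
    params: Optional[Dict[str, float]] = None,
    seed: int = 0,
    X: Optional[np.ndarray] = None,
) -> ScoreModel:
    """Fit the final classifier on the full training split."""
    params = dict(params or DEFAULT_PARAMS)
    if X is None:
        X = featurize(train.records)
    clf = _make_classifier(params, seed)
    clf.fit(X, train.labels)
    return ScoreModel(
        classifier=clf,
        params=params,
        metadata={
            "seed": str(seed),
            "dataset_digest": train.digest(),
            "stock_name": train.stock_name,
            "search_config_digest": train.search_config_digest,
        },
    )


def evaluate(
    model: ScoreModel, test: LabeledDataset, threshold: float = 0.5
) -> Dict[str, object]:
    """F1, MCC and the confusion matrix at the given probability threshold.

    MCC is defined as 0 when any confusion-matrix marginal is zero (the
    standard degenerate-case convention, keeping folds comparable).
    """
    proba = model.predict_proba_records(test.records)
    pred = (proba > threshold).astype(int)
    y = test.labels
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=[0, 1]).ravel()
    denom_terms = [(tp + fp), (tp + fn), (tn + fp), (tn + fn)]
    if any(t == 0 for t in denom_terms):
        mcc = 0.0
    else:
        mcc = float(matthews_corrcoef(y, pred))
    return {
        "f1": float(f1_score(y, pred, zero_division=0)),
        "mcc": mcc,
        "accuracy": float((pred == y).mean()) if len(y) else 0.0,
        "confusion": {"tp": int(tp), "tn": int(tn), "fp": int(fp), "fn": int(fn)},
        "n": int(len(y)),
    }


def predict_synthesizability(
    model: ScoreModel, records: Sequence[MoleculeRecord]
) -> np.ndarray:
    """Probabilities that planning would find a route; order-preserving."""
    if len(records) == 0:
        return np.array([])
    return model.predict_proba_records(records)
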