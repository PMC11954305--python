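"""Five-stage virtual-screening cascade for generated candidates.

Stage order is fixed: (1) predicted-activity AND predicted-synthesizability
probabilities above threshold, (2) a synthesis route exists with the given
stock, (3) the shortest route is within the step budget, (4) rule-of-five
drug-likeness, (5) structural novelty against known ligands.  The planner
is invoked only for stage-1 survivors — the screening-before-planning
economy that makes the cascade affordable — and the report records every
candidate's first failing stage alongside per-stage survivor counts.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import MoleculeRecord, compute_descriptors, morgan_fingerprint, tanimoto
from .planner import RouteTree, SearchConfig, mcts_search
from .reactions import ReactionTemplate, Stock

STAGE_NAMES = (
    "probability_filter",
    "route_found",
    "route_length",
    "rule_of_five",
    "novelty",
)


@dataclass
class TriageConfig:
    """Thresholds of the cascade.

    Probability thresholds are strict (p must exceed 0.8); novelty requires
    the maximum Tanimoto similarity to known ligands to be strictly below
    0.7.  ``ro5_mode`` "classic" tolerates one rule-of-five violation (the
    rule's original formulation); "strict" tolerates none.
    """

    p_active_min: float = 0.8
    p_synth_min: float = 0.8
    max_route_steps: int = 5
    ro5_mode: str = "classic"
    novelty_max_tanimoto: float = 0.7
    fp_radius: int = 3
    fp_nbits: int = 2048

    def __post_init__(self):
        if self.ro5_mode not in ("classic", "strict"):
            raise ValueError("ro5_mode must be classic or strict")
        for name in ("p_active_min", "p_synth_min", "novelty_max_tanimoto"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.max_route_steps < 0:
            raise ValueError("max_route_steps must be >= 0")


def novelty_score(
    mol: MoleculeRecord,
    known_ligands: Sequence[MoleculeRecord],
    fp_radius: int = 3,
    fp_nbits: int = 2048,
) -> Tuple[float, str]:
    """Maximum Tanimoto similarity to any known ligand, plus the argmax id."""
    if not known_ligands:
        raise ValueError("known ligand set must be non-empty")
    fp = morgan_fingerprint(mol, fp_radius, fp_nbits)
    best_sim, best_id = -1.0, ""
    for lig in known_ligands:
        sim = tanimoto(fp, morgan_fingerprint(lig, fp_radius, fp_nbits))
        if sim > best_sim:
            best_sim, best_id = sim, lig.id
    return best_sim, best_id


def lipinski_pass(mol: MoleculeRecord, mode: str = "classic") -> Tuple[bool, List[str]]:
    """Rule-of-five check: MW <= 500, cLogP <= 5, HBD <= 5, HBA <= 10.

    "classic" passes with at most one violation; "strict" requires none.
    """
    d = compute_descriptors(mol)
    violations = []
    if d["mw"] > 500:
        violations.append("mw")
    if d["clogp"] > 5:
        violations.append("clogp")
    if d["hbd"] > 5:
        violations.append("hbd")
    if d["hba"] > 10:
        violations.append("hba")
    allowed = 1 if mode == "classic" else 0
    return len(violations) <= allowed, violations


@dataclass
class TriageReport:
    """Per-stage accounting and the final ranked shortlist."""

    stage_names: Tuple[str, ...]
    survivors: List[int]
    trace: Dict[str, str]  # candidate id -> "PASS" or first failing stage
    shortlist: pd.DataFrame
    routes: Dict[str, RouteTree] = field(default_factory=dict)
    planner_calls: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": list(self.stage_names),
                "survivors": self.survivors,
                "trace": self.trace,
                "planner_calls": self.planner_calls,
                "shortlist_ids": list(self.shortlist["id"]) if len(self.shortlist) else [],
            },
            indent=2,
            sort_keys=True,
        )


def run_cascade(
    candidates: Sequence[MoleculeRecord],
    qsar_model,
    score_model,
    stock: Stock,
    templates: Sequence[ReactionTemplate],
    search_config: Optional[SearchConfig] = None,
    known_ligands: Sequence[MoleculeRecord] = (),
    config: Optional[TriageConfig] = None,
) -> TriageReport:
    """Run the five-stage cascade; see the module docstring for semantics.

    Both models must expose ``predict_proba_records(records) -> array`` on
    the candidates; schema failures abort with stage context.  The final
    shortlist is ranked by descending (p_active + p_synth), shorter routes
    first — a pragmatic ordering heuristic, not a statement about potency.
    """
    config = config or TriageConfig()
    search_config = search_config or SearchConfig()
    candidates = list(candidates)
    trace: Dict[str, str] = {}
    survivors: List[int] = []
    if not candidates:
        return TriageReport(STAGE_NAMES, [0] * len(STAGE_NAMES), {}, pd.DataFrame(columns=["id"]))

    try:
        p_active = np.asarray(qsar_model.predict_proba_records(candidates), dtype=float)
        p_synth = np.asarray(score_model.predict_proba_records(candidates), dtype=float)
    except Exception as exc:
        raise RuntimeError(f"stage probability_filter: model failure: {exc}") from exc

    # stage 1: probability filter (strict >)
    alive = []
    for i, cand in enumerate(candidates):
        if p_active[i] > config.p_active_min and p_synth[i] > config.p_synth_min:
            alive.append(i)
        else:
            trace[cand.id] = "probability_filter"
    survivors.append(len(alive))

    # stage 2: a synthesis route exists (planner invoked only here)
    planner_calls = 0
    routes: Dict[str, RouteTree] = {}
    route_steps: Dict[str, int] = {}
    next_alive = []
    for i in alive:
        cand = candidates[i]
        result = mcts_search(cand, stock, templates, search_config)
        planner_calls += 1
        if result.solved:
            routes[cand.id] = result.routes[0]
            route_steps[cand.id] = result.shortest_route_length
            next_alive.append(i)
        else:
            trace[cand.id] = "route_found"
    alive = next_alive
    survivors.append(len(alive))

    # stage 3: shortest route within the step budget
    next_alive = []
    for i in alive:
        cand = candidates[i]
        if route_steps[cand.id] <= config.max_route_steps:
            next_alive.append(i)
        else:
            trace[cand.id] = "route_length"
    alive = next_alive
    survivors.append(len(alive))

    # stage 4: rule of five
    next_alive = []
    for i in alive:
        cand = candidates[i]
        ok, _ = lipinski_pass(cand, config.ro5_mode)
        if ok:
            next_alive.append(i)
        else:
            trace[cand.id] = "rule_of_five"
    alive = next_alive
    survivors.append(len(alive))

    # stage 5: novelty (strict <)
    next_alive = []
    for i in alive:
        cand = candidates[i]
        if known_ligands:
            sim, _ = novelty_score(cand, known_ligands, config.fp_radius, config.fp_nbits)
        else:
            sim = 0.0
        if sim < config.novelty_max_tanimoto:
            next_alive.append(i)
            trace[cand.id] = "PASS"
        else:
            trace[cand.id] = "novelty"
    alive = next_alive
    survivors.append(len(alive))

    rows = []
    for i in alive:
        cand = candidates[i]
        rows.append(
            {
                "id": cand.id,
                "smiles": cand.smiles_canonical,
                "p_active": float(p_active[i]),
                "p_synth": float(p_synth[i]),
                "route_steps": route_steps[cand.id],
            }
        )
    shortlist = pd.DataFrame(rows, columns=["id", "smiles", "p_active", "p_synth", "route_steps"])
    if len(shortlist):
        shortlist["rank_score"] = shortlist["p_active"] + shortlist["p_synth"]
        shortlist = shortlist.sort_values(
            by=["rank_score", "route_steps", "id"], ascending=[False, True, True]
        ).reset_index(drop=True)

    return TriageReport(
        stage_names=STAGE_NAMES,
        survivors=survivors,
        trace=trace,
        shortlist=shortlist,
        routes={cid: routes[cid] for cid in shortlist["id"]} if len(shortlist) else {},
        planner_calls=planner_calls,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline orchestration
# ---------------------------------------------------------------------------


def _sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config_file: str, out_dir: Optional[str] = None) -> str:
    """Fixture-driven end-to-end run: generate → label → train → triage.

    The YAML config names a fixture seed and the stage settings; the output
    directory receives the fixture files, the labeled planning table, the
    trained score model, the triage report and a manifest of content
    digests.  Reruns with the same config reproduce the manifest exactly.
    """
    import yaml

    from .fixtures import (
        FixtureSpec,
        SubstructureProbabilityModel,
        gen_reaction_universe,
        gen_solvable,
        gen_unsolvable,
        write_fixture_set,
    )
    from .scorer import label_by_planning, stratified_holdout, train_final

    with open(config_file) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("seed", "out_dir"):
        if out_dir is not None and key == "out_dir":
            continue
        if key not in cfg:
            raise KeyError(f"pipeline config missing required key: {key}")
    seed = int(cfg["seed"])
    out_dir = out_dir or cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)

    spec = FixtureSpec(
        seed=seed,
        n_solvable=int(cfg.get("n_solvable", 40)),
        n_unsolvable=int(cfg.get("n_unsolvable", 20)),
        label_noise=float(cfg.get("label_noise", 0.0)),
    )
    fixture_dir = os.path.join(out_dir, "fixtures")
    paths = write_fixture_set(spec, fixture_dir)

    templates, stock, stock_records = gen_reaction_universe(spec)
    solvable = gen_solvable(spec, templates, stock, stock_records)
    unsolvable = gen_unsolvable(spec, solvable, templates, stock)
    molecules = [s.record for s in solvable] + [u.record for u in unsolvable]

    search_config = SearchConfig(
        iteration_limit=int(cfg.get("iteration_limit", 500)),
        max_depth=int(cfg.get("max_depth", 4)),
        seed=seed,
    )
    dataset = label_by_planning(molecules, stock, templates, search_config)
    plan_table = pd.DataFrame(
        {"id": [r.id for r in dataset.records], "label": dataset.labels}
    )
    plan_path = os.path.join(out_dir, "planning_labels.csv")
    plan_table.to_csv(plan_path, index=False)

    train, test = stratified_holdout(dataset, test_fraction=0.2, seed=seed)
    model = train_final(train, seed=seed)
    model_dir = os.path.join(out_dir, "score_model")
    model.save(model_dir)

    qsar = SubstructureProbabilityModel(cfg.get("activity_smarts", spec.activity_smarts))
    report = run_cascade(
        molecules,
        qsar_model=qsar,
        score_model=model,
        stock=stock,
        templates=templates,
        search_config=search_config,
        known_ligands=[s.record for s in solvable[:3]],
        config=TriageConfig(),
    )
    report_path = os.path.join(out_dir, "triage_report.json")
    with open(report_path, "w") as fh:
        fh.write(report.to_json())
    routes_dir = os.path.join(out_dir, "routes")
    os.makedirs(routes_dir, exist_ok=True)
    for cid, route in report.routes.items():
        with open(os.path.join(routes_dir, f"{cid}.json"), "w") as fh:
            fh.write(route.to_json())

    manifest = {}
    for base, _, files in os.walk(out_dir):
        for name in sorted(files):
            path = os.path.join(base, name)
            if name == "manifest.json":
                continue
            rel = os.path.relpath(path, out_dir)
            manifest[rel] = _sha256_file(path)
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir
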