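"""Deterministic synthetic-fixture generators with certified ground truth.

The fixture universe is a hand-curated family of eight common coupling
templates (amide, ester, two ether variants, reductive amination, aryl-aryl
coupling, sulfonamide, N-alkylation) over a stock of small organic
fragments.  Solvable molecules are built by forward template application
from stock — so their solvability and a step-count upper bound are known by
construction — and certified with the exhaustive planner oracle.
Unsolvable molecules carry a trifluoromethyl tag that no template can
detach and no stock member contains, which confines it to an out-of-stock
leaf in every conceivable route; unsolvability is still certified by the
oracle rather than assumed.

Activity tables plant a substructure rule (pyridine by default): matching
molecules draw their pChEMBL value from N(7.5, 0.5), the rest from
N(5.0, 0.5), so the threshold-6.5 labels recover the planted rule up to
Gaussian tail crossings; label noise re-draws from the opposite
distribution with probability epsilon.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .chem import MoleculeRecord, canonicalize, from_mol, write_molecules
from .planner import OracleResult, RouteTree, bfs_oracle
from .reactions import (
    ReactionTemplate,
    Stock,
    apply_forward,
    roundtrip_probe,
    stock_from_records,
    write_templates,
)

# ---------------------------------------------------------------------------
# the curated template family
# ---------------------------------------------------------------------------

#: (id, retro_smarts, name) — every disconnection is an acyclic bond, so
#: retro application always fragments and search spaces stay finite.
TEMPLATE_FAMILY: Tuple[Tuple[str, str, str], ...] = (
    (
        "amide_coupling",
        "[C:1](=[O:2])-!@[NX3;!$([N]-[O]):3]>>[C:1](=[O:2])[OX2H1].[NX3:3]",
        "amide from carboxylic acid and amine",
    ),
    (
        "esterification",
        "[C:1](=[O:2])-!@[OX2:3][C;!$(C=O):4]>>[C:1](=[O:2])[OX2H1].[OX2H1:3][C:4]",
        "ester from carboxylic acid and alcohol",
    ),
    (
        "williamson_ether",
        "[CX4;!$(C=O):1][OX2:2]-!@[CX4;!$(C=O):3]>>[CX4:1][OX2H1:2].[CX4:3]Br",
        "dialkyl ether from alcohol and alkyl bromide",
    ),
    (
        "reductive_amination",
        "[CX4;H2:1]-!@[NX3;!$(N-C=O);!$(N-S):2]>>[CX3;H1:1]=O.[NX3:2]",
        "amine from aldehyde and amine",
    ),
    (
        "ullmann_biaryl",
        "[c:1]-!@[c:2]>>[c:1]Br.[c:2]Br",
        "biaryl from two aryl bromides",
    ),
    (
        "sulfonamide_coupling",
        "[S:1](=[O:2])(=[O:3])-!@[NX3:4]>>[S:1](=[O:2])(=[O:3])Cl.[NX3:4]",
        "sulfonamide from sulfonyl chloride and amine",
    ),
    (
        "n_alkylation",
        "[CX4;!$(C=O):1]-!@[NX3;!$(N-C=O);!$(N-S):2]>>[CX4:1]Br.[NX3:2]",
        "amine from alkyl bromide and amine",
    ),
    (
        "snar_ether",
        "[c:1]-!@[OX2:2][CX4;!$(C=O):3]>>[c:1]Br.[OX2H1:2][CX4:3]",
        "aryl alkyl ether from aryl bromide and alcohol",
    ),
)

#: candidate building blocks; the generator keeps only those compatible
#: with at least two templates of the family
STOCK_POOL: Tuple[str, ...] = (
    # carboxylic acids
    "CC(=O)O",
    "CCC(=O)O",
    "CC(C)C(=O)O",
    "OC(=O)C1CC1",
    "OC(=O)c1ccccc1",
    "OC(=O)c1ccncc1",
    "Cc1ccc(C(=O)O)cc1",
    "OC(=O)CC1CC1",
    # amines
    "CN",
    "CCN",
    "CC(C)N",
    "CNC",
    "NC1CCCCC1",
    "Nc1ccccc1",
    "NCc1ccccc1",
    "NCCO",
    "C1COCCN1",
    "NCCC1CC1",
    # alcohols
    "CO",
    "CCO",
    "CC(C)O",
    "OCC1CC1",
    "OCc1ccccc1",
    "OCCC1CC1",
    # alkyl bromides
    "CBr",
    "CCBr",
    "CC(C)Br",
    "BrCc1ccccc1",
    "BrCC1CC1",
    # aryl bromides
    "Brc1ccccc1",
    "Brc1ccncc1",
    "Cc1ccc(Br)cc1",
    "Brc1ccc(F)cc1",
)

#: probe molecules exercising every template for round-trip validation
ROUNDTRIP_PROBES: Tuple[str, ...] = (
    "CC(=O)NC",
    "CC(=O)OCC",
    "CCOC",
    "CCNC",
    "c1ccc(-c2ccncc2)cc1",
    "CS(=O)(=O)NC",
    "CCNCC",
    "COc1ccccc1",
)


@dataclass
class FixtureSpec:
    """Study conditions for fixture generation; one seed fixes everything."""

    seed: int = 0
    stock_size: int = 30
    n_solvable: int = 50
    steps_range: Tuple[int, int] = (1, 3)
    n_unsolvable: int = 20
    activity_smarts: str = "c1ccncc1"
    label_noise: float = 0.1
    year_range: Tuple[int, int] = (2010, 2022)
    pchembl_threshold: float = 6.5
    oracle_depth: int = 4
    max_build_retries: int = 200


def make_templates(seed: int = 0) -> List[ReactionTemplate]:
    """The eight-template fixture family with seed-varied priors in [0.5, 1.5]."""
    rng = np.random.default_rng(seed)
    priors = rng.uniform(0.5, 1.5, size=len(TEMPLATE_FAMILY))
    templates = []
    for (tid, smarts, name), prior in zip(TEMPLATE_FAMILY, priors):
        templates.append(
            ReactionTemplate(id=tid, retro_smarts=smarts, name=name, prior=round(float(prior), 4))
        )
    probes = [canonicalize(s) for s in ROUNDTRIP_PROBES]
    for t in templates:
        for probe in probes:
            if not roundtrip_probe(t, probe):  # pragma: no cover - template defect guard
                raise RuntimeError(f"template {t.id} fails round-trip probe on {probe.smiles_canonical}")
    return templates


def _forward_reactant_slots(template: ReactionTemplate) -> List[Chem.Mol]:
    rxn = template.forward_rxn
    return [rxn.GetReactantTemplate(i) for i in range(rxn.GetNumReactantTemplates())]


def template_compatibility(mol: MoleculeRecord, templates: Sequence[ReactionTemplate]) -> int:
    """Number of templates in which ``mol`` matches a forward reactant slot."""
    count = 0
    for t in templates:
        if any(mol.mol.HasSubstructMatch(patt) for patt in _forward_reactant_slots(t)):
            count += 1
    return count


def make_stock(
    seed: int = 0, size: int = 30, templates: Optional[Sequence[ReactionTemplate]] = None
) -> Tuple[Stock, List[MoleculeRecord]]:
    """A seed-subsampled stock; every member is compatible with >= 2 templates."""
    templates = templates if templates is not None else make_templates(seed)
    records = [canonicalize(s, f"bb_{i}") for i, s in enumerate(STOCK_POOL)]
    eligible = [r for r in records if template_compatibility(r, templates) >= 2]
    rng = np.random.default_rng(seed + 1)
    if size < len(eligible):
        idx = sorted(rng.choice(len(eligible), size=size, replace=False))
        eligible = [eligible[i] for i in idx]
    stock = stock_from_records(eligible, name=f"fixture_stock_s{seed}")
    return stock, eligible


def gen_reaction_universe(spec: FixtureSpec) -> Tuple[List[ReactionTemplate], Stock, List[MoleculeRecord]]:
    """Templates plus stock for a spec: the substrate every other generator uses."""
    templates = make_templates(spec.seed)
    stock, members = make_stock(spec.seed, spec.stock_size, templates)
    return templates, stock, members


# ---------------------------------------------------------------------------
# solvable / unsolvable molecule construction
# ---------------------------------------------------------------------------


@dataclass
class SolvableMolecule:
    record: MoleculeRecord
    built_steps: int
    witness_route: RouteTree
    oracle: OracleResult


@dataclass
class UnsolvableMolecule:
    record: MoleculeRecord
    oracle: OracleResult


def _match_slot(patt: Chem.Mol, candidates: Sequence[MoleculeRecord]) -> List[MoleculeRecord]:
    return [c for c in candidates if c.mol.HasSubstructMatch(patt)]


def _witness_tree(
    target: MoleculeRecord,
    steps: List[Tuple[str, MoleculeRecord, List[MoleculeRecord]]],
    stock: Stock,
) -> RouteTree:
    """Build the route JSON for a linear forward construction.

    ``steps`` is ordered outermost-first: each entry is (template id,
    product, reactants), the first product being the target.
    """

    def mol_node(rec: MoleculeRecord) -> dict:
        return {
            "type": "mol",
            "smiles": rec.smiles_canonical,
            "inchikey": rec.inchikey,
            "in_stock": rec in stock,
            "children": [],
        }

    root = mol_node(target)
    nodes_by_key = {target.inchikey: root}
    for template_id, product, reactants in steps:
        prod_node = nodes_by_key[product.inchikey]
        rxn = {"type": "reaction", "template_id": template_id, "children": []}
        prod_node["children"] = [rxn]
        for r in reactants:
            child = mol_node(r)
            rxn["children"].append(child)
            nodes_by_key[r.inchikey] = child
    return RouteTree(root, target)


def gen_solvable(
    spec: FixtureSpec,
    templates: Optional[Sequence[ReactionTemplate]] = None,
    stock: Optional[Stock] = None,
    stock_records: Optional[Sequence[MoleculeRecord]] = None,
) -> List[SolvableMolecule]:
    """Molecules built by k forward steps from stock, oracle-certified solvable.

    Each molecule records its construction step count k (an upper bound on
    the true minimum) and a witness route that forward-replays to the
    target; the exhaustive oracle confirms ``min_steps <= k``.
    """
    if templates is None or stock is None or stock_records is None:
        templates, stock, stock_records = gen_reaction_universe(spec)
    rng = np.random.default_rng(spec.seed + 2)
    productive = [
        t
        for t in templates
        if all(_match_slot(p, stock_records) for p in _forward_reactant_slots(t))
    ]
    out: List[SolvableMolecule] = []
    seen = {r.inchikey for r in stock_records}
    attempts = 0
    lo, hi = spec.steps_range
    while len(out) < spec.n_solvable and attempts < spec.max_build_retries * spec.n_solvable:
        attempts += 1
        k = int(rng.integers(lo, hi + 1))
        current: Optional[MoleculeRecord] = None
        trail: List[Tuple[str, MoleculeRecord, List[MoleculeRecord]]] = []
        ok = True
        for step in range(k):
            template = productive[int(rng.integers(len(productive)))]
            slots = _forward_reactant_slots(template)
            reactants: List[MoleculeRecord] = []
            if current is not None:
                slot_idx = [i for i, p in enumerate(slots) if current.mol.HasSubstructMatch(p)]
                if not slot_idx:
                    ok = False
                    break
                use = slot_idx[int(rng.integers(len(slot_idx)))]
            else:
                use = int(rng.integers(len(slots)))
            for i, patt in enumerate(slots):
                if current is not None and i == use:
                    reactants.append(current)
                    continue
                options = _match_slot(patt, stock_records)
                if not options:
                    ok = False
                    break
                reactants.append(options[int(rng.integers(len(options)))])
            if not ok:
                break
            products = apply_forward(template, reactants)
            products = [p for p in products if p.mol.GetNumHeavyAtoms() <= 60]
            if not products:
                ok = False
                break
            current = products[int(rng.integers(len(products)))]
            trail.append((template.id, current, list(reactants)))
        if not ok or current is None or current.inchikey in seen:
            continue
        depth = max(spec.oracle_depth, k)
        oracle = bfs_oracle(current, stock, templates, max_depth=depth)
        if not oracle.feasible or not oracle.solved or oracle.min_steps > k:
            continue
        # rewrite the trail outermost-first for the witness tree
        trail_out = list(reversed(trail))
        witness = _witness_tree(current, trail_out, stock)
        record = MoleculeRecord(
            id=f"solv_{len(out)}",
            smiles_input=current.smiles_canonical,
            smiles_canonical=current.smiles_canonical,
            inchikey=current.inchikey,
        )
        seen.add(current.inchikey)
        out.append(SolvableMolecule(record, built_steps=k, witness_route=witness, oracle=oracle))
    if len(out) < spec.n_solvable:  # pragma: no cover - generator exhaustion guard
        raise RuntimeError(f"could only build {len(out)}/{spec.n_solvable} solvable molecules")
    return out


_TAG_SMARTS = Chem.MolFromSmarts("C(F)(F)F")


def perturb_with_blocker(record: MoleculeRecord, rng: np.random.Generator) -> Optional[MoleculeRecord]:
    """Attach a CF3 tag to a random carbon bearing a hydrogen."""
    mol = Chem.RWMol(record.mol)
    carbons = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]
    if not carbons:
        return None
    target_idx = int(carbons[int(rng.integers(len(carbons)))])
    c_new = mol.AddAtom(Chem.Atom(6))
    for _ in range(3):
        f = mol.AddAtom(Chem.Atom(9))
        mol.AddBond(c_new, f, Chem.BondType.SINGLE)
    mol.AddBond(target_idx, c_new, Chem.BondType.SINGLE)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return from_mol(mol.GetMol())


def gen_unsolvable(
    spec: FixtureSpec,
    solvable: Optional[Sequence[SolvableMolecule]] = None,
    templates: Optional[Sequence[ReactionTemplate]] = None,
    stock: Optional[Stock] = None,
) -> List[UnsolvableMolecule]:
    """CF3-perturbed molecules, oracle-certified unsolvable at ``FixtureSpec.oracle_depth``."""
    if templates is None or stock is None:
        templates, stock, stock_records = gen_reaction_universe(spec)
    else:
        stock_records = None
    if solvable is None:
        solvable = gen_solvable(spec, templates, stock, stock_records)
    rng = np.random.default_rng(spec.seed + 3)
    out: List[UnsolvableMolecule] = []
    seen = set()
    attempts = 0
    while len(out) < spec.n_unsolvable and attempts < spec.max_build_retries * spec.n_unsolvable:
        attempts += 1
        base = solvable[int(rng.integers(len(solvable)))].record
        perturbed = perturb_with_blocker(base, rng)
        if perturbed is None or perturbed.inchikey in seen or perturbed in stock:
            continue
        oracle = bfs_oracle(perturbed, stock, templates, max_depth=spec.oracle_depth)
        if not oracle.feasible or oracle.solved:
            continue
        record = MoleculeRecord(
            id=f"unsolv_{len(out)}",
            smiles_input=perturbed.smiles_canonical,
            smiles_canonical=perturbed.smiles_canonical,
            inchikey=perturbed.inchikey,
        )
        seen.add(perturbed.inchikey)
        out.append(UnsolvableMolecule(record, oracle=oracle))
    if len(out) < spec.n_unsolvable:  # pragma: no cover - generator exhaustion guard
        raise RuntimeError(f"could only build {len(out)}/{spec.n_unsolvable} unsolvable molecules")
    return out


def gen_planted_dataset(
    seed: int,
    n: int,
    noise: float = 0.0,
    activity_smarts: str = "c1ccncc1",
    steps_range: Tuple[int, int] = (1, 3),
) -> Tuple[List[MoleculeRecord], np.ndarray, np.ndarray]:
    """Class-balanced molecules with planted-substructure labels.

    Molecules are assembled by forward template application from the
    fixture stock (no solvability certification — the label here is the
    substructure rule, not plannability) and collected until both classes
    hold n/2 distinct members.  Returns (records, noisy_labels,
    true_labels) where noisy labels flip with probability ``noise``.

    The flip mask is drawn from the same uniform stream for every
    ``noise`` value, so corruptions are nested: every label flipped at
    ε=0.1 is also flipped at ε=0.2 for the same seed.
    """
    records, true, flip_uniform = _planted_pool(seed, n, activity_smarts, steps_range)
    noisy = np.where(flip_uniform < noise, 1 - true, true)
    return list(records), noisy.copy(), true.copy()


@lru_cache(maxsize=8)
def _planted_pool(
    seed: int,
    n: int,
    activity_smarts: str,
    steps_range: Tuple[int, int],
) -> Tuple[Tuple[MoleculeRecord, ...], np.ndarray, np.ndarray]:
    """Expensive noise-independent part of :func:`gen_planted_dataset`."""
    # full eligible stock pool (no subsampling): the planted motif must be
    # constructible regardless of which subset a seed would draw
    spec = FixtureSpec(seed=seed, stock_size=len(STOCK_POOL))
    templates, stock, stock_records = gen_reaction_universe(spec)
    patt = Chem.MolFromSmarts(activity_smarts)
    rng = np.random.default_rng(seed + 6)
    productive = [
        t
        for t in templates
        if all(_match_slot(p, stock_records) for p in _forward_reactant_slots(t))
    ]
    per_class = n // 2
    want = {0: per_class, 1: n - per_class}
    buckets: Dict[int, List[MoleculeRecord]] = {0: [], 1: []}
    seen = set()
    lo, hi = steps_range
    attempts = 0
    max_attempts = 200 * n
    pos_members = [r for r in stock_records if r.mol.HasSubstructMatch(patt)]
    neg_members = [r for r in stock_records if not r.mol.HasSubstructMatch(patt)]
    while (len(buckets[0]) < want[0] or len(buckets[1]) < want[1]) and attempts < max_attempts:
        attempts += 1
        # bias construction toward the class still needing members: the
        # templates never break rings, so seeding (or excluding) a
        # motif-bearing building block decides the label by construction
        target_label = 0 if len(buckets[0]) < want[0] else 1
        if len(buckets[1]) < want[1] and len(buckets[0]) >= want[0]:
            target_label = 1
        elif len(buckets[1]) < want[1] and rng.random() < 0.5:
            target_label = 1
        pool = neg_members if target_label == 0 else stock_records
        k = int(rng.integers(lo, hi + 1))
        current: Optional[MoleculeRecord] = None
        ok = True
        force_pos = target_label == 1 and bool(pos_members)
        for step in range(k):
            template = productive[int(rng.integers(len(productive)))]
            slots = _forward_reactant_slots(template)
            reactants: List[MoleculeRecord] = []
            use = -1
            if current is not None:
                slot_idx = [i for i, p in enumerate(slots) if current.mol.HasSubstructMatch(p)]
                if not slot_idx:
                    ok = False
                    break
                use = slot_idx[int(rng.integers(len(slot_idx)))]
            forced_done = not force_pos or (
                current is not None and current.mol.HasSubstructMatch(patt)
            )
            for i, p in enumerate(slots):
                if i == use:
                    reactants.append(current)
                    continue
                options = _match_slot(p, pool)
                if not forced_done:
                    seeded = [o for o in options if o.mol.HasSubstructMatch(patt)]
                    if seeded:
                        options = seeded
                        forced_done = True
                if not options:
                    ok = False
                    break
                reactants.append(options[int(rng.integers(len(options)))])
            if not ok:
                break
            products = [
                pr for pr in apply_forward(template, reactants) if pr.mol.GetNumHeavyAtoms() <= 60
            ]
            if not products:
                ok = False
                break
            current = products[int(rng.integers(len(products)))]
        if not ok or current is None or current.inchikey in seen:
            continue
        label = int(current.mol.HasSubstructMatch(patt))
        if len(buckets[label]) >= want[label]:
            continue
        seen.add(current.inchikey)
        buckets[label].append(current)
    if len(buckets[0]) + len(buckets[1]) < n:  # pragma: no cover - generator exhaustion guard
        raise RuntimeError("could not assemble a balanced planted dataset")

    records: List[MoleculeRecord] = []
    true_labels: List[int] = []
    for label in (0, 1):
        for mol in buckets[label]:
            records.append(
                MoleculeRecord(
                    id=f"pl_{len(records)}",
                    smiles_input=mol.smiles_canonical,
                    smiles_canonical=mol.smiles_canonical,
                    inchikey=mol.inchikey,
                )
            )
            true_labels.append(label)
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    true = np.array([true_labels[i] for i in order])
    flip_uniform = rng.random(len(records))
    return tuple(records), true, flip_uniform


# ---------------------------------------------------------------------------
# activity tables
# ---------------------------------------------------------------------------


def gen_activity_table(
    spec: FixtureSpec, molecules: Sequence[MoleculeRecord]
):
    """Ligand table (smiles, pchembl, year, id, planted) with a planted rule.

    ``planted`` is the noise-free ground-truth label (substructure match);
    the observed pChEMBL draws from the matching or, with probability
    ``label_noise``, the opposing distribution.
    """
    import pandas as pd

    patt = Chem.MolFromSmarts(spec.activity_smarts)
    if patt is None:
        raise ValueError(f"bad activity SMARTS: {spec.activity_smarts}")
    rng = np.random.default_rng(spec.seed + 4)
    rows = []
    lo, hi = spec.year_range
    for mol in molecules:
        planted = bool(mol.mol.HasSubstructMatch(patt))
        flipped = bool(rng.random() < spec.label_noise)
        draw_active = planted ^ flipped
        mu = 7.5 if draw_active else 5.0
        pchembl = float(rng.normal(mu, 0.5))
        rows.append(
            {
                "smiles": mol.smiles_canonical,
                "pchembl": round(pchembl, 3),
                "year": int(rng.integers(lo, hi + 1)),
                "id": mol.id,
                "planted": int(planted),
                "flipped": int(flipped),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stub scoring models for engineered triage fixtures
# ---------------------------------------------------------------------------


class SubstructureProbabilityModel:
    """A deterministic stand-in classifier keyed on a substructure.

    ``predict_proba_records`` returns ``p_match`` for molecules containing
    the pattern and ``p_other`` otherwise — an exactly knowable oracle for
    cascade fixtures.
    """

    def __init__(self, smarts: str, p_match: float = 0.95, p_other: float = 0.05):
        self.smarts = smarts
        self.pattern = Chem.MolFromSmarts(smarts)
        if self.pattern is None:
            raise ValueError(f"bad SMARTS: {smarts}")
        self.p_match = p_match
        self.p_other = p_other

    def predict_proba_records(self, records: Sequence[MoleculeRecord]) -> np.ndarray:
        return np.array(
            [
                self.p_match if r.mol.HasSubstructMatch(self.pattern) else self.p_other
                for r in records
            ]
        )


# ---------------------------------------------------------------------------
# engineered triage fixture
# ---------------------------------------------------------------------------


@dataclass
class TriageFixture:
    """A 20-candidate cascade fixture with exactly known per-stage outcomes."""

    candidates: List[MoleculeRecord]
    qsar_model: SubstructureProbabilityModel
    score_model: SubstructureProbabilityModel
    stock: Stock
    templates: List[ReactionTemplate]
    known_ligands: List[MoleculeRecord]
    expected_survivors: List[int]
    expected_first_fail: Dict[str, str]
    config: dict  # kwargs for TriageConfig
    search_config: dict  # kwargs for SearchConfig


def gen_triage_fixture(seed: int = 0) -> TriageFixture:
    """Build the engineered cascade fixture: 20 candidates, eliminations (5,3,2,1,1).

    Activity is keyed on a pyridine ring, synthesizability on an amide
    bond (both via deterministic substructure stand-in models).  Survivor
    ground truth per stage: 20 → 15 → 12 → 10 → 9 → 8.  Every planted
    outcome (solvability, minimum steps, rule-of-five, novelty) is
    certified here against the package's own per-stage oracles.
    """
    from .triage import lipinski_pass, novelty_score

    templates = make_templates(seed)
    by_id = {t.id: t for t in templates}
    amide = by_id["amide_coupling"]
    ester = by_id["esterification"]

    def mk(smiles: str) -> MoleculeRecord:
        return canonicalize(smiles)

    pyr_acid = mk("OC(=O)c1ccncc1")
    acetic = mk("CC(=O)O")
    propionic = mk("CCC(=O)O")
    greasy = mk("CCCCCCCCCCCCCCCCN(CCCCCCCCCCCCCCCC)C(=O)c1ccncc1")
    stock_smiles = [
        "OC(=O)c1ccncc1",
        "CC(=O)O",
        "CCC(=O)O",
        "CN",
        "CCN",
        "CC(C)N",
        "NC1CCCCC1",
        "Nc1ccccc1",
        "NCc1ccccc1",
        "C1COCCN1",
        "CNC",
        "NCCC1CC1",
        "NCCO",
        greasy.smiles_canonical,
    ]
    stock_records = [canonicalize(s, f"tb_{i}") for i, s in enumerate(stock_smiles)]
    stock = stock_from_records(stock_records, name=f"triage_stock_s{seed}")

    def amide_of(amine_smiles: str) -> MoleculeRecord:
        products = apply_forward(amide, [pyr_acid, mk(amine_smiles)])
        assert products, f"amide formation failed for {amine_smiles}"
        return products[0]

    # 8 full passers: one-step pyridyl amides from stock amines
    passers = [
        amide_of(a)
        for a in ("CN", "CCN", "CC(C)N", "NC1CCCCC1", "NCc1ccccc1", "C1COCCN1", "CNC", "NCCC1CC1")
    ]
    # 1 novelty failer: the aniline amide, also planted as a known ligand
    novelty_failer = amide_of("Nc1ccccc1")
    # 1 rule-of-five failer: in-stock (0 steps) but far too large and greasy
    ro5_failer = greasy
    # 2 route-length failers: two-step acyl esters of the ethanolamine amide
    intermediate = amide_of("NCCO")
    long_1 = apply_forward(ester, [acetic, intermediate])[0]
    long_2 = apply_forward(ester, [propionic, intermediate])[0]
    # 3 route failers: amides of CF3 amines absent from stock
    unsolvables = [amide_of(a) for a in ("NCC(F)(F)F", "NCCC(F)(F)F", "NC(C)C(F)(F)F")]
    # 5 probability failers: 3 amides without pyridine, 2 pyridines without amide
    prob_failers = [
        mk("CC(=O)NC1CCCCC1"),
        mk("CC(=O)NCc1ccccc1"),
        mk("CC(=O)N1CCOCC1"),
        mk("CCOc1ccncc1"),
        mk("c1ccc(-c2ccncc2)cc1"),
    ]

    groups = (
        [(m, "PASS") for m in passers]
        + [(novelty_failer, "novelty")]
        + [(ro5_failer, "rule_of_five")]
        + [(long_1, "route_length"), (long_2, "route_length")]
        + [(m, "route_found") for m in unsolvables]
        + [(m, "probability_filter") for m in prob_failers]
    )
    assert len(groups) == 20
    rng = np.random.default_rng(seed + 5)
    order = rng.permutation(len(groups))
    candidates: List[MoleculeRecord] = []
    expected_first_fail: Dict[str, str] = {}
    for pos, gi in enumerate(order):
        mol, outcome = groups[gi]
        rec = MoleculeRecord(
            id=f"cand_{pos:02d}",
            smiles_input=mol.smiles_canonical,
            smiles_canonical=mol.smiles_canonical,
            inchikey=mol.inchikey,
        )
        candidates.append(rec)
        expected_first_fail[rec.id] = outcome

    known_ligands = [
        MoleculeRecord(
            id="known_0",
            smiles_input=novelty_failer.smiles_canonical,
            smiles_canonical=novelty_failer.smiles_canonical,
            inchikey=novelty_failer.inchikey,
        ),
        canonicalize("CC(C)Cc1ccc(C(C)C(=O)O)cc1", "known_1"),
    ]

    # certify every planted outcome against the package's own oracles
    from .chem import morgan_fingerprint, tanimoto

    pyridine = Chem.MolFromSmarts("c1ccncc1")
    amide_patt = Chem.MolFromSmarts("[CX3](=O)[NX3]")
    for rec in candidates:
        outcome = expected_first_fail[rec.id]
        has_act = rec.mol.HasSubstructMatch(pyridine)
        has_syn = rec.mol.HasSubstructMatch(amide_patt)
        assert (has_act and has_syn) == (outcome != "probability_filter"), rec.id
        if outcome == "probability_filter":
            continue
        oracle = bfs_oracle(rec, stock, templates, max_depth=4)
        assert oracle.feasible, rec.id
        if outcome == "route_found":
            assert not oracle.solved, rec.id
            continue
        assert oracle.solved, rec.id
        assert (oracle.min_steps > 1) == (outcome == "route_length"), rec.id
        if outcome == "route_length":
            continue
        ok, _ = lipinski_pass(rec, "classic")
        assert ok == (outcome != "rule_of_five"), rec.id
        if outcome == "rule_of_five":
            continue
        sim, _ = novelty_score(rec, known_ligands)
        assert (sim >= 0.7) == (outcome == "novelty"), rec.id

    return TriageFixture(
        candidates=candidates,
        qsar_model=SubstructureProbabilityModel("c1ccncc1"),
        score_model=SubstructureProbabilityModel("[CX3](=O)[NX3]"),
        stock=stock,
        templates=templates,
        known_ligands=known_ligands,
        expected_survivors=[15, 12, 10, 9, 8],
        expected_first_fail=expected_first_fail,
        config={"max_route_steps": 1},
        search_config={"iteration_limit": 500, "max_depth": 4, "seed": seed},
    )


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------


def write_fixture_set(spec: FixtureSpec, out_dir: str) -> Dict[str, str]:
    """Generate the full fixture set and write it under ``out_dir``.

    Emits templates.csv, stock.smi, solvable.smi, unsolvable.smi,
    ligands.csv and ground_truth.json; byte-identical for a fixed spec.
    """
    os.makedirs(out_dir, exist_ok=True)
    templates, stock, stock_records = gen_reaction_universe(spec)
    solvable = gen_solvable(spec, templates, stock, stock_records)
    unsolvable = gen_unsolvable(spec, solvable, templates, stock)
    all_mols = [s.record for s in solvable] + [u.record for u in unsolvable]
    ligands = gen_activity_table(spec, all_mols)

    paths = {
        "templates": os.path.join(out_dir, "templates.csv"),
        "stock": os.path.join(out_dir, "stock.smi"),
        "solvable": os.path.join(out_dir, "solvable.smi"),
        "unsolvable": os.path.join(out_dir, "unsolvable.smi"),
        "ligands": os.path.join(out_dir, "ligands.csv"),
        "ground_truth": os.path.join(out_dir, "ground_truth.json"),
    }
    write_templates(templates, paths["templates"])
    write_molecules(stock_records, paths["stock"])
    write_molecules([s.record for s in solvable], paths["solvable"])
    write_molecules([u.record for u in unsolvable], paths["unsolvable"])
    ligands.to_csv(paths["ligands"], index=False)
    truth = {
        "spec": {
            "seed": spec.seed,
            "stock_size": spec.stock_size,
            "n_solvable": spec.n_solvable,
            "steps_range": list(spec.steps_range),
            "n_unsolvable": spec.n_unsolvable,
            "activity_smarts": spec.activity_smarts,
            "label_noise": spec.label_noise,
            "year_range": list(spec.year_range),
            "oracle_depth": spec.oracle_depth,
        },
        "solvable": {
            s.record.id: {
                "smiles": s.record.smiles_canonical,
                "built_steps": s.built_steps,
                "oracle_min_steps": s.oracle.min_steps,
                "witness_route": json.loads(s.witness_route.to_json()),
            }
            for s in solvable
        },
        "unsolvable": {
            u.record.id: {"smiles": u.record.smiles_canonical, "oracle_depth": spec.oracle_depth}
            for u in unsolvable
        },
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths
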