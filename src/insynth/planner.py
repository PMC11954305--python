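"""Building-block-constrained retrosynthetic search.

The planner searches the AND/OR space of retro-template applications for
routes whose every leaf is an available building block.  Two search engines
are provided:

* :func:`mcts_search` — Monte-Carlo tree search with a UCB selection rule,
  a deterministic template-prior expansion policy, and a stock-coverage
  rollout value.  This is the production engine.
* :func:`bfs_oracle` — an exhaustive search that returns the exact
  solvability status and the exact minimum number of reaction steps on
  small instances.  It is shipped in the package as the reference arbiter
  for tests and fixture certification.

Depth is counted as the *total number of reaction steps* in a route (the
number of reaction nodes in the route tree), so the MCTS depth limit, the
oracle bound and the reported ``shortest_route_length`` all use the same
unit.

Every route reported as solved is validated before it is returned:
forward-replaying its reaction nodes bottom-up must regenerate the target,
and every leaf must be in stock.  This check is always on.
"""

from __future__ import annotations

import json
import math
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .chem import MoleculeRecord
from .reactions import ReactionTemplate, Stock, apply_forward, apply_retro_counted

# ---------------------------------------------------------------------------
# configuration and result types
# ---------------------------------------------------------------------------


@dataclass
class SearchConfig:
    """Search budget and expansion settings.

    The defaults mirror a production planning setup: 900 s per molecule,
    1000 iterations, route depth 8 and 50 expansions per policy call.  The
    search stops at whichever of the time or iteration limit hits first;
    the time limit is enforced between iterations so that runs where the
    iteration limit binds first are exactly reproducible.
    """

    time_limit_s: float = 900.0
    iteration_limit: int = 1000
    max_depth: int = 8
    expansion_width: int = 50
    exploration_c: float = math.sqrt(2.0)
    rollout_gamma: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.time_limit_s <= 0 or self.iteration_limit <= 0:
            raise ValueError("time and iteration limits must be positive")
        if self.max_depth <= 0 or self.expansion_width <= 0:
            raise ValueError("max_depth and expansion_width must be positive")

    def digest(self) -> str:
        import hashlib

        payload = json.dumps(
            {
                "time_limit_s": self.time_limit_s,
                "iteration_limit": self.iteration_limit,
                "max_depth": self.max_depth,
                "expansion_width": self.expansion_width,
                "exploration_c": self.exploration_c,
                "rollout_gamma": self.rollout_gamma,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class RouteTree:
    """A synthesis route: alternating molecule and reaction nodes.

    The underlying representation is the nested-dict JSON schema
    ``{"type": "mol", "smiles": ..., "in_stock": bool, "children": [
    {"type": "reaction", "template_id": ..., "children": [...]}]}``.
    """

    def __init__(self, root: dict, target: MoleculeRecord):
        self.root = root
        self.target = target

    @property
    def n_steps(self) -> int:
        return sum(1 for node in self._walk() if node["type"] == "reaction")

    def leaves(self) -> List[dict]:
        return [
            node
            for node in self._walk()
            if node["type"] == "mol" and not node.get("children")
        ]

    def _walk(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.get("children", []))

    def to_json(self) -> str:
        return json.dumps(self.root, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str, target: Optional[MoleculeRecord] = None) -> "RouteTree":
        from .chem import canonicalize

        root = json.loads(text)
        if target is None:
            target = canonicalize(root["smiles"])
        return cls(root, target)

    def signature(self) -> frozenset:
        """Multiset of (template id, product InChIKey) pairs, for dedup."""
        from collections import Counter

        pairs = Counter()
        for node in self._walk():
            if node["type"] == "mol" and node.get("children"):
                rxn = node["children"][0]
                pairs[(rxn["template_id"], node["inchikey"])] += 1
        return frozenset(pairs.items())


@dataclass
class SearchResult:
    target: MoleculeRecord
    solved: bool
    routes: List[RouteTree]
    shortest_route_length: Optional[int]
    iterations_used: int
    wall_time_s: float
    invalid_expansions: int


@dataclass
class OracleResult:
    """Exact answer from the exhaustive oracle, or an explicit refusal."""

    solved: Optional[bool]
    min_steps: Optional[int]
    feasible: bool = True
    nodes_expanded: int = 0


# ---------------------------------------------------------------------------
# expansion policy
# ---------------------------------------------------------------------------


class ExpansionPolicy:
    """Deterministic expansion policy ranking (template, precursor set) pairs.

    Stands in for a learned single-step model: the score of an applicable
    pair is the template's prior weight; ties break by template id, then by
    the sorted precursor InChIKey tuple.  The interface (``__call__`` on a
    molecule returning ranked pairs) is the plug point for a trained policy.
    """

    def __init__(self, templates: Sequence[ReactionTemplate]):
        self.templates = sorted(templates, key=lambda t: t.id)
        self._cache: Dict[str, Tuple[list, int]] = {}

    def __call__(self, mol: MoleculeRecord, width: int):
        ranked, _ = self.expand(mol)
        return ranked[:width]

    def expand(self, mol: MoleculeRecord) -> Tuple[list, int]:
        cached = self._cache.get(mol.inchikey)
        if cached is not None:
            return cached
        pairs = []
        invalid = 0
        for template in self.templates:
            sets, bad = apply_retro_counted(template, mol)
            invalid += bad
            for precursors in sets:
                key = tuple(sorted(p.inchikey for p in precursors))
                pairs.append((-template.prior, template.id, key, template, precursors))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        ranked = [(t, precs) for _, _, _, t, precs in pairs]
        self._cache[mol.inchikey] = (ranked, invalid)
        return ranked, invalid


def rank_expansions(
    mol: MoleculeRecord, templates: Sequence[ReactionTemplate], width: int
) -> List[Tuple[ReactionTemplate, List[MoleculeRecord]]]:
    """Ranked applicable (template, precursor set) pairs, truncated to ``width``."""
    if width < 1:
        raise ValueError("width must be >= 1")
    return ExpansionPolicy(templates)(mol, width)


# ---------------------------------------------------------------------------
# MCTS
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = (
        "state",
        "depth",
        "parent",
        "action",
        "n_stock_leaves",
        "children",
        "visits",
        "value_sum",
        "expanded",
        "terminal",
        "fully_explored",
    )

    def __init__(self, state, depth, parent, action, n_stock_leaves):
        self.state = state  # sorted tuple (with multiplicity) of unsolved keys
        self.depth = depth  # total reaction steps applied so far
        self.parent = parent
        self.action = action  # (expanded_key, template, precursor records)
        self.n_stock_leaves = n_stock_leaves
        self.children: List["_Node"] = []
        self.visits = 0
        self.value_sum = 0.0
        self.expanded = False
        self.terminal = False
        self.fully_explored = False

    @property
    def solved(self) -> bool:
        return len(self.state) == 0

    def value(self, gamma: float) -> float:
        total = self.n_stock_leaves + len(self.state)
        frac = self.n_stock_leaves / total if total else 1.0
        return frac * gamma**self.depth


def _reconstruct_route(
    node: _Node, target: MoleculeRecord, stock: Stock
) -> RouteTree:
    """Rebuild the route tree from the chain of actions leading to ``node``."""
    actions = []
    cur = node
    while cur.parent is not None:
        actions.append(cur.action)
        cur = cur.parent
    actions.reverse()

    def mol_node(rec: MoleculeRecord) -> dict:
        return {
            "type": "mol",
            "smiles": rec.smiles_canonical,
            "inchikey": rec.inchikey,
            "in_stock": rec in stock,
            "children": [],
        }

    root = mol_node(target)
    open_leaves: Dict[str, List[dict]] = {}
    if target not in stock:
        open_leaves.setdefault(target.inchikey, []).append(root)
    for key, template, precursors in actions:
        leaf = open_leaves[key].pop(0)
        if not open_leaves[key]:
            del open_leaves[key]
        rxn = {"type": "reaction", "template_id": template.id, "children": []}
        leaf["children"] = [rxn]
        for prec in precursors:
            child = mol_node(prec)
            rxn["children"].append(child)
            if not child["in_stock"]:
                open_leaves.setdefault(prec.inchikey, []).append(child)
    return RouteTree(root, target)


def validate_route(route: RouteTree, stock: Stock, templates: Sequence[ReactionTemplate]) -> bool:
    """Forward-replay a route bottom-up and check all leaves are in stock."""
    from .chem import canonicalize

    by_id = {t.id: t for t in templates}

    def replay(mol_node: dict) -> Optional[str]:
        children = mol_node.get("children", [])
        if not children:
            if not mol_node.get("in_stock"):
                return None
            return mol_node["smiles"]
        rxn = children[0]
        template = by_id.get(rxn["template_id"])
        if template is None:
            return None
        precursor_smiles = [replay(c) for c in rxn["children"]]
        if any(s is None for s in precursor_smiles):
            return None
        precursors = [canonicalize(s) for s in precursor_smiles]
        products = apply_forward(template, precursors)
        target_smiles = mol_node["smiles"]
        if target_smiles in {p.smiles_canonical for p in products}:
            return target_smiles
        return None

    leaves_ok = all(
        leaf.get("in_stock") and canonicalize(leaf["smiles"]) in stock
        for leaf in route.leaves()
    )
    return leaves_ok and replay(route.root) == route.target.smiles_canonical


def mcts_search(
    target: MoleculeRecord,
    stock: Stock,
    templates: Sequence[ReactionTemplate],
    config: Optional[SearchConfig] = None,
    policy: Optional[ExpansionPolicy] = None,
) -> SearchResult:
    """Monte-Carlo tree search for building-block-constrained routes.

    Each iteration runs one select (UCB) → expand (ranked template
    applications) → evaluate (in-stock leaf fraction, depth-discounted) →
    backpropagate cycle.  All solved routes discovered are retained; the
    shortest one defines ``shortest_route_length``.  The search is fully
    reproducible for a fixed config because the expansion policy and all
    tie-breaks are deterministic.
    """
    config = config or SearchConfig()
    config.validate()
    t0 = time.monotonic()

    if target in stock:
        root_mol = {
            "type": "mol",
            "smiles": target.smiles_canonical,
            "inchikey": target.inchikey,
            "in_stock": True,
            "children": [],
        }
        route = RouteTree(root_mol, target)
        return SearchResult(
            target=target,
            solved=True,
            routes=[route],
            shortest_route_length=0,
            iterations_used=0,
            wall_time_s=time.monotonic() - t0,
            invalid_expansions=0,
        )

    policy = policy or ExpansionPolicy(templates)
    records: Dict[str, MoleculeRecord] = {target.inchikey: target}
    root = _Node(state=(target.inchikey,), depth=0, parent=None, action=None, n_stock_leaves=0)
    solved_nodes: List[_Node] = []
    route_signatures = set()
    routes: List[RouteTree] = []
    invalid_total = 0
    gamma = config.rollout_gamma
    c = config.exploration_c

    def expand(node: _Node) -> None:
        nonlocal invalid_total
        node.expanded = True
        key = node.state[0]
        mol = records[key]
        ranked, invalid = policy.expand(mol)
        invalid_total += invalid
        rest = node.state[1:]
        for template, precursors in ranked[: config.expansion_width]:
            new_unsolved = list(rest)
            n_stock = node.n_stock_leaves
            for prec in precursors:
                records.setdefault(prec.inchikey, prec)
                if prec in stock:
                    n_stock += 1
                else:
                    new_unsolved.append(prec.inchikey)
            child = _Node(
                state=tuple(sorted(new_unsolved)),
                depth=node.depth + 1,
                parent=node,
                action=(key, template, precursors),
                n_stock_leaves=n_stock,
            )
            node.children.append(child)
            if child.solved:
                child.terminal = True
                child.fully_explored = True
                solved_nodes.append(child)
            elif child.depth >= config.max_depth:
                # unsolved at the depth limit: dead end
                child.terminal = True
                child.fully_explored = True
        if not node.children:
            node.terminal = True
            node.fully_explored = True

    def select(node: _Node) -> _Node:
        """Descend by UCB to a node awaiting expansion (or an exhausted one)."""
        while node.expanded and not node.terminal:
            open_children = [ch for ch in node.children if not ch.fully_explored]
            if not open_children:
                node.fully_explored = True
                return node
            unvisited = [ch for ch in open_children if ch.visits == 0]
            if unvisited:
                return unvisited[0]
            log_n = math.log(max(node.visits, 1))
            node = max(
                open_children,
                key=lambda ch: (ch.value_sum / ch.visits + c * math.sqrt(log_n / ch.visits)),
            )
        return node

    def backprop(node: _Node, value: float) -> None:
        while node is not None:
            node.visits += 1
            node.value_sum += value
            if node.expanded and not node.terminal and node.children:
                if all(ch.fully_explored for ch in node.children):
                    node.fully_explored = True
            node = node.parent

    iterations = 0
    while iterations < config.iteration_limit:
        if time.monotonic() - t0 > config.time_limit_s:
            break
        if root.fully_explored:
            break
        leaf = select(root)
        if not leaf.expanded and not leaf.terminal:
            expand(leaf)
            if leaf.children:
                # evaluate the top-ranked fresh child so solves and stock
                # coverage feed straight into the UCB statistics
                leaf = leaf.children[0]
        backprop(leaf, leaf.value(gamma))
        iterations += 1

    for node in solved_nodes:
        route = _reconstruct_route(node, target, stock)
        sig = route.signature()
        if sig in route_signatures:
            continue
        route_signatures.add(sig)
        if not validate_route(route, stock, templates):  # pragma: no cover - soundness guard
            raise RuntimeError(
                f"internal error: extracted route for {target.smiles_canonical} failed validation"
            )
        routes.append(route)

    routes.sort(key=lambda r: (r.n_steps, r.to_json()))
    solved = bool(routes)
    return SearchResult(
        target=target,
        solved=solved,
        routes=routes,
        shortest_route_length=routes[0].n_steps if solved else None,
        iterations_used=iterations,
        wall_time_s=time.monotonic() - t0,
        invalid_expansions=invalid_total,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


DEFAULT_ORACLE_NODE_BUDGET = 200_000


def bfs_oracle(
    target: MoleculeRecord,
    stock: Stock,
    templates: Sequence[ReactionTemplate],
    max_depth: int = 4,
    node_budget: int = DEFAULT_ORACLE_NODE_BUDGET,
    policy: Optional[ExpansionPolicy] = None,
) -> OracleResult:
    """Exhaustive AND/OR search: exact solvability and minimum step count.

    ``max_depth`` bounds the total number of reaction steps in a route.  The
    oracle either answers exactly or, if the ``node_budget`` is exceeded,
    returns ``feasible=False`` — never a wrong answer.  Intended for small
    instances; the budget guard makes misuse loud rather than slow.
    """
    policy = policy or ExpansionPolicy(templates)
    counter = {"nodes": 0}
    memo: Dict[Tuple[str, int], Optional[int]] = {}

    class _Infeasible(Exception):
        pass

    def best(mol: MoleculeRecord, budget: int) -> Optional[int]:
        """Exact minimum total steps to make ``mol``, or None if > budget."""
        if mol in stock:
            return 0
        if budget <= 0:
            return None
        key = (mol.inchikey, budget)
        if key in memo:
            return memo[key]
        counter["nodes"] += 1
        if counter["nodes"] > node_budget:
            raise _Infeasible
        result: Optional[int] = None
        cap = budget
        ranked, _ = policy.expand(mol)
        for template, precursors in ranked:
            total = 1
            ok = True
            for prec in sorted(precursors, key=lambda p: p.inchikey):
                sub = best(prec, cap - total)
                if sub is None:
                    ok = False
                    break
                total += sub
            if ok and total <= cap:
                result = total
                cap = total - 1  # only look for strictly better routes now
        memo[key] = result
        return result

    try:
        steps = best(target, max_depth)
    except _Infeasible:
        return OracleResult(solved=None, min_steps=None, feasible=False, nodes_expanded=counter["nodes"])
    return OracleResult(
        solved=steps is not None,
        min_steps=steps,
        feasible=True,
        nodes_expanded=counter["nodes"],
    )


# ---------------------------------------------------------------------------
# batch planning
# ---------------------------------------------------------------------------


def batch_plan(
    molecules: Sequence[MoleculeRecord],
    stock: Stock,
    templates: Sequence[ReactionTemplate],
    config: Optional[SearchConfig] = None,
    journal_path: Optional[str] = None,
    include_times: bool = False,
) -> pd.DataFrame:
    """Plan every molecule and return a per-molecule summary table.

    Columns: ``id, smiles, solved, shortest_route_length, iterations,
    invalid_expansions`` (wall times are reported only when
    ``include_times`` is set, keeping the default table byte-reproducible).
    Individual failures are recorded per row and never abort the batch.  If
    ``journal_path`` is given, completed rows are appended there as they
    finish and a rerun resumes after the last completed molecule.
    """
    if len(molecules) == 0:
        raise ValueError("batch_plan requires a non-empty molecule list")
    config = config or SearchConfig()
    policy = ExpansionPolicy(templates)

    done: Dict[str, dict] = {}
    if journal_path and os.path.exists(journal_path):
        prior = pd.read_csv(journal_path)
        # CSV round-trips empty strings as NaN; normalize so a resumed
        # table is identical to a fresh one
        if "error" in prior.columns:
            prior["error"] = prior["error"].fillna("")
        if "shortest_route_length" in prior.columns:
            prior["shortest_route_length"] = (
                prior["shortest_route_length"].astype("Int64").astype(object)
            )
        for _, row in prior.iterrows():
            d = row.to_dict()
            if d.get("shortest_route_length") is pd.NA:
                d["shortest_route_length"] = None
            done[str(d["id"])] = d

    rows = []
    for mol in molecules:
        if mol.id in done:
            rows.append(done[mol.id])
            continue
        row = {"id": mol.id, "smiles": mol.smiles_canonical}
        try:
            result = mcts_search(mol, stock, templates, config, policy=policy)
            row.update(
                solved=bool(result.solved),
                shortest_route_length=(
                    result.shortest_route_length if result.solved else None
                ),
                iterations=result.iterations_used,
                invalid_expansions=result.invalid_expansions,
                error="",
            )
            if include_times:
                row["wall_time_s"] = result.wall_time_s
        except Exception as exc:  # pragma: no cover - defensive batch guard
            row.update(
                solved=False,
                shortest_route_length=None,
                iterations=0,
                invalid_expansions=0,
                error=str(exc),
            )
        rows.append(row)
        if journal_path:
            pd.DataFrame(rows).to_csv(journal_path, index=False)
    table = pd.DataFrame(rows)
    table["shortest_route_length"] = table["shortest_route_length"].astype("Int64")
    return table


def batch_summary(table: pd.DataFrame) -> dict:
    """Aggregate solvability fraction and route-length distribution."""
    solved = table["solved"].astype(bool)
    lengths = table.loc[solved, "shortest_route_length"].dropna().astype(int)
    return {
        "n": int(len(table)),
        "n_solved": int(solved.sum()),
        "solvability": float(solved.mean()) if len(table) else 0.0,
        "route_length_mean": float(lengths.mean()) if len(lengths) else None,
        "route_length_counts": {int(k): int(v) for k, v in lengths.value_counts().sort_index().items()},
    }
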