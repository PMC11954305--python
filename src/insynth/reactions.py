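"""Reaction templates, building-block stocks and template application.

Templates are retro-SMARTS rules (``product pattern >> precursor patterns``)
with a prior weight used by the planner's expansion ranking.  The forward
direction of a template is obtained by swapping the two sides of the
retro-SMARTS; every shipped template is required to be round-trip sound:
re-combining the precursors of a successful retro application under the
same template regenerates the product.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import MoleculeRecord, canonicalize, from_mol

logger = logging.getLogger(__name__)


class TemplateError(ValueError):
    pass


@dataclass
class ReactionTemplate:
    """A retro-transformation rule with an expansion-ranking prior."""

    id: str
    retro_smarts: str
    name: str = ""
    prior: float = 1.0
    max_precursors: int = 2
    _retro_rxn: Optional[AllChem.ChemicalReaction] = field(default=None, repr=False, compare=False)
    _forward_rxn: Optional[AllChem.ChemicalReaction] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.prior < 0:
            raise TemplateError(f"template {self.id}: prior must be >= 0")
        if ">>" not in self.retro_smarts:
            raise TemplateError(f"template {self.id}: retro_smarts lacks '>>'")
        self._compile()

    def _compile(self) -> None:
        try:
            retro = AllChem.ReactionFromSmarts(self.retro_smarts)
        except Exception as exc:
            raise TemplateError(f"template {self.id}: unparseable retro SMARTS ({exc})")
        if retro is None or retro.GetNumReactantTemplates() != 1:
            raise TemplateError(
                f"template {self.id}: retro SMARTS must have exactly one product pattern"
            )
        left, right = self.retro_smarts.split(">>")
        try:
            forward = AllChem.ReactionFromSmarts(f"{right}>>{left}")
        except Exception as exc:
            raise TemplateError(f"template {self.id}: forward direction unparseable ({exc})")
        self._retro_rxn = retro
        self._forward_rxn = forward
        self.max_precursors = retro.GetNumProductTemplates()

    @property
    def retro_rxn(self) -> AllChem.ChemicalReaction:
        if self._retro_rxn is None:
            self._compile()
        return self._retro_rxn

    @property
    def forward_rxn(self) -> AllChem.ChemicalReaction:
        if self._forward_rxn is None:
            self._compile()
        return self._forward_rxn

    @property
    def n_reactants(self) -> int:
        return self.forward_rxn.GetNumReactantTemplates()


@dataclass
class Stock:
    """A set of available building blocks keyed by full InChIKey.

    Full-key matching (rather than the connectivity-only first block) is the
    conservative choice: stereoisomers of a stocked compound do not count as
    in stock.
    """

    name: str
    members: Set[str] = field(default_factory=set)
    source_path: str = ""
    smiles_by_key: Dict[str, str] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    def __contains__(self, item) -> bool:
        if isinstance(item, MoleculeRecord):
            return item.inchikey in self.members
        return str(item).upper() in self.members

    def add(self, record: MoleculeRecord) -> None:
        self.members.add(record.inchikey)
        self.smiles_by_key.setdefault(record.inchikey, record.smiles_canonical)

    def union(self, other: "Stock", name: Optional[str] = None) -> "Stock":
        merged = Stock(name=name or f"{self.name}+{other.name}")
        merged.members = set(self.members) | set(other.members)
        merged.smiles_by_key = {**other.smiles_by_key, **self.smiles_by_key}
        return merged


_INCHIKEY_LEN = 27


def _looks_like_inchikey(token: str) -> bool:
    t = token.strip().upper()
    return len(t) == _INCHIKEY_LEN and t.count("-") == 2 and t.replace("-", "").isalnum()


def load_stock(path: str, name: Optional[str] = None) -> Stock:
    """Load a stock from a ``.smi`` file or a one-InChIKey-per-line list.

    SMILES entries are canonicalized to InChIKeys; duplicates collapse.  An
    empty stock is valid (everything becomes unsolvable) but logged.
    """
    stock = Stock(name=name or os.path.basename(path), source_path=path)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split()[0]
            if _looks_like_inchikey(token):
                stock.members.add(token.upper())
            else:
                try:
                    stock.add(canonicalize(token))
                except Exception:
                    logger.warning("skipping unparseable stock entry %r in %s", token, path)
    if stock.size == 0:
        logger.warning("stock %s is empty; no target will be solvable", stock.name)
    return stock


def stock_from_records(records: Sequence[MoleculeRecord], name: str = "stock") -> Stock:
    stock = Stock(name=name)
    for rec in records:
        stock.add(rec)
    return stock


def load_templates(path: str) -> List[ReactionTemplate]:
    """Load and validate templates from CSV (id,retro_smarts[,name,prior]) or JSON.

    Every template must compile in both directions; invalid or duplicated
    ids abort the load with an error naming the offenders.
    """
    rows: List[dict]
    if path.endswith(".json"):
        with open(path) as fh:
            rows = json.load(fh)
    else:
        import pandas as pd

        df = pd.read_csv(path)
        missing = {"id", "retro_smarts"} - set(df.columns)
        if missing:
            raise TemplateError(f"template file {path} missing columns: {sorted(missing)}")
        rows = df.to_dict("records")

    templates: List[ReactionTemplate] = []
    bad: List[str] = []
    seen_ids: Set[str] = set()
    dupes: List[str] = []
    for row in rows:
        tid = str(row["id"])
        if tid in seen_ids:
            dupes.append(tid)
            continue
        seen_ids.add(tid)
        try:
            templates.append(
                ReactionTemplate(
                    id=tid,
                    retro_smarts=str(row["retro_smarts"]),
                    name=str(row.get("name", "") or ""),
                    prior=float(row.get("prior", 1.0) if row.get("prior") == row.get("prior") else 1.0),
                )
            )
        except TemplateError as exc:
            logger.error("%s", exc)
            bad.append(tid)
    if dupes:
        raise TemplateError(f"duplicate template ids: {dupes}")
    if bad:
        raise TemplateError(f"invalid templates: {bad}")
    if not templates:
        raise TemplateError(f"no valid templates in {path}")
    return templates


def write_templates(templates: Sequence[ReactionTemplate], path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "id": [t.id for t in templates],
            "retro_smarts": [t.retro_smarts for t in templates],
            "name": [t.name for t in templates],
            "prior": [t.prior for t in templates],
        }
    ).to_csv(path, index=False)


def _sanitize_products(tup) -> Optional[List[MoleculeRecord]]:
    """Canonicalize one RunReactants output tuple; None if any fragment is bad."""
    out = []
    for m in tup:
        try:
            Chem.SanitizeMol(m)
            out.append(from_mol(m))
        except Exception:
            return None
    return out


def apply_retro(
    template: ReactionTemplate, product: MoleculeRecord
) -> List[List[MoleculeRecord]]:
    """Apply a retro template to a product at all symmetry-distinct sites.

    Returns a list of precursor sets, deduplicated by the multiset of
    precursor InChIKeys; an empty list when the product pattern does not
    match.  Transformations yielding unparseable fragments are dropped (the
    caller may count them via :func:`apply_retro_counted`).
    """
    sets, _ = apply_retro_counted(template, product)
    return sets


def apply_retro_counted(
    template: ReactionTemplate, product: MoleculeRecord
) -> Tuple[List[List[MoleculeRecord]], int]:
    """As :func:`apply_retro`, also returning the invalid-expansion count."""
    try:
        outcomes = template.retro_rxn.RunReactants((product.mol,))
    except Exception:
        return [], 1
    results: List[List[MoleculeRecord]] = []
    seen: Set[Tuple[str, ...]] = set()
    invalid = 0
    for tup in outcomes:
        precursors = _sanitize_products(tup)
        if precursors is None:
            invalid += 1
            continue
        key = tuple(sorted(p.inchikey for p in precursors))
        if key in seen:
            continue
        seen.add(key)
        results.append(precursors)
    return results, invalid


def apply_forward(
    template: ReactionTemplate, reactants: Sequence[MoleculeRecord]
) -> List[MoleculeRecord]:
    """Run a template forward; returns canonical products, [] if inapplicable.

    Tries all orderings of the reactants against the template's reactant
    patterns so the caller need not know the pattern order.
    """
    from itertools import permutations

    n = template.n_reactants
    if len(reactants) != n:
        return []
    seen: Set[str] = set()
    products: List[MoleculeRecord] = []
    orderings = set(permutations(range(n)))
    for order in sorted(orderings):
        mols = tuple(reactants[i].mol for i in order)
        try:
            outcomes = template.forward_rxn.RunReactants(mols)
        except Exception:
            continue
        for tup in outcomes:
            recs = _sanitize_products(tup)
            if recs is None or len(recs) != 1:
                continue
            rec = recs[0]
            if rec.inchikey not in seen:
                seen.add(rec.inchikey)
                products.append(rec)
    return products


def roundtrip_probe(template: ReactionTemplate, probe: MoleculeRecord) -> bool:
    """Check retro→forward soundness of a template on one probe molecule.

    True when every retro precursor set regenerates the probe under the
    forward direction (vacuously true when the template does not apply).
    """
    for precursors in apply_retro(template, probe):
        regenerated = apply_forward(template, precursors)
        if probe.smiles_canonical not in {r.smiles_canonical for r in regenerated}:
            return False
    return True
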