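"""Library curation: cleaning, building-block removal, Butina clustering.

The curation pipeline mirrors how compound-library subsets are prepared for
synthesis-planning benchmarks: clean to drug-like molecules, strip entries
that are themselves purchasable building blocks, sphere-exclusion cluster
the remainder, and keep the centroids of the n largest clusters (reporting
how many molecules those clusters represent in total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem import CLUSTERING_FP_PARAMS, Fingerprint, MoleculeRecord, from_mol, tanimoto
from .reactions import Stock

logger = logging.getLogger(__name__)

#: elements allowed in a cleaned library
ELEMENT_WHITELIST = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)


@dataclass
class CleaningConfig:
    """Thresholds of the cleaning pipeline; all config-exposed."""

    min_heavy_atoms: int = 6
    max_heavy_atoms: int = 70
    element_whitelist: frozenset = ELEMENT_WHITELIST


@dataclass
class RejectionLog:
    """Per-reason rejection counts plus (id, reason) pairs."""

    entries: List[Tuple[str, str]] = field(default_factory=list)

    def add(self, mol_id: str, reason: str) -> None:
        self.entries.append((mol_id, reason))

    @property
    def counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for _, reason in self.entries:
            out[reason] = out.get(reason, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.entries)


_uncharger = rdMolStandardize.Uncharger()


def _largest_organic_fragment(mol: Chem.Mol) -> Optional[Chem.Mol]:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = []
    for f in frags:
        if any(a.GetSymbol() == "C" for a in f.GetAtoms()):
            organic.append(f)
    if not organic:
        return None
    return max(organic, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def clean_library(
    records: Sequence[MoleculeRecord], config: Optional[CleaningConfig] = None
) -> Tuple[List[MoleculeRecord], RejectionLog]:
    """Drug-likeness cleaning pipeline.

    Steps: keep the largest organic fragment → neutralize charges where
    valence-legal → element whitelist → heavy-atom window → deduplicate by
    InChIKey.  Idempotent: cleaning a cleaned library is the identity.
    """
    config = config or CleaningConfig()
    kept: List[MoleculeRecord] = []
    log = RejectionLog()
    seen = set()
    for rec in records:
        mol = _largest_organic_fragment(rec.mol)
        if mol is None:
            log.add(rec.id, "no_organic_fragment")
            continue
        try:
            Chem.SanitizeMol(mol)
            mol = _uncharger.uncharge(mol)
            Chem.SanitizeMol(mol)
        except Exception:
            log.add(rec.id, "sanitize_failed")
            continue
        symbols = {a.GetSymbol() for a in mol.GetAtoms()}
        if not symbols <= config.element_whitelist:
            log.add(rec.id, "element_whitelist")
            continue
        n_heavy = mol.GetNumHeavyAtoms()
        if not (config.min_heavy_atoms <= n_heavy <= config.max_heavy_atoms):
            log.add(rec.id, "heavy_atom_range")
            continue
        cleaned = from_mol(mol, mol_id=rec.id)
        if cleaned.inchikey in seen:
            log.add(rec.id, "duplicate")
            continue
        seen.add(cleaned.inchikey)
        kept.append(cleaned)
    return kept, log


def remove_stock_members(
    records: Sequence[MoleculeRecord], stocks: Sequence[Stock]
) -> Tuple[List[MoleculeRecord], int]:
    """Drop records whose InChIKey appears in any of the given stocks."""
    members = set()
    for stock in stocks:
        members |= stock.members
    kept = [r for r in records if r.inchikey not in members]
    removed = len(records) - len(kept)
    if removed:
        logger.info("removed %d records present in %d stock(s)", removed, len(stocks))
    return kept, removed


@dataclass
class ClusterAssignment:
    """Result of sphere-exclusion clustering.

    ``clusters`` is ordered by descending size (ties by first-seen centroid
    index) and forms a partition of the input indices; every member sits
    within the distance cutoff of its centroid.
    """

    clusters: List[Tuple[int, List[int]]]
    cutoff: float
    fp_params: Tuple[int, int] = CLUSTERING_FP_PARAMS

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self, n: int) -> List[int]:
        out = [-1] * n
        for label, (_, members) in enumerate(self.clusters):
            for m in members:
                out[m] = label
        return out


def butina_cluster(fps: Sequence[Fingerprint], cutoff: float) -> ClusterAssignment:
    """Classic Butina sphere-exclusion clustering.

    ``cutoff`` is a *distance* (1 − Tanimoto) threshold.  Neighbor lists at
    distance ≤ cutoff are computed, then the unassigned molecule with the
    most unassigned neighbors is repeatedly picked as a centroid, absorbing
    its unassigned neighbors.  Ties on the neighbor count break toward the
    lowest input index, making the partition deterministic.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    n = len(fps)
    if n == 0:
        return ClusterAssignment(clusters=[], cutoff=cutoff)
    nbits = fps[0].nbits
    if any(fp.nbits != nbits for fp in fps):
        raise ValueError("all fingerprints must share nbits")

    neighbors: List[set] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if 1.0 - tanimoto(fps[i], fps[j]) <= cutoff:
                neighbors[i].add(j)
                neighbors[j].add(i)

    unassigned = set(range(n))
    clusters: List[Tuple[int, List[int]]] = []
    while unassigned:
        centroid = max(
            unassigned,
            key=lambda i: (len(neighbors[i] & unassigned), -i),
        )
        members = sorted((neighbors[centroid] & unassigned) | {centroid})
        clusters.append((centroid, members))
        unassigned -= set(members)
    # order by descending size; ties keep discovery (first-seen) order
    clusters = [c for _, c in sorted(enumerate(clusters), key=lambda t: (-len(t[1][1]), t[0]))]
    return ClusterAssignment(clusters=clusters, cutoff=cutoff)


def select_centroid_subset(
    records: Sequence[MoleculeRecord], assignment: ClusterAssignment, n_clusters: int
) -> Tuple[List[MoleculeRecord], int]:
    """Centroids of the n largest clusters plus the member count they cover."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > assignment.n_clusters:
        logger.warning(
            "requested %d clusters but only %d exist; returning all centroids",
            n_clusters,
            assignment.n_clusters,
        )
        n_clusters = assignment.n_clusters
    chosen = assignment.clusters[:n_clusters]
    centroids = [records[c] for c, _ in chosen]
    covered = sum(len(members) for _, members in chosen)
    return centroids, covered
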