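"""Molecule representation, canonicalization, fingerprints, descriptors and I/O.

Every stage of the toolkit passes :class:`MoleculeRecord` objects around.  A
record is created once by :func:`canonicalize` and carries the canonical
SMILES, the standard InChIKey (the structural identity used for
deduplication, stock membership and rediscovery checks) and lazily computed
caches for Morgan fingerprints and physicochemical descriptors.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: fingerprint settings used for synthesizability / activity featurization
SCORING_FP_PARAMS = (3, 2048)
#: fingerprint settings used for library clustering
CLUSTERING_FP_PARAMS = (2, 1024)

#: names of the physicochemical descriptor block, in fixed column order
DESCRIPTOR_NAMES: Tuple[str, ...] = (
    "mw",
    "clogp",
    "hbd",
    "hba",
    "tpsa",
    "rotatable_bonds",
    "aromatic_rings",
    "heavy_atoms",
    "ring_count",
    "fraction_csp3",
    "formal_charge",
    "stereocenters",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed.

    Carries the offending string in :attr:`smiles`.
    """

    def __init__(self, smiles: str, reason: str = "unparseable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class Fingerprint:
    """A Morgan (circular) fingerprint folded to ``nbits`` bits."""

    radius: int
    nbits: int
    bits: FrozenSet[int]

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.nbits <= 0:
            raise ValueError("nbits must be > 0")
        if any(b < 0 or b >= self.nbits for b in self.bits):
            raise ValueError("bit index out of range")

    @property
    def n_on(self) -> int:
        return len(self.bits)


@dataclass
class MoleculeRecord:
    """A molecule with cached canonical structure, fingerprints, descriptors."""

    id: str
    smiles_input: str
    smiles_canonical: str
    inchikey: str
    fp_cache: Dict[Tuple[int, int], Fingerprint] = field(default_factory=dict)
    descriptor_cache: Optional[Dict[str, float]] = None
    _mol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    @property
    def mol(self) -> Chem.Mol:
        if self._mol is None:
            self._mol = Chem.MolFromSmiles(self.smiles_canonical)
            if self._mol is None:  # pragma: no cover - canonical SMILES parse
                raise SmilesParseError(self.smiles_canonical)
        return self._mol

    def fingerprint(self, radius: int = 3, nbits: int = 2048) -> Fingerprint:
        return morgan_fingerprint(self, radius, nbits)

    @property
    def descriptors(self) -> Dict[str, float]:
        return compute_descriptors(self)


def canonicalize(smiles: str, mol_id: Optional[str] = None) -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    Canonicalization is idempotent: feeding the canonical SMILES back in
    yields an identical canonical string and InChIKey.

    Raises
    ------
    SmilesParseError
        If the string is empty or does not parse.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return from_mol(mol, mol_id=mol_id, smiles_input=smiles)


def from_mol(
    mol: Chem.Mol, mol_id: Optional[str] = None, smiles_input: Optional[str] = None
) -> MoleculeRecord:
    """Build a record from an RDKit molecule (already sanitized)."""
    canonical = Chem.MolToSmiles(mol)
    inchikey = Chem.MolToInchiKey(mol)
    return MoleculeRecord(
        id=mol_id if mol_id is not None else inchikey,
        smiles_input=smiles_input if smiles_input is not None else canonical,
        smiles_canonical=canonical,
        inchikey=inchikey,
        _mol=mol,
    )


def morgan_fingerprint(mol: MoleculeRecord, radius: int = 3, nbits: int = 2048) -> Fingerprint:
    """Morgan fingerprint of ``mol``, cached on the record.

    Deterministic for a fixed canonical structure; two SMILES spellings of
    the same molecule produce identical bitsets.
    """
    key = (radius, nbits)
    cached = mol.fp_cache.get(key)
    if cached is not None:
        return cached
    bv = rdMolDescriptors.GetMorganFingerprintAsBitVect(mol.mol, radius, nBits=nbits)
    fp = Fingerprint(radius=radius, nbits=nbits, bits=frozenset(bv.GetOnBits()))
    mol.fp_cache[key] = fp
    return fp


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| between two fingerprints.

    Two empty fingerprints are defined to be maximally similar (1.0): two
    featureless objects carry no distinguishing information, and this avoids
    a 0/0.  The occurrence is logged.
    """
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint size mismatch: {a.nbits} != {b.nbits}")
    union = len(a.bits | b.bits)
    if union == 0:
        logger.debug("tanimoto of two empty fingerprints; returning 1.0 by convention")
        return 1.0
    return len(a.bits & b.bits) / union


def compute_descriptors(mol: MoleculeRecord) -> Dict[str, float]:
    """The 12-descriptor physicochemical block, in :data:`DESCRIPTOR_NAMES` order.

    HBD/HBA are counted by the Lipinski convention (N-H/O-H donors, N+O
    acceptors) so that the rule-of-five triage filter is self-consistent
    with these descriptors.  cLogP is Crippen's atom-contribution estimate.
    """
    if mol.descriptor_cache is not None:
        return mol.descriptor_cache
    m = mol.mol
    d = {
        "mw": Descriptors.MolWt(m),
        "clogp": Crippen.MolLogP(m),
        "hbd": float(Lipinski.NHOHCount(m)),
        "hba": float(Lipinski.NOCount(m)),
        "tpsa": rdMolDescriptors.CalcTPSA(m),
        "rotatable_bonds": float(rdMolDescriptors.CalcNumRotatableBonds(m)),
        "aromatic_rings": float(rdMolDescriptors.CalcNumAromaticRings(m)),
        "heavy_atoms": float(m.GetNumHeavyAtoms()),
        "ring_count": float(rdMolDescriptors.CalcNumRings(m)),
        "fraction_csp3": rdMolDescriptors.CalcFractionCSP3(m),
        "formal_charge": float(Chem.GetFormalCharge(m)),
        "stereocenters": float(
            len(Chem.FindMolChiralCenters(m, includeUnassigned=True, useLegacyImplementation=False))
        ),
    }
    for k, v in d.items():
        if not (v == v and abs(v) != float("inf")):
            raise ValueError(f"non-finite descriptor {k} for {mol.smiles_canonical}")
    mol.descriptor_cache = d
    return d


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _iter_smi_lines(path: str):
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else None
            yield smiles, mol_id


def read_molecules(path: str, fmt: Optional[str] = None) -> Tuple[List[MoleculeRecord], int]:
    """Read molecules from a ``.smi``, ``.sdf`` or ``.csv`` file.

    Unparseable entries are skipped with a logged warning; the skip count is
    returned alongside the records.  An empty file yields an empty list.
    """
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower() or "smi"
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: List[MoleculeRecord] = []
    skipped = 0
    if fmt in ("smi", "smiles", "txt"):
        for i, (smiles, mol_id) in enumerate(_iter_smi_lines(path)):
            try:
                records.append(canonicalize(smiles, mol_id or f"mol_{i}"))
            except SmilesParseError:
                logger.warning("skipping unparseable SMILES %r in %s", smiles, path)
                skipped += 1
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(path, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping unparseable SDF entry %d in %s", i, path)
                skipped += 1
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
            records.append(from_mol(mol, mol_id=mol_id))
    elif fmt == "csv":
        import pandas as pd

        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise ValueError(f"CSV {path} lacks required column 'smiles'")
        for i, row in df.iterrows():
            mol_id = str(row["id"]) if "id" in df.columns else f"mol_{i}"
            try:
                records.append(canonicalize(str(row["smiles"]), mol_id))
            except SmilesParseError:
                logger.warning("skipping unparseable SMILES row %d in %s", i, path)
                skipped += 1
    else:
        raise ValueError(f"unsupported molecule format: {fmt}")
    return records, skipped


def write_molecules(records: Sequence[MoleculeRecord], path: str, fmt: Optional[str] = None) -> None:
    """Write records to ``.smi``, ``.sdf`` or ``.csv``; round-trip stable."""
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower() or "smi"
    if fmt in ("smi", "smiles", "txt"):
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f"{rec.smiles_canonical} {rec.id}\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(path)
        for rec in records:
            mol = Chem.Mol(rec.mol)
            mol.SetProp("_Name", rec.id)
            writer.write(mol)
        writer.close()
    elif fmt == "csv":
        import pandas as pd

        pd.DataFrame(
            {"smiles": [r.smiles_canonical for r in records], "id": [r.id for r in records]}
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported molecule format: {fmt}")


def deduplicate(records: Iterable[MoleculeRecord]) -> List[MoleculeRecord]:
    """Keep the first record per InChIKey, preserving input order."""
    seen = set()
    out = []
    for rec in records:
        if rec.inchikey not in seen:
            seen.add(rec.inchikey)
            out.append(rec)
    return out
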