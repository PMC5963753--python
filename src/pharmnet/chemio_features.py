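"""Molecule libraries, pharmacophore feature perception and screening
descriptors.

Feature perception is rule-based and deliberately simple: the rule table
(:data:`DEFAULT_FEATURE_RULES`) is data, not code, so the exact definitions
used for hydrogen-bond donors/acceptors and hydrophobes can be audited and
overridden.  Descriptors used by the screening filters (HBD/HBA counts) are
counted from the *same* rule table so the filters and the feature perception
cannot disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdMolDescriptors

from .errors import ChemistryError, DomainError, EmbeddingError, FormatError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Closed vocabulary of feature types.
FEATURE_TYPES = ("HYD_ARO", "HYD", "HBA", "HBD")

#: Seed used whenever a conformer has to be generated and the caller did not
#: supply one; fixed so that feature perception is reproducible.
DEFAULT_EMBED_SEED = 1234

#: Default perception rules.  HBA/HBD are SMARTS per-atom patterns; the
#: hydrophobe rules are structural (ring and cluster based) and only the
#: minimum aliphatic-cluster size is configurable.
DEFAULT_FEATURE_RULES: dict = {
    # N/O bearing a lone pair; amide-type N and charged atoms excluded.
    "hba_smarts": [
        "[O;X1;+0]",                       # carbonyl-type oxygen
        "[O;X2;+0]",                       # hydroxyl / ether oxygen
        "[N;X1;+0]",                       # nitrile nitrogen
        "[N;X3;v3;+0;!$([N][C,S]=[O,S,N])]",  # amine N, not amide/sulfonamide
        "[n;X2;+0]",                       # pyridine-type aromatic N
    ],
    # Heavy atoms carrying at least one O-H / N-H.
    "hbd_smarts": [
        "[N;!H0;+0]",
        "[n;!H0;+0]",
        "[O;!H0;+0]",
    ],
    "min_aliphatic_cluster": 3,
}


@dataclass
class MoleculeRecord:
    """One library entry: id, structure and optional conformers/activity."""

    id: str
    smiles: str
    conformers: list = field(default_factory=list)  # list of (n_atoms, 3) arrays
    ic50_uM: float | None = None
    source: str = ""

    _mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.id:
            raise DomainError("molecule id must be nonempty")
        if self.ic50_uM is not None and not self.ic50_uM > 0:
            raise DomainError(f"ic50_uM must be positive, got {self.ic50_uM}")

    def mol(self) -> Chem.Mol:
        """Parsed (sanitized) RDKit molecule; cached."""
        if self._mol is None:
            m = Chem.MolFromSmiles(self.smiles)
            if m is None:
                raise ChemistryError(f"unparsable structure for molecule {self.id!r}")
            self._mol = m
        return self._mol


@dataclass(frozen=True)
class FeaturePoint:
    feature_type: str
    position: tuple  # (x, y, z) in Angstrom
    atom_indices: tuple

    def __post_init__(self):
        if self.feature_type not in FEATURE_TYPES:
            raise DomainError(f"unknown feature type {self.feature_type!r}")
        if not all(np.isfinite(self.position)):
            raise DomainError("feature position must be finite")


@dataclass
class FeaturePointSet:
    """Typed 3-D feature points perceived from one conformer."""

    molecule_id: str
    conformer_index: int
    points: list  # of FeaturePoint

    def positions(self) -> np.ndarray:
        if not self.points:
            return np.empty((0, 3))
        return np.array([p.position for p in self.points], dtype=float)

    def types(self) -> list:
        return [p.feature_type for p in self.points]


@dataclass(frozen=True)
class DescriptorRecord:
    molecule_id: str
    hbd_count: int
    hba_count: int
    rotatable_bonds: int
    ring_count: int
    tpsa: float


# ---------------------------------------------------------------------------
# library I/O
# ---------------------------------------------------------------------------

def _unique_id(base: str, seen: set) -> str:
    ident = base
    n = 1
    while ident in seen:
        n += 1
        ident = f"{base}#{n}"
    if ident != base:
        logger.warning("duplicate molecule id %r renamed to %r", base, ident)
    seen.add(ident)
    return ident


def read_library(path, fmt: str | None = None) -> list:
    """Read a molecule library from a ``.smi`` or ``.sdf`` file.

    Unparsable entries are logged and skipped; a file that contains entries
    but yields none raises :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"library file not found: {path}")
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() == ".sdf" else "smiles"
    if fmt not in ("smiles", "sdf"):
        raise FormatError(f"unknown library format {fmt!r}")

    records: list = []
    seen: set = set()
    n_entries = 0
    if fmt == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_entries += 1
            parts = line.split()
            smiles = parts[0]
            name = parts[1] if len(parts) > 1 else f"mol{lineno}"
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                logger.warning("skipping unparsable SMILES at line %d: %s", lineno, smiles)
                continue
            records.append(
                MoleculeRecord(id=_unique_id(name, seen), smiles=Chem.MolToSmiles(mol), source=str(path))
            )
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for idx, mol in enumerate(supplier):
            n_entries += 1
            if mol is None:
                logger.warning("skipping unparsable SDF record %d", idx)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"record{idx + 1}"
            rec = MoleculeRecord(id=_unique_id(name, seen), smiles=Chem.MolToSmiles(mol), source=str(path))
            if mol.GetNumConformers() > 0:
                rec._mol = mol
                rec.conformers.append(np.array(mol.GetConformer().GetPositions(), dtype=float))
            records.append(rec)

    if n_entries > 0 and not records:
        raise FormatError(f"no parsable entries in {path}")
    return records


def write_library(records: Iterable[MoleculeRecord], path, fmt: str | None = None) -> None:
    """Write records to ``.smi`` (``SMILES id`` per line) or ``.sdf``."""
    path = Path(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() == ".sdf" else "smiles"
    if fmt == "smiles":
        with path.open("w") as fh:
            for rec in records:
                fh.write(f"{rec.smiles} {rec.id}\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        for rec in records:
            mol = Chem.Mol(rec.mol())
            mol.SetProp("_Name", rec.id)
            if rec.conformers:
                conf = Chem.Conformer(mol.GetNumAtoms())
                for i, xyz in enumerate(rec.conformers[0]):
                    conf.SetAtomPosition(i, [float(v) for v in xyz])
                mol.RemoveAllConformers()
                mol.AddConformer(conf)
            writer.write(mol)
        writer.close()
    else:
        raise FormatError(f"unknown library format {fmt!r}")


def ensure_conformer(record: MoleculeRecord, seed: int = DEFAULT_EMBED_SEED) -> MoleculeRecord:
    """Generate one conformer by distance-geometry embedding if absent.

    The embedding is seeded, so repeated calls are deterministic.  The
    record is modified in place and returned.
    """
    if record.conformers:
        return record
    molh = Chem.AddHs(record.mol())
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    cid = AllChem.EmbedMolecule(molh, params)
    if cid < 0:
        raise EmbeddingError(f"conformer embedding failed for molecule {record.id!r}")
    mol = Chem.RemoveHs(molh)
    record.conformers.append(np.array(mol.GetConformer().GetPositions(), dtype=float))
    return record


# ---------------------------------------------------------------------------
# feature perception
# ---------------------------------------------------------------------------

def _match_atoms(mol: Chem.Mol, smarts_list: Sequence[str]) -> list:
    from .errors import ConfigError

    hits: set = set()
    for smarts in smarts_list:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ConfigError(f"invalid SMARTS pattern in rule table: {smarts!r}")
        for match in mol.GetSubstructMatches(patt):
            hits.add(match[0])
    return sorted(hits)


def perceive_features(
    record: MoleculeRecord,
    conformer_index: int = 0,
    rules: Mapping | None = None,
) -> FeaturePointSet:
    """Perceive typed pharmacophore feature points on one conformer.

    * ``HYD_ARO`` -- centroid of every aromatic ring;
    * ``HYD`` -- centroid of every non-aromatic carbocycle and of every
      maximal cluster of >= ``min_aliphatic_cluster`` chain carbons with no
      heteroatom neighbours;
    * ``HBA`` / ``HBD`` -- acceptor/donor heavy atoms from the SMARTS rules.
    """
    if conformer_index < 0 or conformer_index >= len(record.conformers):
        raise DomainError(
            f"molecule {record.id!r} has no conformer {conformer_index} "
            f"({len(record.conformers)} available)"
        )
    rules = dict(DEFAULT_FEATURE_RULES, **(rules or {}))
    mol = record.mol()
    coords = np.asarray(record.conformers[conformer_index], dtype=float)
    if coords.shape != (mol.GetNumAtoms(), 3):
        raise ChemistryError(
            f"conformer {conformer_index} of {record.id!r} has shape "
            f"{coords.shape}, expected ({mol.GetNumAtoms()}, 3)"
        )

    points: list = []

    ring_info = mol.GetRingInfo()
    ring_atom_ids: set = set()
    for ring in ring_info.AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        ring_atom_ids.update(ring)
        centroid = tuple(coords[list(ring)].mean(axis=0))
        if all(a.GetIsAromatic() for a in atoms):
            points.append(FeaturePoint("HYD_ARO", centroid, tuple(sorted(ring))))
        elif all(a.GetAtomicNum() == 6 for a in atoms):
            points.append(FeaturePoint("HYD", centroid, tuple(sorted(ring))))

    # maximal clusters of chain carbons in a pure-carbon environment
    eligible = set()
    for atom in mol.GetAtoms():
        if (
            atom.GetAtomicNum() == 6
            and not atom.GetIsAromatic()
            and atom.GetIdx() not in ring_atom_ids
            and all(nb.GetAtomicNum() == 6 for nb in atom.GetNeighbors())
        ):
            eligible.add(atom.GetIdx())
    seen: set = set()
    for start in sorted(eligible):
        if start in seen:
            continue
        component = {start}
        frontier = [start]
        while frontier:
            a = frontier.pop()
            for nb in mol.GetAtomWithIdx(a).GetNeighbors():
                j = nb.GetIdx()
                if j in eligible and j not in component:
                    component.add(j)
                    frontier.append(j)
        seen |= component
        if len(component) >= int(rules["min_aliphatic_cluster"]):
            idx = sorted(component)
            points.append(FeaturePoint("HYD", tuple(coords[idx].mean(axis=0)), tuple(idx)))

    for i in _match_atoms(mol, rules["hba_smarts"]):
        points.append(FeaturePoint("HBA", tuple(coords[i]), (i,)))
    for i in _match_atoms(mol, rules["hbd_smarts"]):
        points.append(FeaturePoint("HBD", tuple(coords[i]), (i,)))

    return FeaturePointSet(record.id, conformer_index, points)


def compute_descriptors(record: MoleculeRecord, rules: Mapping | None = None) -> DescriptorRecord:
    """Screening-filter descriptors; HBD/HBA counted from the feature rule
    table, remaining descriptors from standard topological definitions."""
    rules = dict(DEFAULT_FEATURE_RULES, **(rules or {}))
    try:
        mol = record.mol()
    except ChemistryError:
        raise
    return DescriptorRecord(
        molecule_id=record.id,
        hbd_count=len(_match_atoms(mol, rules["hbd_smarts"])),
        hba_count=len(_match_atoms(mol, rules["hba_smarts"])),
        rotatable_bonds=int(
            rdMolDescriptors.CalcNumRotatableBonds(
                mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
            )
        ),
        ring_count=int(rdMolDescriptors.CalcNumRings(mol)),
        tpsa=float(rdMolDescriptors.CalcTPSA(mol)),
    )


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def feature_sets_to_dataframe(feature_sets: Iterable[FeaturePointSet]):
    import pandas as pd

    rows = []
    for fs in feature_sets:
        for k, p in enumerate(fs.points):
            rows.append(
                {
                    "molecule_id": fs.molecule_id,
                    "conformer_index": fs.conformer_index,
                    "point_index": k,
                    "feature_type": p.feature_type,
                    "x": p.position[0],
                    "y": p.position[1],
                    "z": p.position[2],
                    "atom_indices": ";".join(map(str, p.atom_indices)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "molecule_id", "conformer_index", "point_index",
            "feature_type", "x", "y", "z", "atom_indices",
        ],
    )


def descriptors_to_dataframe(descriptors: Iterable[DescriptorRecord]):
    import pandas as pd

    return pd.DataFrame([vars(d) for d in descriptors])


def rules_to_yaml(rules: Mapping, path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(rules), sort_keys=False))


def rules_from_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
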