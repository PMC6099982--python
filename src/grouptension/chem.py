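"""Connectivity-level molecule model for atom-group perception.

Molecules are parsed with RDKit and snapshotted into plain dataclasses
(:class:`Atom`, :class:`Bond`, :class:`Molecule`) carrying exactly the
annotations the group-perception layer needs: element, formal charge,
hydrogen count, aromaticity, Kekulé bond orders, and two derived flags
(hybridization class and pi-system membership).

The aromaticity convention is deliberately narrower than RDKit's default:
only six-membered rings consisting solely of carbon and nitrogen retain
aromatic flags.  Five-membered heteroaromatics (thiophene, furan, pyrrole)
are kept in their Kekulé form, so e.g. the thiophene sulfur is perceived as
a divalent S with two pi-flagged carbon neighbours rather than an aromatic
centre.  Imidazolium cations receive a dedicated normalisation
(:func:`normalize_imidazolium`): the ring charge is moved from nitrogen to
the C2 carbon between the two nitrogens, the two N-C2 bonds become
aromatic, and the C4=C5 backbone stays a localised double bond.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Heavy elements the parameterisation covers (hydrogen is implicit).
ALLOWED_ELEMENTS = frozenset(
    {"B", "C", "N", "O", "P", "S", "Si", "F", "Cl", "Br", "I"}
)

SINGLE = "single"
AROMATIC = "aromatic"
DOUBLE = "double"
TRIPLE = "triple"

_RD_ORDER = {
    Chem.BondType.SINGLE: SINGLE,
    Chem.BondType.DOUBLE: DOUBLE,
    Chem.BondType.TRIPLE: TRIPLE,
    Chem.BondType.AROMATIC: AROMATIC,
}


class InputError(ValueError):
    """Unparsable input (bad SMILES, unreadable file, no usable rows)."""


class DomainError(ValueError):
    """Chemically valid input outside the model's domain (e.g. element)."""


@dataclass
class Atom:
    """One heavy atom with the annotations group perception consumes."""

    index: int
    element: str
    formal_charge: int
    n_hydrogens: int
    is_aromatic: bool
    hybridization: str = "sp3"
    in_pi_system: bool = False


@dataclass
class Bond:
    """An edge between two heavy atoms with a bond-order class."""

    a1: int
    a2: int
    order: str

    def other(self, idx: int) -> int:
        return self.a2 if idx == self.a1 else self.a1


@dataclass
class Molecule:
    """Heavy-atom graph of one compound record.

    Ionic liquids are a single record whose cation and anion are separate
    connected components; they share one record identifier and one constant
    term in the additivity equation.
    """

    identifier: str
    smiles: str
    atoms: list[Atom]
    bonds: list[Bond]
    rings: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._adjacency: list[list[Bond]] = [[] for _ in self.atoms]
        for b in self.bonds:
            self._adjacency[b.a1].append(b)
            self._adjacency[b.a2].append(b)
        self.refresh()

    # -- derived annotations -------------------------------------------------

    def refresh(self) -> None:
        """Recompute hybridization and pi-membership from bond orders."""
        for atom in self.atoms:
            orders = [b.order for b in self._adjacency[atom.index]]
            n_pi = orders.count(DOUBLE) + 2 * orders.count(TRIPLE)
            if atom.is_aromatic:
                atom.hybridization = AROMATIC
            elif n_pi >= 2:
                atom.hybridization = "sp"
            elif n_pi == 1:
                atom.hybridization = "sp2"
            else:
                atom.hybridization = "sp3"
            atom.in_pi_system = atom.is_aromatic or n_pi > 0

    def bonds_of(self, idx: int) -> list[Bond]:
        return self._adjacency[idx]

    def neighbours(self, idx: int) -> list[tuple[Atom, Bond]]:
        return [(self.atoms[b.other(idx)], b) for b in self._adjacency[idx]]

    def heavy_degree(self, idx: int) -> int:
        return len(self._adjacency[idx])

    def bond_between(self, i: int, j: int) -> Optional[Bond]:
        for b in self._adjacency[i]:
            if b.other(i) == j:
                return b
        return None

    @property
    def n_heavy_atoms(self) -> int:
        return len(self.atoms)

    @property
    def total_hydrogens(self) -> int:
        return sum(a.n_hydrogens for a in self.atoms)

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)


def _snapshot(mol: Chem.Mol, identifier: str, smiles: str) -> Molecule:
    """Freeze an RDKit molecule into the connectivity-level dataclasses."""
    ri = mol.GetRingInfo()
    # aromatic flags are kept only for 6-rings made of C/N that RDKit
    # perceives aromatic; everything else is used in Kekulé form
    aromatic_atoms: set[int] = set()
    aromatic_bonds: set[tuple[int, int]] = set()
    for ring in ri.AtomRings():
        if len(ring) != 6:
            continue
        ratoms = [mol.GetAtomWithIdx(i) for i in ring]
        if all(a.GetIsAromatic() for a in ratoms) and all(
            a.GetSymbol() in ("C", "N") for a in ratoms
        ):
            aromatic_atoms.update(ring)
            for i, j in zip(ring, ring[1:] + ring[:1]):
                aromatic_bonds.add((min(i, j), max(i, j)))

    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)

    atoms = [
        Atom(
            index=a.GetIdx(),
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            n_hydrogens=a.GetTotalNumHs(),
            is_aromatic=a.GetIdx() in aromatic_atoms,
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in kek.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if (min(i, j), max(i, j)) in aromatic_bonds:
            order = AROMATIC
        else:
            order = _RD_ORDER[b.GetBondType()]
        bonds.append(Bond(i, j, order))
    return Molecule(
        identifier=identifier,
        smiles=smiles,
        atoms=atoms,
        bonds=bonds,
        rings=[tuple(r) for r in ri.AtomRings()],
    )


def read_smiles(smiles: str, identifier: str = "") -> Molecule:
    """Parse a SMILES string into a normalised :class:`Molecule`.

    Raises
    ------
    InputError
        if the SMILES cannot be parsed.
    DomainError
        if the structure contains an element outside the supported set
        (H, B, C, N, O, P, S, Si and the halogens).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"cannot parse SMILES {smiles!r} (record {identifier!r})")
    bad = sorted(
        {a.GetSymbol() for a in mol.GetAtoms()} - ALLOWED_ELEMENTS
    )
    if bad:
        raise DomainError(
            f"record {identifier or smiles!r} contains unsupported element(s) "
            f"{', '.join(bad)}; supported: H, B, C, N, O, P, S, Si, halogens"
        )
    molecule = _snapshot(mol, identifier or smiles, smiles)
    return normalize_imidazolium(molecule)


def from_rdkit(mol: Chem.Mol, identifier: str = "") -> Molecule:
    """Ingest an already-built RDKit molecule (e.g. from an SDF record)."""
    smiles = Chem.MolToSmiles(mol)
    return read_smiles(smiles, identifier)


# -- imidazolium charge-placement rule ----------------------------------------


def _imidazolium_rings(molecule: Molecule) -> Iterable[dict]:
    """Five-membered N-C-N rings eligible for the charge-placement rule."""
    for ring in molecule.rings:
        if len(ring) != 5:
            continue
        elements = [molecule.atoms[i].element for i in ring]
        if sorted(elements) != ["C", "C", "C", "N", "N"]:
            continue
        n_idx = [i for i in ring if molecule.atoms[i].element == "N"]
        c2 = None
        for i in ring:
            if molecule.atoms[i].element != "C":
                continue
            if all(molecule.bond_between(i, n) is not None for n in n_idx):
                c2 = i
        if c2 is None:  # nitrogens adjacent (pyrazole-type): rule not applicable
            continue
        backbone = [i for i in ring if i != c2 and i not in n_idx]
        yield {"ring": ring, "n": n_idx, "c2": c2, "backbone": backbone}


def normalize_imidazolium(molecule: Molecule) -> Molecule:
    """Relocate the imidazolium ring charge onto the C2 carbon.

    For every five-membered ring with an N-C-N motif carrying a +1 on a ring
    nitrogen, the charge moves to the carbon between the two nitrogens; the
    two N-C2 bonds become aromatic (as do those three atoms) while the
    C4=C5 backbone stays a localised double bond with single bonds to the
    nitrogens.  Idempotent; a no-op for every other structure (pyridinium
    keeps its charged aromatic nitrogen, neutral imidazole is untouched).
    """
    changed = False
    for motif in _imidazolium_rings(molecule):
        n1, n3 = motif["n"]
        c2 = motif["c2"]
        c4, c5 = motif["backbone"]
        a_n1, a_n3 = molecule.atoms[n1], molecule.atoms[n3]
        a_c2 = molecule.atoms[c2]
        charged_n = a_n1.formal_charge == 1 or a_n3.formal_charge == 1
        if not (charged_n or a_c2.formal_charge == 1):
            continue
        # move the charge (no-op when already on C2)
        if charged_n:
            a_n1.formal_charge = 0
            a_n3.formal_charge = 0
            a_c2.formal_charge = 1
            changed = True
        for n in (n1, n3):
            molecule.bond_between(n, c2).order = AROMATIC
        bb = molecule.bond_between(c4, c5)
        if bb is not None:
            bb.order = DOUBLE
        for c in (c4, c5):
            for n in (n1, n3):
                b = molecule.bond_between(c, n)
                if b is not None:
                    b.order = SINGLE
            molecule.atoms[c].is_aromatic = False
        for i in (n1, n3, c2):
            molecule.atoms[i].is_aromatic = True
    del changed  # bond orders may change even when the charge already sat on C2
    molecule.refresh()
    return molecule


# -- dataset ingestion ---------------------------------------------------------


@dataclass
class DatasetRecord:
    molecule: Molecule
    st_exp: Optional[float]  # observed surface tension, dyn/cm at 293.15 K


@dataclass
class Dataset:
    records: list[DatasetRecord]
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def molecules(self) -> list[Molecule]:
        return [r.molecule for r in self.records]


def read_dataset(path: str | Path, format: Optional[str] = None) -> Dataset:
    """Read molecules (and optional observed surface tensions, dyn/cm).

    Supported formats: ``csv`` (columns ``id``, ``smiles``, optional
    ``st_exp``), ``smi`` (SMILES whitespace identifier per line) and ``sdf``
    (V2000).  Rows that fail to parse are skipped with a warning and counted
    in ``Dataset.n_skipped``; a file with no parsable rows raises
    :class:`InputError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format is None:
        format = path.suffix.lstrip(".").lower() or "smi"
    records: list[DatasetRecord] = []
    n_skipped = 0

    def _try(smiles: str, ident: str, st: Optional[float]) -> None:
        nonlocal n_skipped
        try:
            mol = read_smiles(smiles, ident)
        except (InputError, DomainError) as exc:
            logger.warning("skipping record: %s", exc)
            n_skipped += 1
            return
        records.append(DatasetRecord(mol, st))

    if format == "csv":
        import pandas as pd

        df = pd.read_csv(path)
        missing = {"id", "smiles"} - set(df.columns)
        if missing:
            raise InputError(f"{path}: missing column(s) {sorted(missing)}")
        for _, row in df.iterrows():
            st = None
            if "st_exp" in df.columns and pd.notna(row["st_exp"]):
                st = float(row["st_exp"])
            if pd.isna(row["smiles"]):
                n_skipped += 1
                continue
            _try(str(row["smiles"]), str(row["id"]), st)
    elif format == "smi":
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            _try(parts[0], parts[1].strip() if len(parts) > 1 else parts[0], None)
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, mol in enumerate(supplier):
            if mol is None:
                n_skipped += 1
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{i}"
            _try(Chem.MolToSmiles(mol), name, None)
    else:
        raise InputError(f"unknown format {format!r} (expected csv, smi or sdf)")

    if not records:
        raise InputError(f"{path}: no parsable rows")
    return Dataset(records, n_skipped)
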