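"""Atom-group perception: molecule -> canonical group counts.

Every perception centre (a heavy atom with at least one hydrogen or at
least two heavy neighbours) yields exactly one atom group, written as a
canonical text signature ``"<atom type>/<neighbours>"``:

* the atom type encodes element, formal charge and a hybridization class
  (``C sp3``, ``C(+) aromatic``, ``N(-)``, ``O``, ``S2``/``S4``,
  ``P3``/``P4``, ``Si``, ``B(-)``, ...);
* the neighbour string lists hydrogens first, then neighbour elements in a
  fixed priority order (B < C < N < O < P < S < Si < F < Cl < Br < J) with
  bond-class prefixes (none = single, ``:`` aromatic, ``=`` double,
  ``#`` triple), multiplicities as digits, a trailing ``(+)``/``(-)`` when
  any neighbour is charged, and a trailing ``(pi)``/``(2pi)`` pi-neighbour
  count for saturated N / O / divalent S centres.

Terminal hydrogen-free atoms (halogens, carbonyl/nitro oxygens, nitrile
nitrogens, thiocarbonyl sulfur, ...) are not centres; they are expressed
through the neighbour strings of the atoms bearing them.  Iodine is
rendered ``J``.

Three whole-molecule special groups complement the atom groups: ``Alkane``
and ``Unsaturated HC`` (number of carbons of a saturated / unsaturated pure
hydrocarbon) and ``(COH)n`` (surplus count of carbon-bound hydroxy groups,
n - 1 for n > 1 hydroxyls).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .chem import AROMATIC, DOUBLE, SINGLE, TRIPLE, Atom, Molecule

__all__ = [
    "AtomGroupSignature",
    "GroupCountVector",
    "perceive_atom_group",
    "perceive_special_groups",
    "decompose",
    "is_perception_centre",
    "SPECIAL_GROUPS",
]

#: neighbour element priority, German convention J for iodine
_ELEMENT_ORDER = ["B", "C", "N", "O", "P", "S", "Si", "F", "Cl", "Br", "J"]
_ELEMENT_RANK = {el: i for i, el in enumerate(_ELEMENT_ORDER)}
_BOND_RANK = {SINGLE: 0, AROMATIC: 1, DOUBLE: 2, TRIPLE: 3}
_BOND_PREFIX = {SINGLE: "", AROMATIC: ":", DOUBLE: "=", TRIPLE: "#"}

SPECIAL_GROUPS = ("(COH)n", "Alkane", "Unsaturated HC")


def _render_element(element: str) -> str:
    return "J" if element == "I" else element


def _charge_mark(charge: int) -> str:
    if charge > 0:
        return "(+)"
    if charge < 0:
        return "(-)"
    return ""


@dataclass(frozen=True)
class AtomGroupSignature:
    """Canonical ``atom type / neighbours`` key of one atom group."""

    atom_type: str
    neighbours: str

    @property
    def key(self) -> str:
        return f"{self.atom_type}/{self.neighbours}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


@dataclass
class GroupCountVector:
    """Group counts of one compound record (the A_i and B_j of the model)."""

    atom_group_counts: dict[str, int] = field(default_factory=dict)
    special_group_counts: dict[str, int] = field(default_factory=dict)
    unknown_signatures: list[str] = field(default_factory=list)

    def all_counts(self) -> dict[str, int]:
        merged = dict(self.atom_group_counts)
        merged.update(self.special_group_counts)
        return merged

    @property
    def n_atom_groups(self) -> int:
        return sum(self.atom_group_counts.values())


def is_perception_centre(atom: Atom, molecule: Molecule) -> bool:
    """A heavy atom is a centre iff it bears hydrogen or >=2 heavy bonds."""
    return atom.n_hydrogens > 0 or molecule.heavy_degree(atom.index) >= 2


def _central_atom_type(atom: Atom, molecule: Molecule) -> str:
    el = atom.element
    mark = _charge_mark(atom.formal_charge)
    if el == "C":
        return f"C{mark} {atom.hybridization}"
    if el == "N":
        if atom.formal_charge < 0:
            return "N(-)"
        return f"N{mark} {atom.hybridization}"
    if el == "O":
        return f"O{mark}"
    if el == "S":
        if mark:
            return f"S{mark}"
        valence = atom.n_hydrogens + sum(
            {SINGLE: 1, AROMATIC: 1, DOUBLE: 2, TRIPLE: 3}[b.order]
            for b in molecule.bonds_of(atom.index)
        )
        return "S2" if valence <= 2 else "S4"
    if el == "P":
        if mark:
            return f"P{mark}"
        sigma = atom.n_hydrogens + molecule.heavy_degree(atom.index)
        return f"P{sigma}"
    # Si, B and (never in practice) other elements carry no class digit
    return f"{_render_element(el)}{mark}"


def _pi_suffix(atom: Atom, molecule: Molecule) -> str:
    """Pi-neighbour marker for saturated N, ether/hydroxy O, divalent S."""
    el = atom.element
    if el == "N":
        if atom.hybridization != "sp3" or atom.formal_charge < 0:
            return ""
    elif el == "O":
        if atom.formal_charge != 0:
            return ""
    elif el == "S":
        if atom.formal_charge != 0 or _central_atom_type(atom, molecule) != "S2":
            return ""
    else:
        return ""
    n_pi = sum(
        1
        for nb, bond in molecule.neighbours(atom.index)
        if bond.order == SINGLE and nb.element in ("C", "N") and nb.in_pi_system
    )
    if n_pi == 0:
        return ""
    return "(pi)" if n_pi == 1 else f"({n_pi}pi)"


def _neighbour_string(atom: Atom, molecule: Molecule) -> str:
    groups: Counter[tuple[str, str]] = Counter()
    signs: set[int] = set()
    for nb, bond in molecule.neighbours(atom.index):
        groups[(_render_element(nb.element), bond.order)] += 1
        if nb.formal_charge:
            signs.add(1 if nb.formal_charge > 0 else -1)
    parts: list[str] = []
    if atom.n_hydrogens:
        parts.append("H" + (str(atom.n_hydrogens) if atom.n_hydrogens > 1 else ""))
    for (el, order), count in sorted(
        groups.items(), key=lambda kv: (_ELEMENT_RANK[kv[0][0]], _BOND_RANK[kv[0][1]])
    ):
        parts.append(_BOND_PREFIX[order] + el + (str(count) if count > 1 else ""))
    body = "".join(parts)
    # one trailing sign mark per charge sign present among the neighbours
    if 1 in signs:
        body += "(+)"
    if -1 in signs:
        body += "(-)"
    return body + _pi_suffix(atom, molecule)


def perceive_atom_group(atom: Atom, molecule: Molecule) -> AtomGroupSignature:
    """Canonical signature of one perception centre.

    The molecule must already be normalised (imidazolium charge placement
    applied); :func:`grouptension.chem.read_smiles` does this on ingestion.
    """
    if atom.element == "H":
        raise ValueError("hydrogen atoms are never perception centres")
    return AtomGroupSignature(
        _central_atom_type(atom, molecule), _neighbour_string(atom, molecule)
    )


def perceive_special_groups(molecule: Molecule) -> dict[str, int]:
    """Whole-molecule correction groups: Alkane, Unsaturated HC, (COH)n."""
    specials: dict[str, int] = {}
    elements = {a.element for a in molecule.atoms}
    if elements == {"C"}:
        n_carbon = molecule.n_heavy_atoms
        unsaturated = any(b.order != SINGLE for b in molecule.bonds)
        specials["Unsaturated HC" if unsaturated else "Alkane"] = n_carbon
        return specials
    n_coh = sum(
        1
        for a in molecule.atoms
        if a.element == "O"
        and a.formal_charge == 0
        and a.n_hydrogens >= 1
        and molecule.heavy_degree(a.index) == 1
        and molecule.neighbours(a.index)[0][0].element == "C"
    )
    if n_coh > 1:
        specials["(COH)n"] = n_coh - 1
    return specials


def decompose(
    molecule: Molecule, table: Optional["ParameterTable"] = None
) -> GroupCountVector:
    """Break a molecule down into its group-count vector.

    Parameters
    ----------
    molecule
        A normalised molecule record (ionic liquids: both components).
    table
        The parameter table used to flag unknown signatures.  Defaults to
        the published table; pass an empty/new table when building design
        matrices for refitting.
    """
    if table is None:
        from .params import load_published_table

        table = load_published_table()
    counts: Counter[str] = Counter()
    for atom in molecule.atoms:
        if is_perception_centre(atom, molecule):
            counts[perceive_atom_group(atom, molecule).key] += 1
    specials = perceive_special_groups(molecule)
    unknown = sorted(sig for sig in counts if table.lookup(sig) is None)
    return GroupCountVector(
        atom_group_counts=dict(counts),
        special_group_counts=specials,
        unknown_signatures=unknown,
    )
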