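"""Two-partner protein complex model and sidechain contact geometry.

A complex is read from PDB text into a light-weight residue/atom
representation with an explicit split of its chains into two binding
partners A and B. Contacts are defined on sidechain heavy atoms: two
residues from opposite partners are in contact when the minimum distance
between any of their sidechain atoms is strictly below a cutoff. Glycine
uses its CA atom as a sidechain surrogate so it can participate in
interfaces like every other residue type.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .constants import BACKBONE_ATOMS, RESIDUE_ALIASES, THREE_TO_ONE
from .errors import ChainNotFoundError, EmptyPartnerError

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueView",
    "ComplexStructure",
    "ContactMap",
    "parse_complex",
    "detect_contacts",
]


@dataclass(frozen=True)
class AtomRecord:
    """A single heavy atom with the fields contact/SAS geometry needs."""

    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class ResidueView:
    """One standard amino-acid residue with its retained heavy atoms."""

    chain_id: str
    seq_number: int
    insertion_code: str
    aa_type: str  # one-letter code
    atoms: tuple[AtomRecord, ...]

    def __post_init__(self) -> None:
        if self.aa_type not in THREE_TO_ONE.values():
            raise ValueError(f"not a standard amino acid: {self.aa_type!r}")

    @property
    def sidechain_atoms(self) -> tuple[AtomRecord, ...]:
        """Heavy sidechain atoms; for glycine the CA surrogate."""
        side = tuple(a for a in self.atoms if a.name not in BACKBONE_ATOMS)
        if not side and self.aa_type == "G":
            side = tuple(a for a in self.atoms if a.name == "CA")
        return side

    @property
    def key(self) -> tuple[str, int, str]:
        """Stable identifier (chain, number, insertion code)."""
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ComplexStructure:
    """A parsed complex whose chains are partitioned into partners A and B."""

    complex_id: str
    partner_A: frozenset[str]
    partner_B: frozenset[str]
    residues: tuple[ResidueView, ...]

    def __post_init__(self) -> None:
        self.partner_A = frozenset(self.partner_A)
        self.partner_B = frozenset(self.partner_B)
        if not self.partner_A or not self.partner_B:
            raise EmptyPartnerError(f"{self.complex_id}: both partners need >= 1 chain")
        if self.partner_A & self.partner_B:
            raise ValueError(f"{self.complex_id}: partners share chains")
        for res in self.residues:
            if res.chain_id not in self.partner_A | self.partner_B:
                raise ValueError(
                    f"{self.complex_id}: residue chain {res.chain_id!r} is in no partner"
                )

    def partner_of(self, residue: ResidueView) -> str:
        return "A" if residue.chain_id in self.partner_A else "B"

    def partner_residues(self, partner: str) -> tuple[ResidueView, ...]:
        chains = self.partner_A if partner == "A" else self.partner_B
        return tuple(r for r in self.residues if r.chain_id in chains)

    def swapped(self) -> "ComplexStructure":
        """The same complex with partner labels exchanged."""
        return ComplexStructure(
            self.complex_id, self.partner_B, self.partner_A, self.residues
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexStructure":
        """Rigid-body copy: x -> R x + t applied to every atom."""
        rot = np.asarray(rotation, float)
        tr = np.asarray(translation, float)
        new_res = tuple(
            ResidueView(
                r.chain_id,
                r.seq_number,
                r.insertion_code,
                r.aa_type,
                tuple(
                    AtomRecord(a.name, a.element, rot @ a.position + tr, a.occupancy, a.altloc)
                    for a in r.atoms
                ),
            )
            for r in self.residues
        )
        return ComplexStructure(self.complex_id, self.partner_A, self.partner_B, new_res)


@dataclass(frozen=True)
class ContactMap:
    """Cross-partner residue pairs below a sidechain-distance cutoff."""

    cutoff: float
    pairs: frozenset[frozenset[tuple[str, int, str]]]
    interfacial_residues: frozenset[tuple[str, int, str]] = field(init=False)

    def __post_init__(self) -> None:
        members: set[tuple[str, int, str]] = set()
        for pair in self.pairs:
            members.update(pair)
        object.__setattr__(self, "interfacial_residues", frozenset(members))

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_keys(self) -> Iterator[tuple[tuple[str, int, str], tuple[str, int, str]]]:
        for pair in self.pairs:
            a, b = sorted(pair)
            yield a, b


def _pick_altloc(bio_atom) -> "tuple[str, str, np.ndarray, float, str | None] | None":
    """Resolve a (possibly disordered) Biopython atom to one conformer."""
    if bio_atom.is_disordered():
        best = max(
            bio_atom.disordered_get_list(),
            key=lambda a: (a.get_occupancy() or 0.0, -ord(a.get_altloc() or " ")),
        )
    else:
        best = bio_atom
    element = (best.element or "").strip().upper()
    if element == "H" or element == "D":
        return None
    altloc = best.get_altloc().strip() or None
    return (
        best.get_name().strip(),
        element,
        np.asarray(best.get_coord(), dtype=float),
        float(best.get_occupancy() if best.get_occupancy() is not None else 1.0),
        altloc,
    )


def parse_complex(
    pdb_source: str | TextIO,
    partner_A: Iterable[str],
    partner_B: Iterable[str],
    complex_id: str = "complex",
) -> ComplexStructure:
    """Parse PDB text into a :class:`ComplexStructure`.

    Only the 20 standard amino acids are kept (selenomethionine is mapped
    to methionine); heteroatoms, waters and other non-standard residues
    are dropped with a warning. For atoms with alternate locations the
    highest-occupancy conformer is retained. Hydrogens are ignored.

    Parameters
    ----------
    pdb_source:
        PDB text or an open text stream.
    partner_A, partner_B:
        Chain identifiers of the two binding partners.
    """
    chains_a = frozenset(str(c) for c in partner_A)
    chains_b = frozenset(str(c) for c in partner_B)
    handle = io.StringIO(pdb_source) if isinstance(pdb_source, str) else pdb_source
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = next(parser.get_structure(complex_id, handle).get_models())

    present = {chain.id for chain in model}
    for cid in sorted((chains_a | chains_b) - present):
        raise ChainNotFoundError(f"{complex_id}: chain {cid!r} not in structure")

    residues: list[ResidueView] = []
    for chain in model:
        if chain.id not in chains_a | chains_b:
            continue
        for res in chain:
            hetflag, seq_number, icode = res.get_id()
            resname = res.get_resname().strip().upper()
            resname = RESIDUE_ALIASES.get(resname, resname)
            if resname not in THREE_TO_ONE:
                if resname != "HOH":
                    logger.warning(
                        "%s: dropping non-standard residue %s %s%s",
                        complex_id, resname, chain.id, seq_number,
                    )
                continue
            atoms = []
            for bio_atom in res:
                picked = _pick_altloc(bio_atom)
                if picked is None:
                    continue
                name, element, pos, occ, altloc = picked
                atoms.append(AtomRecord(name, element, pos, occ, altloc))
            if not atoms:
                continue
            residues.append(
                ResidueView(
                    chain_id=chain.id,
                    seq_number=seq_number,
                    insertion_code=icode.strip(),
                    aa_type=THREE_TO_ONE[resname],
                    atoms=tuple(atoms),
                )
            )

    for name, chains in (("A", chains_a), ("B", chains_b)):
        if not any(r.chain_id in chains for r in residues):
            raise EmptyPartnerError(f"{complex_id}: partner {name} has no standard residues")
    return ComplexStructure(complex_id, chains_a, chains_b, tuple(residues))


def _sidechain_coordinates(
    residues: Sequence[ResidueView],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack sidechain-atom coordinates with a per-atom residue index.

    Residues with no resolved sidechain atoms (and no CA surrogate) are
    skipped with a warning; they cannot take part in contacts.
    """
    coords: list[np.ndarray] = []
    owner: list[int] = []
    for idx, res in enumerate(residues):
        side = res.sidechain_atoms
        if not side:
            logger.warning(
                "residue %s%s has no resolved sidechain atoms; excluded from contacts",
                res.chain_id, res.seq_number,
            )
            continue
        for atom in side:
            coords.append(atom.position)
            owner.append(idx)
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.asarray(coords), np.asarray(owner, dtype=int)


def detect_contacts(complex_structure: ComplexStructure, cutoff: float) -> ContactMap:
    """Find all cross-partner residue pairs with sidechain atoms closer
    than ``cutoff`` (strict inequality).

    The result is symmetric in partner order and deterministic; an empty
    interface is a valid outcome.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res_a = complex_structure.partner_residues("A")
    res_b = complex_structure.partner_residues("B")
    xyz_a, own_a = _sidechain_coordinates(res_a)
    xyz_b, own_b = _sidechain_coordinates(res_b)
    pairs: set[frozenset[tuple[str, int, str]]] = set()
    if len(xyz_a) and len(xyz_b):
        tree_b = cKDTree(xyz_b)
        # query_ball_point with strict post-filter: KD-tree returns <= r.
        for i, neighbours in enumerate(cKDTree(xyz_a).query_ball_tree(tree_b, cutoff)):
            if not neighbours:
                continue
            a_res = res_a[own_a[i]]
            pos_a = xyz_a[i]
            for j in neighbours:
                if float(np.linalg.norm(pos_a - xyz_b[j])) < cutoff:
                    pairs.add(frozenset({a_res.key, res_b[own_b[j]].key}))
    return ContactMap(cutoff=cutoff, pairs=frozenset(pairs))
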