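"""Knowledge-based interfacial pair potential.

Energies are log-odds of observed versus composition-expected contact
frequencies over a library of two-partner complexes:

    u(i, j) = -kT * ln( N_obs(i, j) / (chi_i * chi_j * N_obs) )

where N_obs(i, j) counts cross-partner sidechain contacts between residue
types i and j (5.5 A rule) pooled over the library, N_obs is the pooled
total, and chi_i is the mole fraction of type i among interfacial
residues. A pseudocount keeps unobserved-but-possible pairs finite; pairs
involving a residue type never seen at any interface are flagged
unobserved and score zero.

The binding energy of a complex is the sum of u over its contact pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Sequence, TextIO

import math

from .constants import AMINO_ACIDS, POTENTIAL_CONTACT_CUTOFF
from .errors import PPAffinityError
from .structure import ComplexStructure, ContactMap, detect_contacts

__all__ = ["PotentialTable", "build_potential", "score_complex"]

PairKey = tuple[str, str]


def _pair(a: str, b: str) -> PairKey:
    return (a, b) if a <= b else (b, a)


@dataclass
class PotentialTable:
    """Contact counts, interface composition and pair energies (kT units)."""

    pair_counts: dict[PairKey, int]
    total_pairs: int
    mole_fractions: dict[str, float]
    energies: dict[PairKey, float]
    unobserved: frozenset[PairKey]
    kT: float = 1.0
    cutoff: float = POTENTIAL_CONTACT_CUTOFF
    pseudocount: float = 0.5
    library_size: int = 0

    def energy(self, aa_a: str, aa_b: str) -> float:
        return self.energies.get(_pair(aa_a, aa_b), 0.0)

    def to_tsv(self, stream: TextIO) -> None:
        stream.write(f"# kT\t{float(self.kT)!r}\n")
        stream.write(f"# cutoff\t{float(self.cutoff)!r}\n")
        stream.write(f"# pseudocount\t{float(self.pseudocount)!r}\n")
        stream.write(f"# library_size\t{self.library_size}\n")
        stream.write(f"# total_pairs\t{self.total_pairs}\n")
        for aa in AMINO_ACIDS:
            stream.write(f"chi\t{aa}\t{float(self.mole_fractions.get(aa, 0.0))!r}\n")
        for a, b in sorted(self.energies):
            flag = "unobserved" if (a, b) in self.unobserved else "ok"
            stream.write(
                f"pair\t{a}\t{b}\t{self.pair_counts.get((a, b), 0)}\t"
                f"{float(self.energies[(a, b)])!r}\t{flag}\n"
            )

    @classmethod
    def from_tsv(cls, stream: TextIO) -> "PotentialTable":
        meta: dict[str, str] = {}
        chi: dict[str, float] = {}
        counts: dict[PairKey, int] = {}
        energies: dict[PairKey, float] = {}
        unobserved: set[PairKey] = set()
        for line in stream:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, value = line[1:].split("\t")
                meta[key.strip()] = value
                continue
            fields = line.split("\t")
            if fields[0] == "chi":
                chi[fields[1]] = float(fields[2])
            elif fields[0] == "pair":
                key = (fields[1], fields[2])
                if int(fields[3]) > 0:
                    counts[key] = int(fields[3])
                energies[key] = float(fields[4])
                if fields[5] == "unobserved":
                    unobserved.add(key)
        return cls(
            pair_counts=counts,
            total_pairs=int(meta["total_pairs"]),
            mole_fractions=chi,
            energies=energies,
            unobserved=frozenset(unobserved),
            kT=float(meta["kT"]),
            cutoff=float(meta["cutoff"]),
            pseudocount=float(meta["pseudocount"]),
            library_size=int(meta["library_size"]),
        )


def _count_interface(
    complex_structure: ComplexStructure, cutoff: float
) -> tuple[dict[PairKey, int], dict[str, int], int]:
    """Pair counts, per-type interfacial-residue counts and total pairs."""
    contacts = detect_contacts(complex_structure, cutoff)
    residues = {res.key: res for res in complex_structure.residues}
    pair_counts: dict[PairKey, int] = {}
    for key_a, key_b in contacts.pair_keys():
        pk = _pair(residues[key_a].aa_type, residues[key_b].aa_type)
        pair_counts[pk] = pair_counts.get(pk, 0) + 1
    type_counts: dict[str, int] = {}
    for key in contacts.interfacial_residues:
        aa = residues[key].aa_type
        type_counts[aa] = type_counts.get(aa, 0) + 1
    return pair_counts, type_counts, len(contacts)


def build_potential(
    library: Sequence[ComplexStructure] | Iterable[ComplexStructure],
    cutoff: float = POTENTIAL_CONTACT_CUTOFF,
    pseudocount: float = 0.5,
    kT: float = 1.0,
) -> PotentialTable:
    """Pool contact statistics over a structure library into a potential.

    chi_i counts each interfacial residue once (a residue-count mole
    fraction, not a pair-participation fraction). With pseudocount c and
    P the number of pair categories formed by the observed types,

        u(i,j) = -kT * ln( (N(i,j)+c) / (chi_i chi_j (N + c*P)) ).
    """
    library = list(library)
    if not library:
        raise PPAffinityError("empty structure library")

    pair_counts: dict[PairKey, int] = {}
    type_counts: dict[str, int] = {}
    total = 0
    for cplx in library:
        pc, tc, n = _count_interface(cplx, cutoff)
        total += n
        for key, count in pc.items():
            pair_counts[key] = pair_counts.get(key, 0) + count
        for aa, count in tc.items():
            type_counts[aa] = type_counts.get(aa, 0) + count

    if total == 0:
        raise PPAffinityError("structure library contains no interfaces")

    n_interfacial = sum(type_counts.values())
    chi = {aa: type_counts.get(aa, 0) / n_interfacial for aa in AMINO_ACIDS}

    observed_types = sorted(aa for aa in AMINO_ACIDS if chi[aa] > 0)
    smoothed_pairs = list(combinations_with_replacement(observed_types, 2))
    denominator_total = total + pseudocount * len(smoothed_pairs)

    energies: dict[PairKey, float] = {}
    unobserved: set[PairKey] = set()
    for a, b in combinations_with_replacement(AMINO_ACIDS, 2):
        key = _pair(a, b)
        if chi[a] == 0.0 or chi[b] == 0.0:
            energies[key] = 0.0
            unobserved.add(key)
            continue
        numerator = pair_counts.get(key, 0) + pseudocount
        if numerator == 0:  # pseudocount 0 and never observed
            energies[key] = 0.0
            unobserved.add(key)
            continue
        energies[key] = -kT * math.log(numerator / (chi[a] * chi[b] * denominator_total))

    return PotentialTable(
        pair_counts=pair_counts,
        total_pairs=total,
        mole_fractions=chi,
        energies=energies,
        unobserved=frozenset(unobserved),
        kT=kT,
        cutoff=cutoff,
        pseudocount=pseudocount,
        library_size=len(library),
    )


def score_complex(
    complex_structure: ComplexStructure,
    table: PotentialTable,
    cutoff: float | None = None,
    contacts: ContactMap | None = None,
) -> float:
    """Sum of pair energies over the complex's interface contacts (kT units).

    An empty interface scores 0. ``cutoff`` defaults to the cutoff the
    table was built with.
    """
    if cutoff is None:
        cutoff = table.cutoff
    if contacts is None:
        contacts = detect_contacts(complex_structure, cutoff)
    residues = {res.key: res for res in complex_structure.residues}
    return sum(
        table.energy(residues[a].aa_type, residues[b].aa_type)
        for a, b in contacts.pair_keys()
    )

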