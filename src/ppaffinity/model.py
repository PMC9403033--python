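"""Environment-decomposed binding-affinity model.

The binding free energy of a two-partner complex is written as a weighted
sum over two kinds of counts:

* **interfacial**: one count per cross-partner residue contact (5 A
  sidechain rule), categorised by the unordered pair of (amino acid,
  secondary structure) classes of its two members — 60 combined classes,
  hence 60·61/2 = 1830 unordered pair categories;
* **non-interfacial**: one count per residue outside the interface,
  categorised by (amino acid, secondary structure, buried/exposed) —
  20·3·2 = 120 categories — and scaled by a single factor ``w_n`` that
  balances non-interfacial against interfacial contributions.

ΔG_calc = Σ_cat n_itf(cat)·W_itf(cat) + w_n · Σ_cat n_nitf(cat)·W_nitf(cat)

Weights live in [−1, 1]; the model's output is on an arbitrary linear
scale until the cross-validation driver rescales predictions onto
experimental units (see :mod:`ppaffinity.refine`).

Mutations are *threaded*: residue identities are relabelled on unchanged
wild-type geometry, so contact geometry and secondary structure carry
over and only category assignments move.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence, TextIO

import numpy as np

from .constants import AA_INDEX, AMINO_ACIDS, GAS_CONSTANT_KCAL, INTERFACE_CONTACT_CUTOFF
from .environment import SS_STATES, SASProfile, classify_exposure, relative_sas
from .errors import MutationMismatchError, PPAffinityError
from .structure import ComplexStructure, ContactMap, ResidueView, detect_contacts

__all__ = [
    "N_COMBINED_CLASSES",
    "N_INTERFACIAL_CATEGORIES",
    "N_NONINTERFACIAL_CATEGORIES",
    "N_WEIGHTS",
    "combined_class",
    "interfacial_index",
    "noninterfacial_index",
    "FeatureVector",
    "WeightVector",
    "Mutation",
    "parse_mutation",
    "extract_features",
    "thread_mutations",
    "predict_affinity",
    "kd_to_dg",
]

SS_INDEX = {s: i for i, s in enumerate(SS_STATES)}
EXPOSURE_INDEX = {"B": 0, "E": 1}

N_COMBINED_CLASSES = 20 * 3  # (amino acid, secondary structure)
N_INTERFACIAL_CATEGORIES = N_COMBINED_CLASSES * (N_COMBINED_CLASSES + 1) // 2
N_NONINTERFACIAL_CATEGORIES = 20 * 3 * 2
N_WEIGHTS = N_INTERFACIAL_CATEGORIES + N_NONINTERFACIAL_CATEGORIES


def combined_class(aa: str, ss: str) -> int:
    """Flat index of the (amino acid, secondary structure) class, 0..59."""
    return AA_INDEX[aa] * 3 + SS_INDEX[ss]


def interfacial_index(class_a: int, class_b: int) -> int:
    """Triangular index of an unordered pair of combined classes, 0..1829."""
    i, j = (class_a, class_b) if class_a <= class_b else (class_b, class_a)
    return i * N_COMBINED_CLASSES - i * (i + 1) // 2 + j


def interfacial_pair_from_index(idx: int) -> tuple[int, int]:
    """Inverse of :func:`interfacial_index`."""
    i = 0
    offset = 0
    while offset + (N_COMBINED_CLASSES - i) <= idx:
        offset += N_COMBINED_CLASSES - i
        i += 1
    return i, i + (idx - offset)


def noninterfacial_index(aa: str, ss: str, exposure: str) -> int:
    """Flat index of the (amino acid, secondary structure, B/E) class, 0..119."""
    return AA_INDEX[aa] * 6 + SS_INDEX[ss] * 2 + EXPOSURE_INDEX[exposure]


def describe_interfacial(idx: int) -> str:
    a, b = interfacial_pair_from_index(idx)
    return "{}/{}-{}/{}".format(
        AMINO_ACIDS[a // 3], SS_STATES[a % 3], AMINO_ACIDS[b // 3], SS_STATES[b % 3]
    )


def describe_noninterfacial(idx: int) -> str:
    return "{}/{}/{}".format(
        AMINO_ACIDS[idx // 6], SS_STATES[(idx % 6) // 2], "BE"[idx % 2]
    )


@dataclass
class FeatureVector:
    """Sparse per-complex category counts — the model's sufficient statistic."""

    complex_id: str
    interfacial: dict[int, int] = field(default_factory=dict)
    noninterfacial: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping, bound in (
            (self.interfacial, N_INTERFACIAL_CATEGORIES),
            (self.noninterfacial, N_NONINTERFACIAL_CATEGORIES),
        ):
            for key, count in mapping.items():
                if not (0 <= key < bound) or count < 0 or count != int(count):
                    raise ValueError(f"bad feature entry {key}: {count}")

    @property
    def n_contacts(self) -> int:
        return sum(self.interfacial.values())

    @property
    def n_noninterfacial(self) -> int:
        return sum(self.noninterfacial.values())

    def to_tsv(self, stream: TextIO) -> None:
        stream.write(f"# complex_id\t{self.complex_id}\n")
        for idx in sorted(self.interfacial):
            stream.write(f"itf\t{idx}\t{self.interfacial[idx]}\n")
        for idx in sorted(self.noninterfacial):
            stream.write(f"nitf\t{idx}\t{self.noninterfacial[idx]}\n")

    @classmethod
    def from_tsv(cls, stream: TextIO) -> "FeatureVector":
        complex_id = "complex"
        itf: dict[int, int] = {}
        nitf: dict[int, int] = {}
        for line in stream:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts and parts[0].strip() == "complex_id":
                    complex_id = parts[1].strip()
                continue
            kind, idx, count = line.split("\t")
            (itf if kind == "itf" else nitf)[int(idx)] = int(count)
        return cls(complex_id, itf, nitf)


@dataclass
class WeightVector:
    """Bounded weights for all 1830 + 120 categories plus the scalar w_n."""

    w_itf: np.ndarray
    w_nitf: np.ndarray
    w_n: float

    def __post_init__(self) -> None:
        self.w_itf = np.asarray(self.w_itf, dtype=float)
        self.w_nitf = np.asarray(self.w_nitf, dtype=float)
        if self.w_itf.shape != (N_INTERFACIAL_CATEGORIES,):
            raise ValueError("w_itf must have 1830 entries")
        if self.w_nitf.shape != (N_NONINTERFACIAL_CATEGORIES,):
            raise ValueError("w_nitf must have 120 entries")
        if np.any(np.abs(self.w_itf) > 1) or np.any(np.abs(self.w_nitf) > 1):
            raise ValueError("category weights must lie in [-1, 1]")
        if not (0.0 <= self.w_n <= 1.0):
            raise ValueError("w_n must lie in [0, 1]")

    @classmethod
    def zeros(cls, w_n: float = 0.7) -> "WeightVector":
        return cls(np.zeros(N_INTERFACIAL_CATEGORIES), np.zeros(N_NONINTERFACIAL_CATEGORIES), w_n)

    @classmethod
    def random(cls, rng: np.random.Generator, w_n: float = 0.7) -> "WeightVector":
        return cls(
            rng.uniform(-1, 1, N_INTERFACIAL_CATEGORIES),
            rng.uniform(-1, 1, N_NONINTERFACIAL_CATEGORIES),
            w_n,
        )

    def as_flat(self) -> np.ndarray:
        return np.concatenate([self.w_itf, self.w_nitf])

    def to_tsv(self, stream: TextIO) -> None:
        stream.write(f"# w_n\t{float(self.w_n)!r}\n")
        for idx, value in enumerate(self.w_itf):
            stream.write(f"itf\t{idx}\t{describe_interfacial(idx)}\t{float(value)!r}\n")
        for idx, value in enumerate(self.w_nitf):
            stream.write(f"nitf\t{idx}\t{describe_noninterfacial(idx)}\t{float(value)!r}\n")

    @classmethod
    def from_tsv(cls, stream: TextIO) -> "WeightVector":
        w_n = 0.7
        w_itf = np.zeros(N_INTERFACIAL_CATEGORIES)
        w_nitf = np.zeros(N_NONINTERFACIAL_CATEGORIES)
        for line in stream:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts and parts[0].strip() == "w_n":
                    w_n = float(parts[1])
                continue
            kind, idx, _label, value = line.split("\t")
            (w_itf if kind == "itf" else w_nitf)[int(idx)] = float(value)
        return cls(w_itf, w_nitf, w_n)


@dataclass(frozen=True)
class Mutation:
    """A point substitution at one residue position."""

    chain_id: str
    seq_number: int
    wild_aa: str
    mutant_aa: str
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.wild_aa == self.mutant_aa:
            raise ValueError("wild-type and mutant amino acid are identical")
        for aa in (self.wild_aa, self.mutant_aa):
            if aa not in AA_INDEX:
                raise ValueError(f"not a standard amino acid: {aa!r}")

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def __str__(self) -> str:
        return f"{self.chain_id}{self.wild_aa}{self.seq_number}{self.insertion_code}{self.mutant_aa}"


_MUTATION_RE = re.compile(
    r"^(?P<chain>[A-Za-z0-9])(?P<wt>[A-Z])(?P<num>-?\d+)(?P<icode>[A-Za-z]?)(?P<mut>[A-Z])$"
)


def parse_mutation(text: str) -> Mutation:
    """Parse ``<chain><wild><number>[icode]<mutant>`` notation, e.g. ``AL33G``."""
    m = _MUTATION_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse mutation {text!r}")
    return Mutation(
        chain_id=m.group("chain"),
        seq_number=int(m.group("num")),
        wild_aa=m.group("wt"),
        mutant_aa=m.group("mut"),
        insertion_code=m.group("icode"),
    )


def thread_mutations(
    complex_structure: ComplexStructure, mutations: Sequence[Mutation]
) -> ComplexStructure:
    """Relabel residue identities on unchanged wild-type geometry.

    The mutated residues keep their wild-type atoms (so contact distances
    and secondary structure are untouched); only the amino-acid type used
    in category assignment changes. An empty mutation list returns an
    identical structure.
    """
    by_site = {}
    for mut in mutations:
        if mut.site in by_site:
            raise ValueError(f"duplicate mutation site {mut.site}")
        by_site[mut.site] = mut
    new_residues = []
    seen = set()
    for res in complex_structure.residues:
        mut = by_site.get(res.key)
        if mut is None:
            new_residues.append(res)
            continue
        if res.aa_type != mut.wild_aa:
            raise MutationMismatchError(
                f"{complex_structure.complex_id} site {res.key}: structure has "
                f"{res.aa_type}, mutation expects {mut.wild_aa}"
            )
        seen.add(res.key)
        new_residues.append(
            ResidueView(res.chain_id, res.seq_number, res.insertion_code,
                        mut.mutant_aa, res.atoms)
        )
    missing = set(by_site) - seen
    if missing:
        raise MutationMismatchError(f"mutation sites absent from structure: {sorted(missing)}")
    return ComplexStructure(
        complex_structure.complex_id,
        complex_structure.partner_A,
        complex_structure.partner_B,
        tuple(new_residues),
    )


def extract_features(
    complex_structure: ComplexStructure,
    ss: Mapping[tuple[str, int, str], str],
    sas: Mapping[tuple[str, int, str], SASProfile],
    cutoff: float = INTERFACE_CONTACT_CUTOFF,
    contacts: ContactMap | None = None,
) -> FeatureVector:
    """Count the model's interfacial and non-interfacial categories.

    ``ss`` and ``sas`` must cover every residue of the complex.
    ``contacts`` may be supplied to reuse a precomputed contact map
    (it must have been computed at the same cutoff).
    """
    residues = {res.key: res for res in complex_structure.residues}
    for key in residues:
        if key not in ss:
            raise PPAffinityError(f"residue {key} missing from the secondary-structure map")
        if key not in sas:
            raise PPAffinityError(f"residue {key} missing from the accessibility map")

    if contacts is None:
        contacts = detect_contacts(complex_structure, cutoff)
    elif contacts.cutoff != cutoff:
        raise ValueError("supplied contact map was computed at a different cutoff")

    itf: dict[int, int] = {}
    for key_a, key_b in contacts.pair_keys():
        ca = combined_class(residues[key_a].aa_type, ss[key_a])
        cb = combined_class(residues[key_b].aa_type, ss[key_b])
        idx = interfacial_index(ca, cb)
        itf[idx] = itf.get(idx, 0) + 1

    nitf: dict[int, int] = {}
    for key, res in residues.items():
        if key in contacts.interfacial_residues:
            continue
        # exposure re-derived from the (possibly relabelled) residue type:
        # threaded mutants keep wild-type geometry but normalise by the
        # mutant's reference area.
        rel = relative_sas(res.aa_type, sas[key].sas_complex)
        idx = noninterfacial_index(res.aa_type, ss[key], classify_exposure(rel))
        nitf[idx] = nitf.get(idx, 0) + 1

    return FeatureVector(complex_structure.complex_id, itf, nitf)


def predict_affinity(features: FeatureVector, weights: WeightVector) -> float:
    """ΔG_calc = interfacial term + w_n · non-interfacial term (model units)."""
    total = 0.0
    for idx, count in features.interfacial.items():
        total += count * weights.w_itf[idx]
    nitf = 0.0
    for idx, count in features.noninterfacial.items():
        nitf += count * weights.w_nitf[idx]
    return total + weights.w_n * nitf


def kd_to_dg(kd: float, temperature: float = 298.0) -> float:
    """Binding free energy ΔG = R·T·ln(Kd) in kcal/mol (Kd in mol/L)."""
    if kd <= 0:
        raise ValueError("dissociation constant must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)
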