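"""Affinity datasets: grouped wild-type/mutant records with features.

An :class:`AffinityDataset` holds one record per measured complex —
families group a wild-type complex with its mutants — together with the
feature vectors the affinity model needs. A :class:`ComplexFeaturizer`
computes the expensive geometry (contacts, secondary structure, solvent
accessibility) once per wild-type structure and emits feature vectors
for any threaded mutant cheaply, since threading changes residue labels
but not coordinates.

A SKEMPI-style CSV reader turns tabular affinity data (complex id,
partner chains, mutation list, wild-type and mutant dissociation
constants) into such a dataset given the wild-type PDB structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .constants import INTERFACE_CONTACT_CUTOFF
from .environment import (
    SASProfile,
    assign_secondary_structure,
    classify_region,
    residue_area_components,
)
from .errors import PPAffinityError
from .model import (
    FeatureVector,
    Mutation,
    N_INTERFACIAL_CATEGORIES,
    N_NONINTERFACIAL_CATEGORIES,
    extract_features,
    kd_to_dg,
    parse_mutation,
    thread_mutations,
)
from .structure import ComplexStructure, detect_contacts, parse_complex

__all__ = [
    "AffinityRecord",
    "AffinityDataset",
    "ComplexFeaturizer",
    "read_skempi_table",
    "load_skempi_dataset",
    "design_matrices",
]

ResKey = tuple[str, int, str]


@dataclass
class AffinityRecord:
    """One measured complex: a wild type or a threaded mutant."""

    complex_id: str
    family_id: str
    mutations: tuple[Mutation, ...]
    features: FeatureVector
    dg_exp: float
    dg_calc: float | None = None
    mutation_region: str | None = None  # region of the mutated site (single mutants)

    @property
    def is_wildtype(self) -> bool:
        return len(self.mutations) == 0


@dataclass
class AffinityDataset:
    """Records partitioned into families, each with exactly one wild type."""

    records: list[AffinityRecord]

    def __post_init__(self) -> None:
        for family_id, indices in self.families.items():
            n_wt = sum(1 for i in indices if self.records[i].is_wildtype)
            if n_wt != 1:
                raise PPAffinityError(
                    f"family {family_id!r} has {n_wt} wild-type records (needs exactly 1)"
                )

    @property
    def families(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, rec in enumerate(self.records):
            out.setdefault(rec.family_id, []).append(i)
        return out

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.families)

    def wildtype_index(self, family_id: str) -> int:
        for i in self.families[family_id]:
            if self.records[i].is_wildtype:
                return i
        raise KeyError(family_id)

    @property
    def dg_exp(self) -> np.ndarray:
        return np.array([rec.dg_exp for rec in self.records])

    def subset(self, indices: Sequence[int]) -> "AffinityDataset":
        return AffinityDataset([self.records[i] for i in indices])

    def __len__(self) -> int:
        return len(self.records)


class ComplexFeaturizer:
    """Precomputed geometry of one wild-type complex, reused across mutants.

    Contacts, secondary structure and accessible areas depend only on
    coordinates, which threading leaves untouched; per-mutant work is a
    relabelling plus category recounting.
    """

    def __init__(
        self,
        complex_structure: ComplexStructure,
        cutoff: float = INTERFACE_CONTACT_CUTOFF,
        n_points: int = 960,
    ):
        self.complex = complex_structure
        self.cutoff = cutoff
        self.n_points = n_points
        self.contacts = detect_contacts(complex_structure, cutoff)
        self.ss = assign_secondary_structure(complex_structure)
        comp = residue_area_components(complex_structure, "complex", n_points=n_points)
        mono = residue_area_components(complex_structure, "monomer_A", n_points=n_points)
        mono.update(residue_area_components(complex_structure, "monomer_B", n_points=n_points))
        self._areas_complex = comp
        self._areas_monomer = mono
        self._wt_aa = {res.key: res.aa_type for res in complex_structure.residues}
        self._regions: dict[ResKey, str] | None = None

    def _sas_map(self, structure: ComplexStructure) -> dict[ResKey, SASProfile]:
        """Accessibility profiles for a (possibly relabelled) structure.

        A residue relabelled to glycine exposes its CA-atom area as the
        sidechain surrogate; every other residue keeps the measured
        wild-type sidechain area, normalised downstream by the current
        residue type's reference area.
        """
        out: dict[ResKey, SASProfile] = {}
        for res in structure.residues:
            side_c, ca_c = self._areas_complex[res.key]
            side_m, ca_m = self._areas_monomer[res.key]
            if res.aa_type == "G" and self._wt_aa[res.key] != "G":
                sas_c, sas_m = ca_c, ca_m
            else:
                sas_c, sas_m = side_c, side_m
            out[res.key] = SASProfile(res.key, res.aa_type, sas_c, sas_m)
        return out

    def features(self, mutations: Sequence[Mutation] = ()) -> FeatureVector:
        structure = thread_mutations(self.complex, mutations) if mutations else self.complex
        return extract_features(
            structure, self.ss, self._sas_map(structure),
            cutoff=self.cutoff, contacts=self.contacts,
        )

    def regions(self) -> dict[ResKey, str]:
        """Five-region labels of the wild-type complex (cached)."""
        if self._regions is None:
            profiles = {}
            for res in self.complex.residues:
                side_c, _ = self._areas_complex[res.key]
                side_m, _ = self._areas_monomer[res.key]
                profiles[res.key] = SASProfile(res.key, res.aa_type, side_c, side_m)
            self._regions = classify_region(self.complex, profiles)
        return self._regions


# ---------------------------------------------------------------------------
# SKEMPI-style tabular input
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "#pdb": "complex",
    "pdb": "complex",
    "complex": "complex",
    "mutation(s)": "mutations",
    "mutations": "mutations",
    "mutation": "mutations",
    "affinity_wt": "kd_wt",
    "kd_wt": "kd_wt",
    "affinity_mut": "kd_mut",
    "kd_mut": "kd_mut",
    "temperature": "temperature",
}


def read_skempi_table(source) -> pd.DataFrame:
    """Read a SKEMPI-style CSV into a normalised table.

    Expected columns (case-insensitive, common aliases accepted):
    ``complex`` — ``<id>_<chainsA>_<chainsB>``, e.g. ``1BRS_A_D``;
    ``mutations`` — semicolon-separated ``<chain><wild><number><mutant>``
    entries, empty for a wild-type-only row; ``kd_wt``/``kd_mut`` —
    dissociation constants in mol/L; optional ``temperature`` in kelvin
    (298 K assumed when absent).
    """
    df = pd.read_csv(source)
    df.columns = [_COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in df.columns]
    required = {"complex", "mutations", "kd_wt", "kd_mut"}
    missing = required - set(df.columns)
    if missing:
        raise PPAffinityError(f"affinity table is missing columns: {sorted(missing)}")
    if "temperature" not in df.columns:
        df["temperature"] = 298.0
    df["temperature"] = df["temperature"].fillna(298.0)
    df["mutations"] = df["mutations"].fillna("")
    parts = df["complex"].str.split("_")
    if not (parts.str.len() == 3).all():
        raise PPAffinityError("complex column must look like <id>_<chainsA>_<chainsB>")
    df["pdb_id"] = parts.str[0]
    df["partner_a"] = parts.str[1]
    df["partner_b"] = parts.str[2]
    return df


def load_skempi_dataset(
    table: pd.DataFrame | str | Path,
    pdb_dir: str | Path,
    cutoff: float = INTERFACE_CONTACT_CUTOFF,
    n_points: int = 960,
) -> AffinityDataset:
    """Build an :class:`AffinityDataset` from a SKEMPI-style table and a
    directory of wild-type PDB files (``<pdb_id>.pdb``).

    Each table row yields one mutant record; one wild-type record per
    complex is derived from the ``kd_wt`` column (the first row's value).
    Single mutants are annotated with the five-region label of their
    mutated site in the wild-type structure.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_skempi_table(table)
    pdb_dir = Path(pdb_dir)

    records: list[AffinityRecord] = []
    for family_id, group in table.groupby("complex", sort=True):
        first = group.iloc[0]
        pdb_path = pdb_dir / f"{first['pdb_id']}.pdb"
        structure = parse_complex(
            pdb_path.read_text(),
            partner_A=list(first["partner_a"].replace(",", "")),
            partner_B=list(first["partner_b"].replace(",", "")),
            complex_id=str(family_id),
        )
        featurizer = ComplexFeaturizer(structure, cutoff=cutoff, n_points=n_points)
        regions = featurizer.regions()

        records.append(
            AffinityRecord(
                complex_id=str(family_id),
                family_id=str(family_id),
                mutations=(),
                features=featurizer.features(),
                dg_exp=kd_to_dg(float(first["kd_wt"]), float(first["temperature"])),
            )
        )
        for _, row in group.iterrows():
            muts = tuple(
                parse_mutation(tok) for tok in str(row["mutations"]).split(";") if tok.strip()
            )
            if not muts:
                continue
            region = regions.get(muts[0].site) if len(muts) == 1 else None
            records.append(
                AffinityRecord(
                    complex_id=f"{family_id}:{row['mutations']}",
                    family_id=str(family_id),
                    mutations=muts,
                    features=featurizer.features(muts),
                    dg_exp=kd_to_dg(float(row["kd_mut"]), float(row["temperature"])),
                    mutation_region=region,
                )
            )
    return AffinityDataset(records)


def design_matrices(records: Sequence[AffinityRecord]) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """Sparse count matrices (records x categories) for the two blocks."""
    def build(n_cols: int, attr: str) -> sparse.csr_matrix:
        rows, cols, data = [], [], []
        for i, rec in enumerate(records):
            for idx, count in getattr(rec.features, attr).items():
                rows.append(i)
                cols.append(idx)
                data.append(count)
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(records), n_cols), dtype=float
        )

    return (
        build(N_INTERFACIAL_CATEGORIES, "interfacial"),
        build(N_NONINTERFACIAL_CATEGORIES, "noninterfacial"),
    )
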