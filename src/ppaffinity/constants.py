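"""Shared constants: amino-acid alphabets, radii and reference-area tables.

The van der Waals radii and per-residue maximal sidechain accessible areas
are shipped as editable YAML files under :mod:`ppaffinity.data`; the loaders
here cache them and allow overrides for non-default tables.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Non-standard residue names mapped onto a standard parent before parsing.
RESIDUE_ALIASES: dict[str, str] = {"MSE": "MET"}

#: Backbone atom names; everything else in a residue is sidechain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Probe radius of a water molecule for accessible-surface calculations (A).
WATER_PROBE_RADIUS: float = 1.4

#: Contact cutoff used when counting pairs for the statistical potential (A).
POTENTIAL_CONTACT_CUTOFF: float = 5.5

#: Contact cutoff defining interfacial residues in the affinity model (A).
INTERFACE_CONTACT_CUTOFF: float = 5.0

#: Relative sidechain accessibility above which a residue is exposed.
EXPOSURE_THRESHOLD: float = 0.30

#: Relative accessibility threshold of the five-region decomposition.
REGION_THRESHOLD: float = 0.25

#: Gas constant in kcal/(mol*K), for converting Kd to a binding free energy.
GAS_CONSTANT_KCAL: float = 0.0019872


def _load_yaml(name: str) -> dict:
    with resources.files("ppaffinity.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def vdw_radii() -> dict[str, float]:
    """Van der Waals radius per element symbol, in Angstrom."""
    return {str(k).upper(): float(v) for k, v in _load_yaml("vdw_radii.yaml").items()}


@lru_cache(maxsize=None)
def max_sidechain_sasa() -> dict[str, float]:
    """Maximal sidechain accessible area per residue type (Gly-X-Gly reference).

    Used as the normaliser when converting absolute sidechain areas to
    relative accessibilities. Glycine carries a CA-surrogate reference area.
    """
    return {str(k): float(v) for k, v in _load_yaml("max_sidechain_sasa.yaml").items()}
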