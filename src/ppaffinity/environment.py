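"""Per-residue structural environment: secondary structure, solvent
accessibility and the five-region interface decomposition.

Secondary structure is assigned with a built-in Kabsch–Sander style
hydrogen-bond analysis (backbone amide H reconstructed geometrically,
electrostatic bond energy with the standard −0.5 kcal/mol threshold)
collapsed to three states: helix states {H, G, I} -> H, bridge/strand
states {E, B} -> S, everything else -> L.

Solvent-accessible surface areas use the Shrake–Rupley sphere-point
quadrature with a 1.4 A water probe; per-residue values are sums over
sidechain atoms (CA surrogate for glycine).

The five-region decomposition compares a residue's relative sidechain
accessibility in the isolated monomer (r_m) with that in the complex
(r_c) at a 25% threshold: interior / surface for residues untouched by
binding, and support / rim / core for residues that lose accessibility
on complex formation.
"""

from __future__ import annotations

import math
from typing import Literal, Mapping

import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    EXPOSURE_THRESHOLD,
    REGION_THRESHOLD,
    WATER_PROBE_RADIUS,
    max_sidechain_sasa,
    vdw_radii,
)
from .errors import MissingBackboneError, SASAInputError, UnknownElementError
from .structure import ComplexStructure, ResidueView

__all__ = [
    "SS_STATES",
    "REGION_LABELS",
    "SASProfile",
    "assign_secondary_structure",
    "compute_sas",
    "sas_profiles",
    "classify_exposure",
    "classify_region",
    "relative_sas",
]

SS_STATES = ("H", "S", "L")
REGION_LABELS = ("core", "rim", "support", "surface", "interior")

ResKey = tuple[str, int, str]

# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander hydrogen bonds, 3-state collapse)
# ---------------------------------------------------------------------------

_HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_HB_COUPLING = 0.084 * 332.0  # q1*q2*f of the Kabsch-Sander electrostatic model


def _backbone_arrays(residues: list[ResidueView]) -> dict[str, np.ndarray]:
    out = {}
    for name in ("N", "CA", "C", "O"):
        arr = np.full((len(residues), 3), np.nan)
        for i, res in enumerate(residues):
            atom = res.atom(name)
            if atom is not None:
                arr[i] = atom.position
        out[name] = arr
    return out


def _hbond_matrix(chain: list[ResidueView]) -> np.ndarray:
    """hb[a, d] is True when the amide of residue d donates to the carbonyl
    of residue a with Kabsch-Sander energy below the −0.5 kcal/mol cutoff."""
    n = len(chain)
    bb = _backbone_arrays(chain)
    hpos = np.full((n, 3), np.nan)
    for d in range(1, n):
        if chain[d].aa_type == "P":  # proline has no amide hydrogen
            continue
        co = bb["C"][d - 1] - bb["O"][d - 1]
        norm = np.linalg.norm(co)
        if not np.isfinite(norm) or norm == 0:
            continue
        hpos[d] = bb["N"][d] + co / norm  # 1.0 A from N, along prev C->O

    hb = np.zeros((n, n), dtype=bool)
    for a in range(n):
        c, o = bb["C"][a], bb["O"][a]
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(o))):
            continue
        for d in range(n):
            if abs(a - d) < 2:  # no bonds within a residue or to a neighbour
                continue
            nn, h = bb["N"][d], hpos[d]
            if not (np.all(np.isfinite(nn)) and np.all(np.isfinite(h))):
                continue
            r_on = np.linalg.norm(o - nn)
            if r_on > 5.2:  # beyond any plausible backbone H-bond
                continue
            r_ch = np.linalg.norm(c - h)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(c - nn)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            energy = _HB_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < _HB_ENERGY_CUTOFF:
                hb[a, d] = True
    return hb


def _assign_chainwise(chain: list[ResidueView]) -> list[str]:
    n = len(chain)
    if n == 0:
        return []
    hb = _hbond_matrix(chain)

    def turn(i: int, k: int) -> bool:
        return i + k < n and hb[i, i + k]

    helix4 = np.zeros(n, dtype=bool)   # alpha helix (H); takes priority
    helix35 = np.zeros(n, dtype=bool)  # 3-10 and pi helices (G, I)
    strand = np.zeros(n, dtype=bool)   # bridges and ladders (B, E)

    for k, target in ((4, helix4), (3, helix35), (5, helix35)):
        for i in range(1, n - k):
            if turn(i - 1, k) and turn(i, k):
                target[i : i + k] = True

    for i in range(n):
        for j in range(i + 3, n):
            para = (turn_pair(hb, i - 1, j) and turn_pair(hb, j, i + 1)) or (
                turn_pair(hb, j - 1, i) and turn_pair(hb, i, j + 1)
            )
            anti = (turn_pair(hb, i, j) and turn_pair(hb, j, i)) or (
                turn_pair(hb, i - 1, j + 1) and turn_pair(hb, j - 1, i + 1)
            )
            if para or anti:
                strand[i] = strand[j] = True

    out = []
    for i in range(n):
        if helix4[i]:
            out.append("H")
        elif strand[i]:
            out.append("S")
        elif helix35[i]:
            out.append("H")
        else:
            out.append("L")
    return out


def turn_pair(hb: np.ndarray, acceptor: int, donor: int) -> bool:
    n = hb.shape[0]
    return 0 <= acceptor < n and 0 <= donor < n and bool(hb[acceptor, donor])


def assign_secondary_structure(
    complex_structure: ComplexStructure,
) -> dict[ResKey, str]:
    """Three-state secondary structure (H/S/L) for every residue.

    Residues for which no helix or strand pattern can be established —
    including chain termini and fragments too short for any pattern —
    fall back to loop (L).
    """
    per_chain: dict[str, list[ResidueView]] = {}
    for res in complex_structure.residues:
        per_chain.setdefault(res.chain_id, []).append(res)

    any_backbone = any(
        res.atom("N") is not None and res.atom("CA") is not None and res.atom("C") is not None
        for res in complex_structure.residues
    )
    if not any_backbone:
        raise MissingBackboneError(
            f"{complex_structure.complex_id}: no backbone atoms for secondary structure"
        )

    result: dict[ResKey, str] = {}
    for chain_residues in per_chain.values():
        labels = _assign_chainwise(chain_residues)
        for res, label in zip(chain_residues, labels):
            result[res.key] = label
    return result


# ---------------------------------------------------------------------------
# Shrake-Rupley solvent-accessible surface
# ---------------------------------------------------------------------------


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radius(element: str, radii: Mapping[str, float]) -> float:
    try:
        return radii[element.upper()]
    except KeyError:
        raise UnknownElementError(f"no van der Waals radius for element {element!r}")


def atom_sas(
    positions: np.ndarray,
    radii: np.ndarray,
    n_points: int = 960,
    probe: float = WATER_PROBE_RADIUS,
) -> np.ndarray:
    """Accessible area per atom (A^2) by Shrake-Rupley quadrature."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    positions = np.asarray(positions, float)
    radii = np.asarray(radii, float)
    n_atoms = len(positions)
    areas = np.zeros(n_atoms)
    if n_atoms == 0:
        return areas
    unit = _sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(positions)
    for i in range(n_atoms):
        r_i = expanded[i]
        pts = positions[i] + r_i * unit
        neighbours = [j for j in tree.query_ball_point(positions[i], r_i + expanded.max())
                      if j != i and np.linalg.norm(positions[j] - positions[i]) < r_i + expanded[j]]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - positions[j], pts - positions[j])
            accessible &= d2 >= expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = accessible.sum() / n_points * 4.0 * math.pi * r_i**2
    return areas


def compute_sas(
    complex_structure: ComplexStructure,
    context: Literal["complex", "monomer_A", "monomer_B"] = "complex",
    n_points: int = 960,
    probe: float = WATER_PROBE_RADIUS,
) -> dict[ResKey, float]:
    """Per-residue sidechain accessible area (A^2) in a given context.

    ``monomer_A``/``monomer_B`` drop every atom of the other partner
    before the calculation, as if the partner had been removed rigidly.
    In all contexts the occluding environment includes backbone atoms;
    only sidechain atoms (CA for glycine) contribute to the reported sums.
    """
    radii_table = vdw_radii()
    if context == "complex":
        residues = list(complex_structure.residues)
    elif context == "monomer_A":
        residues = list(complex_structure.partner_residues("A"))
    elif context == "monomer_B":
        residues = list(complex_structure.partner_residues("B"))
    else:
        raise ValueError(f"unknown context {context!r}")

    positions, radii, owner, is_side = [], [], [], []
    for idx, res in enumerate(residues):
        side_names = {a.name for a in res.sidechain_atoms}
        for atom in res.atoms:
            positions.append(atom.position)
            radii.append(_atom_radius(atom.element, radii_table))
            owner.append(idx)
            is_side.append(atom.name in side_names)
    areas = atom_sas(np.asarray(positions), np.asarray(radii), n_points=n_points, probe=probe)
    owner_arr = np.asarray(owner)
    side_arr = np.asarray(is_side)

    result = {res.key: 0.0 for res in residues}
    for i, area in enumerate(areas):
        if side_arr[i]:
            result[residues[owner_arr[i]].key] += float(area)
    return result


def residue_area_components(
    complex_structure: ComplexStructure,
    context: Literal["complex", "monomer_A", "monomer_B"] = "complex",
    n_points: int = 960,
    probe: float = WATER_PROBE_RADIUS,
) -> dict[ResKey, tuple[float, float]]:
    """Per-residue (sidechain area, CA-atom area) in a given context.

    The CA component supports the glycine surrogate when a residue is
    relabelled to glycine on unchanged geometry: its ``sidechain`` surface
    is then the accessible area of the CA atom.
    """
    radii_table = vdw_radii()
    if context == "complex":
        residues = list(complex_structure.residues)
    elif context == "monomer_A":
        residues = list(complex_structure.partner_residues("A"))
    else:
        residues = list(complex_structure.partner_residues("B"))

    positions, radii, owner, names = [], [], [], []
    for idx, res in enumerate(residues):
        for atom in res.atoms:
            positions.append(atom.position)
            radii.append(_atom_radius(atom.element, radii_table))
            owner.append(idx)
            names.append(atom.name)
    areas = atom_sas(np.asarray(positions), np.asarray(radii), n_points=n_points, probe=probe)

    side: dict[ResKey, float] = {res.key: 0.0 for res in residues}
    ca: dict[ResKey, float] = {res.key: 0.0 for res in residues}
    side_names = {res.key: {a.name for a in res.sidechain_atoms} for res in residues}
    for i, area in enumerate(areas):
        key = residues[owner[i]].key
        if names[i] in side_names[key]:
            side[key] += float(area)
        if names[i] == "CA":
            ca[key] = float(area)
    return {key: (side[key], ca[key]) for key in side}


def relative_sas(residue_aa: str, area: float) -> float:
    """Fraction of the residue type's maximal sidechain accessible area."""
    if area < 0:
        raise SASAInputError("negative accessible area")
    return area / max_sidechain_sasa()[residue_aa]


class SASProfile:
    """Sidechain accessibility of one residue in monomer and complex context."""

    __slots__ = ("key", "aa_type", "sas_complex", "sas_monomer", "rel_complex", "rel_monomer")

    def __init__(self, key: ResKey, aa_type: str, sas_complex: float, sas_monomer: float,
                 quadrature_tol: float = 0.05):
        if sas_complex < 0 or sas_monomer < 0:
            raise SASAInputError(f"{key}: negative accessible area")
        if sas_complex > sas_monomer * (1 + quadrature_tol) + 1e-9:
            raise SASAInputError(
                f"{key}: complex-context area {sas_complex:.2f} exceeds monomer "
                f"area {sas_monomer:.2f}; inconsistent inputs"
            )
        self.key = key
        self.aa_type = aa_type
        self.sas_complex = sas_complex
        self.sas_monomer = sas_monomer
        self.rel_complex = relative_sas(aa_type, sas_complex)
        self.rel_monomer = relative_sas(aa_type, sas_monomer)

    @property
    def exposure(self) -> str:
        return classify_exposure(self.rel_complex)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"SASProfile({self.key}, {self.aa_type}, "
                f"rel_c={self.rel_complex:.3f}, rel_m={self.rel_monomer:.3f})")


def sas_profiles(
    complex_structure: ComplexStructure, n_points: int = 960
) -> dict[ResKey, SASProfile]:
    """Monomer- and complex-context accessibility for every residue."""
    sas_c = compute_sas(complex_structure, "complex", n_points=n_points)
    sas_m = compute_sas(complex_structure, "monomer_A", n_points=n_points)
    sas_m.update(compute_sas(complex_structure, "monomer_B", n_points=n_points))
    out: dict[ResKey, SASProfile] = {}
    for res in complex_structure.residues:
        out[res.key] = SASProfile(
            res.key, res.aa_type,
            sas_complex=min(sas_c[res.key], sas_m[res.key]),
            sas_monomer=sas_m[res.key],
        )
    return out


def classify_exposure(rel_complex: float, threshold: float = EXPOSURE_THRESHOLD) -> str:
    """Exposed (E) when strictly more than 30% of the maximal sidechain
    surface is accessible, else buried (B)."""
    if rel_complex < 0:
        raise SASAInputError("negative relative accessibility")
    return "E" if rel_complex > threshold else "B"


def _region_of(r_m: float, r_c: float, threshold: float, delta_tol: float) -> str:
    delta = r_m - r_c
    if delta <= delta_tol:
        return "interior" if r_m < threshold else "surface"
    if r_m < threshold:
        return "support"
    if r_c >= threshold:
        return "rim"
    return "core"


def classify_region(
    complex_structure: ComplexStructure,
    profiles: Mapping[ResKey, SASProfile] | None = None,
    n_points: int = 960,
    threshold: float = REGION_THRESHOLD,
    delta_tol: float = 1e-6,
) -> dict[ResKey, str]:
    """Five-region label for every residue of the complex.

    With r_m / r_c the relative sidechain accessibility in monomer and
    complex context and Δ = r_m − r_c:

    ========  ==========================================
    interior  Δ ≈ 0 and r_m < 25%
    surface   Δ ≈ 0 and r_m ≥ 25%
    support   Δ > 0 and r_m < 25%
    rim       Δ > 0 and r_c ≥ 25%
    core      Δ > 0, r_m ≥ 25% and r_c < 25%
    ========  ==========================================
    """
    if profiles is None:
        profiles = sas_profiles(complex_structure, n_points=n_points)
    out: dict[ResKey, str] = {}
    for res in complex_structure.residues:
        p = profiles[res.key]
        if p.rel_complex > p.rel_monomer + delta_tol:
            raise SASAInputError(
                f"{res.key}: complex accessibility exceeds monomer accessibility"
            )
        out[res.key] = _region_of(p.rel_monomer, min(p.rel_complex, p.rel_monomer),
                                  threshold, delta_tol)
    return out
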