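"""Synthetic two-partner complexes and planted-weight affinity datasets.

The generator emulates the structure of mutation-affinity databases: a
number of families, each one wild-type complex plus threaded mutants,
with experimental affinities manufactured from a planted weight vector
(optionally with additive Gaussian noise). Structures are idealized —
chains mix helical and extended segments with standard backbone
geometry, and each residue carries a single-sphere pseudo-sidechain at
the CB position — which is enough to exercise contact counting,
accessibility classes and the whole fitting machinery, while remaining
fast and fully reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import AMINO_ACIDS, ONE_TO_THREE
from .dataset import AffinityDataset, AffinityRecord, ComplexFeaturizer
from .errors import FixtureGeometryError
from .model import Mutation, WeightVector, predict_affinity
from .structure import AtomRecord, ComplexStructure, ResidueView, parse_complex

__all__ = [
    "FixtureSpec",
    "SyntheticDataset",
    "make_complex",
    "make_dataset",
    "to_pdb",
    "build_backbone",
    "ideal_helix_complex",
    "antiparallel_sheet_complex",
]

# Standard backbone internal coordinates (lengths in A, angles in degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D after A-B-C."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array(
        [-bond * math.cos(angle), bond * math.sin(angle) * math.cos(torsion),
         bond * math.sin(angle) * math.sin(torsion)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Tetrahedral CB placement from the backbone frame (L-configuration)."""
    u1 = _unit(n - ca)
    u2 = _unit(c - ca)
    cos_t = math.cos(math.radians(110.5))
    s = u1 + u2
    alpha = cos_t / float(u1 @ s)
    w = _unit(np.cross(u1, u2))
    beta = math.sqrt(max(0.0, 1.0 - alpha * alpha * float(s @ s)))
    return ca + _B_CA_CB * (alpha * s + beta * w)


def build_backbone(phi_psi: Sequence[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone (N, CA, C, O) plus CB coordinates for a chain with the given
    per-residue (phi, psi) torsions; omega is held at 180 degrees."""
    n_res = len(phi_psi)
    if n_res == 0:
        return []
    coords: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    angle = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([math.cos(math.pi - angle), math.sin(math.pi - angle), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, n_res):
        prev = coords[i - 1]
        psi_prev = phi_psi[i - 1][1]
        n_i = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        ca_i = _place(prev["CA"], prev["C"], n_i, _B_N_CA, _A_C_N_CA, 180.0)
        c_i = _place(prev["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, phi_psi[i][0])
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})

    for i, res in enumerate(coords):
        if i + 1 < n_res:
            to_n = _unit(coords[i + 1]["N"] - res["C"])
            to_ca = _unit(res["CA"] - res["C"])
            res["O"] = res["C"] + _B_C_O * -_unit(to_n + to_ca)
        else:
            res["O"] = _place(res["N"], res["CA"], res["C"], _B_C_O, 120.8,
                              phi_psi[i][1] + 180.0)
        res["CB"] = _cb_position(res["N"], res["CA"], res["C"])
    return coords


def _chain_residues(
    chain_id: str, sequence: str, phi_psi: Sequence[tuple[float, float]],
    transform: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[ResidueView]:
    coords = build_backbone(phi_psi)
    rot, tr = transform if transform is not None else (np.eye(3), np.zeros(3))
    residues = []
    for i, (aa, res) in enumerate(zip(sequence, coords)):
        atoms = []
        for name in ("N", "CA", "C", "O"):
            atoms.append(AtomRecord(name, name[0], rot @ res[name] + tr))
        if aa != "G":
            atoms.append(AtomRecord("CB", "C", rot @ res["CB"] + tr))
        residues.append(ResidueView(chain_id, i + 1, "", aa, tuple(atoms)))
    return residues


def _mixed_phi_psi(n_res: int) -> list[tuple[float, float]]:
    """First ~60% helical, remainder extended."""
    n_helix = max(4, int(round(0.6 * n_res)))
    return [HELIX_PHI_PSI] * min(n_helix, n_res) + [STRAND_PHI_PSI] * max(0, n_res - n_helix)


def _sidechain_xyz(residues: Sequence[ResidueView]) -> np.ndarray:
    pts = []
    for res in residues:
        for atom in res.sidechain_atoms:
            pts.append(atom.position)
    return np.asarray(pts)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of a synthetic affinity dataset."""

    seed: int = 0
    n_families: int = 10
    mutants_per_family: int = 30
    residues_per_partner: int = 30
    interface_width: float = 4.5  # minimum cross-partner sidechain distance, A
    noise_sd: float = 0.0  # additive noise on dg_exp, kcal/mol
    planted_weights: WeightVector | str = "random"
    planted_wn: float = 0.7
    family_divergence: float = 0.02  # fraction of positions re-randomised per family
    mutation_interface_bias: float = 0.5  # probability a mutated site is interfacial
    alanine_fraction: float = 0.5  # scan-style fraction of substitutions to alanine
    mutation_panel: str = "ADGKLSW"  # target repertoire of non-alanine substitutions
    sas_points: int = 240  # Shrake-Rupley quadrature for feature extraction
    target_mean: float = -10.0  # kcal/mol location of the generated affinities
    target_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_families < 2:
            raise ValueError("n_families must be >= 2")
        if self.residues_per_partner < 5:
            raise ValueError("residues_per_partner must be >= 5")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def make_complex(spec: FixtureSpec, family_index: int) -> tuple[ComplexStructure, str]:
    """One idealized two-chain complex with a controllable interface.

    Chain B is built like chain A, flipped, and translated along the
    line of closest approach until the minimum cross-partner sidechain
    distance equals ``spec.interface_width`` exactly. Returns the
    in-memory structure and its PDB text (which re-parses identically).
    """
    if spec.interface_width < 0:
        raise FixtureGeometryError("interface_width must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, family_index)))
    n = spec.residues_per_partner

    # Families are sequence variants of a common scaffold: a base sequence
    # pair drawn once per dataset seed, with a fraction of positions
    # re-randomised per family. Shared scaffold positions make the model's
    # categories recur across families, which keeps the planted weights
    # identifiable from a desk-scale number of families.
    rng_base = np.random.default_rng(np.random.SeedSequence((spec.seed, 424242)))
    base_a = rng_base.choice(list(AMINO_ACIDS), size=n)
    base_b = rng_base.choice(list(AMINO_ACIDS), size=n)

    def diverge(base: np.ndarray) -> str:
        mask = rng.random(n) < spec.family_divergence
        fresh = rng.choice(list(AMINO_ACIDS), size=n)
        return "".join(np.where(mask, fresh, base))

    seq_a = diverge(base_a)
    seq_b = diverge(base_b)
    phi_psi = _mixed_phi_psi(n)

    res_a = _chain_residues("A", seq_a, phi_psi)

    # Dock the partners strand-to-strand: rotate chain B by 180 degrees
    # about an axis perpendicular to A's extended segment so the two
    # extended segments run antiparallel side by side (and the helical
    # segments point to opposite ends), then push B in until the minimum
    # cross-partner sidechain distance equals interface_width exactly.
    n_helix = sum(1 for pp in phi_psi if pp == HELIX_PHI_PSI)
    strand_ca = np.array([res_a[i].atom("CA").position for i in range(n_helix, n)])
    if len(strand_ca) >= 2:
        axis_u = _unit(strand_ca[-1] - strand_ca[0])
        pivot = strand_ca.mean(axis=0)
    else:
        all_ca = np.array([r.atom("CA").position for r in res_a])
        axis_u = _unit(all_ca[-1] - all_ca[0])
        pivot = all_ca.mean(axis=0)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(ref @ axis_u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    w_axis = _unit(ref - (ref @ axis_u) * axis_u)
    # Rodrigues rotation by pi about w_axis: R = 2 w w^T - I
    rot = 2.0 * np.outer(w_axis, w_axis) - np.eye(3)
    approach = np.cross(axis_u, w_axis)

    start = pivot + 200.0 * approach - rot @ pivot
    res_b = _chain_residues("B", seq_b, phi_psi, transform=(rot, start))

    xyz_a = _sidechain_xyz(res_a)
    xyz_b = _sidechain_xyz(res_b)

    def min_dist(t: float) -> float:
        shifted = xyz_b - t * approach
        d2 = ((shifted[:, None, :] - xyz_a[None, :, :]) ** 2).sum(axis=2)
        return math.sqrt(float(d2.min()))

    # walk chain B in from far away until the minimum separation reaches
    # the target, then bisect to hit interface_width exactly
    t = 0.0
    while min_dist(t) > spec.interface_width and t < 400.0:
        t += 1.0
    lo_t, hi_t = t - 1.0, t  # min_dist(lo_t) >= width > min_dist(hi_t)
    for _ in range(80):
        mid = 0.5 * (lo_t + hi_t)
        if min_dist(mid) > spec.interface_width:
            lo_t = mid
        else:
            hi_t = mid
    shift = -lo_t * approach  # approach side keeps min distance >= width

    res_b = [
        ResidueView(r.chain_id, r.seq_number, r.insertion_code, r.aa_type,
                    tuple(AtomRecord(a.name, a.element, a.position + shift) for a in r.atoms))
        for r in res_b
    ]

    cplx = ComplexStructure(
        f"SYN{family_index:03d}", frozenset({"A"}), frozenset({"B"}),
        tuple(res_a) + tuple(res_b),
    )
    return cplx, to_pdb(cplx)


def to_pdb(complex_structure: ComplexStructure) -> str:
    """Serialise a complex as minimal standard PDB text."""
    lines = []
    serial = 1
    last_chain = None
    for res in complex_structure.residues:
        if last_chain is not None and res.chain_id != last_chain:
            lines.append("TER")
        last_chain = res.chain_id
        res3 = ONE_TO_THREE[res.aa_type]
        for atom in res.atoms:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.position
            lines.append(
                f"ATOM  {serial:5d} {name:4s} {res3:3s} {res.chain_id:1s}"
                f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass
class SyntheticDataset:
    """A planted-weight dataset with its ground truth."""

    dataset: AffinityDataset
    planted: WeightVector
    spec: FixtureSpec
    complexes: dict[str, ComplexStructure] = field(default_factory=dict)
    pdb_texts: dict[str, str] = field(default_factory=dict)
    noiseless_dg: np.ndarray | None = None


def make_dataset(spec: FixtureSpec) -> SyntheticDataset:
    """Families of one wild type plus threaded mutants with affinities
    manufactured from a planted weight vector.

    Mutation panels mimic experimental scans: sites are biased toward
    the interface, half the substitutions go to alanine and the rest are
    drawn from a small recurring repertoire. Raw planted scores are
    mapped affinely onto a plausible affinity range (mean −10, SD 3
    kcal/mol by default) and Gaussian noise of ``spec.noise_sd`` is
    added; with zero noise the experimental values are an exact affine
    image of the planted model's predictions.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 987654321)))
    if isinstance(spec.planted_weights, WeightVector):
        planted = WeightVector(
            spec.planted_weights.w_itf, spec.planted_weights.w_nitf, spec.planted_wn
        )
    else:
        planted = WeightVector.random(rng, w_n=spec.planted_wn)

    records: list[AffinityRecord] = []
    complexes: dict[str, ComplexStructure] = {}
    pdb_texts: dict[str, str] = {}
    raw_scores: list[float] = []

    for fam in range(spec.n_families):
        cplx, pdb_text = make_complex(spec, fam)
        family_id = cplx.complex_id
        complexes[family_id] = cplx
        pdb_texts[family_id] = pdb_text
        featurizer = ComplexFeaturizer(cplx, n_points=spec.sas_points)
        regions = featurizer.regions()

        wt_features = featurizer.features()
        records.append(
            AffinityRecord(family_id, family_id, (), wt_features, dg_exp=0.0)
        )
        raw_scores.append(predict_affinity(wt_features, planted))

        residues = list(cplx.residues)
        interfacial = [
            i for i, r in enumerate(residues)
            if r.key in featurizer.contacts.interfacial_residues
        ]
        elsewhere = [i for i in range(len(residues)) if i not in interfacial]
        for m in range(spec.mutants_per_family):
            n_sites = 1 if rng.random() < 0.8 else 2
            sites: list[int] = []
            for _ in range(n_sites):
                pool = (
                    interfacial
                    if interfacial and rng.random() < spec.mutation_interface_bias
                    else elsewhere
                )
                s = int(rng.choice(pool))
                while s in sites:
                    s = int(rng.choice(pool))
                sites.append(s)
            muts = []
            for s in sites:
                res = residues[s]
                if rng.random() < spec.alanine_fraction and res.aa_type != "A":
                    target = "A"
                else:
                    panel = [aa for aa in spec.mutation_panel if aa != res.aa_type]
                    target = str(rng.choice(panel or [aa for aa in AMINO_ACIDS if aa != res.aa_type]))
                muts.append(
                    Mutation(res.chain_id, res.seq_number, res.aa_type,
                             target, res.insertion_code)
                )
            muts = tuple(muts)
            features = featurizer.features(muts)
            region = regions.get(muts[0].site) if len(muts) == 1 else None
            records.append(
                AffinityRecord(
                    f"{family_id}:m{m}", family_id, muts, features,
                    dg_exp=0.0, mutation_region=region,
                )
            )
            raw_scores.append(predict_affinity(features, planted))

    raw = np.asarray(raw_scores)
    sd = raw.std()
    if sd > 0:
        noiseless = spec.target_mean + (raw - raw.mean()) * spec.target_sd / sd
    else:
        noiseless = np.full_like(raw, spec.target_mean)
    noisy = noiseless + rng.normal(0.0, spec.noise_sd, size=len(raw)) if spec.noise_sd > 0 else noiseless
    for rec, dg in zip(records, noisy):
        rec.dg_exp = float(dg)

    return SyntheticDataset(
        dataset=AffinityDataset(records),
        planted=planted,
        spec=spec,
        complexes=complexes,
        pdb_texts=pdb_texts,
        noiseless_dg=noiseless,
    )


# ---------------------------------------------------------------------------
# Reference conformations for secondary-structure tests and examples
# ---------------------------------------------------------------------------


def ideal_helix_complex(n_res: int = 12, sequence: str | None = None) -> ComplexStructure:
    """An ideal alpha-helix (phi = -57, psi = -47) paired with a far-away
    partner chain so the object satisfies the two-partner contract."""
    seq = sequence or "A" * n_res
    res_a = _chain_residues("A", seq, [HELIX_PHI_PSI] * n_res)
    res_b = _chain_residues(
        "B", "A" * 5, [STRAND_PHI_PSI] * 5,
        transform=(np.eye(3), np.array([0.0, 120.0, 0.0])),
    )
    return ComplexStructure("HELIX", frozenset({"A"}), frozenset({"B"}),
                            tuple(res_a) + tuple(res_b))


def antiparallel_sheet_complex(n_res: int = 8) -> ComplexStructure:
    """A two-strand antiparallel beta-sheet as a single chain (with a
    chain break), paired with a far-away partner chain.

    The relative strand placement is found by a small deterministic grid
    search over flip/translation parameters, scoring candidates by their
    backbone hydrogen-bond count; both strands live in one chain so the
    per-chain secondary-structure assignment sees their mutual bonds.
    """
    from .environment import _hbond_matrix  # used only to score placements

    seq = "V" * n_res
    phi_psi = [STRAND_PHI_PSI] * n_res
    strand1 = _chain_residues("A", seq, phi_psi)
    ca = np.array([r.atom("CA").position for r in strand1])
    axis_u = _unit(ca[-1] - ca[0])
    pivot = ca.mean(axis=0)
    ref = np.array([0.0, 0.0, 1.0])
    w_axis = _unit(ref - (ref @ axis_u) * axis_u)
    v_axis = np.cross(axis_u, w_axis)
    rot = 2.0 * np.outer(w_axis, w_axis) - np.eye(3)  # pi about w: u -> -u
    xyz_1 = np.array([a.position for r in strand1 for a in r.atoms])

    def build_strand2(du: float, dv: float, dw: float) -> list[ResidueView]:
        tr = pivot + du * axis_u + dv * v_axis + dw * w_axis - rot @ pivot
        return [
            ResidueView(r.chain_id, r.seq_number + n_res + 4, r.insertion_code,
                        r.aa_type,
                        tuple(AtomRecord(a.name, a.element, rot @ a.position + tr)
                              for a in r.atoms))
            for r in strand1
        ]

    best = None
    for du in np.arange(-3.0, 3.01, 0.5):
        for dv in np.arange(2.5, 5.51, 0.25):
            for dw in (-1.0, -0.5, 0.0, 0.5, 1.0):
                strand2 = build_strand2(du, dv, dw)
                xyz_2 = np.array([a.position for r in strand2 for a in r.atoms])
                dmin = math.sqrt(
                    float((((xyz_2[:, None, :] - xyz_1[None, :, :]) ** 2).sum(axis=2)).min())
                )
                if dmin < 1.9:  # clash
                    continue
                hb = _hbond_matrix(list(strand1) + strand2)
                cross = int(hb[:n_res, n_res:].sum() + hb[n_res:, :n_res].sum())
                if best is None or cross > best[0]:
                    best = (cross, (du, dv, dw))
    strand2 = build_strand2(*best[1])
    partner = _chain_residues(
        "B", "A" * 5, [STRAND_PHI_PSI] * 5,
        transform=(np.eye(3), np.array([0.0, 150.0, 0.0])),
    )
    return ComplexStructure("SHEET", frozenset({"A"}), frozenset({"B"}),
                            tuple(strand1) + tuple(strand2) + tuple(partner))
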