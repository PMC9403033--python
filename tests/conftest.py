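"""Shared fixtures: small synthetic complexes and hand-written PDB text."""

import numpy as np
import pytest

import ppaffinity as ppa


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00  0.00           C
ATOM      6  N   LEU A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  LEU A   2       3.988   2.836   0.000  1.00  0.00           C
ATOM      8  C   LEU A   2       5.504   2.705   0.000  1.00  0.00           C
ATOM      9  O   LEU A   2       6.030   1.594   0.000  1.00  0.00           O
ATOM     10  CB  LEU A   2       3.570   3.654   1.230  1.00  0.00           C
TER
ATOM     11  N   GLY B   1       0.000   6.000   0.000  1.00  0.00           N
ATOM     12  CA  GLY B   1       1.458   6.000   0.000  1.00  0.00           C
ATOM     13  C   GLY B   1       2.009   7.420   0.000  1.00  0.00           C
ATOM     14  O   GLY B   1       1.251   8.390   0.000  1.00  0.00           O
ATOM     15  N   TRP B   2       3.332   7.536   0.000  1.00  0.00           N
ATOM     16  CA  TRP B   2       3.988   8.836   0.000  1.00  0.00           C
ATOM     17  C   TRP B   2       5.504   8.705   0.000  1.00  0.00           C
ATOM     18  O   TRP B   2       6.030   7.594   0.000  1.00  0.00           O
ATOM     19  CB  TRP B   2       3.570   9.654   1.230  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   SER A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  OG ASER A   1       2.100  -1.000   1.000  0.60  0.00           O
ATOM      6  OG BSER A   1       2.500  -1.300   0.700  0.40  0.00           O
TER
ATOM      7  N   MSE B   1       0.000   6.000   0.000  1.00  0.00           N
ATOM      8  CA  MSE B   1       1.458   6.000   0.000  1.00  0.00           C
ATOM      9  C   MSE B   1       2.009   7.420   0.000  1.00  0.00           C
ATOM     10  O   MSE B   1       1.251   8.390   0.000  1.00  0.00           O
ATOM     11 SE   MSE B   1       2.800   5.000   1.500  1.00  0.00          SE
TER
HETATM   12  O   HOH B   2       9.000   9.000   9.000  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def minimal_complex():
    return ppa.parse_complex(MINIMAL_PDB, ["A"], ["B"], "minimal")


@pytest.fixture(scope="session")
def small_fixture_complex():
    """A generated 30-residue-per-partner complex with a real interface."""
    cplx, _ = ppa.make_complex(ppa.FixtureSpec(seed=2), 0)
    return cplx


@pytest.fixture(scope="session")
def tiny_spec():
    return ppa.FixtureSpec(
        seed=3, n_families=3, mutants_per_family=5, residues_per_partner=20,
        sas_points=120,
    )


@pytest.fixture(scope="session")
def tiny_synth(tiny_spec):
    return ppa.make_dataset(tiny_spec)


def brute_force_contacts(cplx, cutoff):
    """Independent all-pairs sidechain contact scan (oracle)."""
    pairs = set()
    res_a = cplx.partner_residues("A")
    res_b = cplx.partner_residues("B")
    for ra in res_a:
        for rb in res_b:
            found = False
            for atom_a in ra.sidechain_atoms:
                for atom_b in rb.sidechain_atoms:
                    d = float(np.linalg.norm(atom_a.position - atom_b.position))
                    if d < cutoff:
                        found = True
            if found:
                pairs.add(frozenset({ra.key, rb.key}))
    return pairs
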