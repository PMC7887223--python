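"""Shared fixtures: geometric atom fixtures and the independent grid oracle."""

from __future__ import annotations

import numpy as np
import pytest

from oligosym.core import AtomRecord, AtomSet

Z_AXIS = (np.zeros(3), np.array([0.0, 0.0, 1.0]))


def ring_atoms(radius_fn, z_lo, z_hi, spacing=0.5, n_per=36, vdw=1.85) -> AtomSet:
    """Stacked rings of atoms: a discretised tube with radius radius_fn(z)."""
    atoms, serial = [], 0
    for z in np.arange(z_lo, z_hi + 1e-9, spacing):
        a = radius_fn(z)
        for ang in np.linspace(0.0, 2.0 * np.pi, n_per, endpoint=False):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial, "C", "C", "CYL", int(round(z * 10)), "X",
                    np.array([a * np.cos(ang), a * np.sin(ang), z]), vdw=vdw,
                )
            )
    return AtomSet(atoms, "ring-fixture")


def ideal_helix(n, rise=1.5, twist=100.0, rad=2.3, phase=0.0) -> np.ndarray:
    i = np.arange(n)
    ang = np.radians(twist * i + phase)
    return np.stack([rad * np.cos(ang), rad * np.sin(ang), rise * i], axis=1)


def grid_oracle_radius(atoms: AtomSet, s: float, domain_radius: float, h: float = 0.1) -> float:
    """Exhaustive lattice search for the maximal clearance in the plane z=s.

    Independent of the profiler: evaluates min_i(||p-x_i||-r_i) on an
    ``h``-spaced lattice over a disc of ``domain_radius`` about the z axis
    and returns the maximum.  The domain must lie inside the channel wall so
    the exterior is excluded by construction.
    """
    xyz = atoms.coords()
    rad = atoms.radii()
    g = np.arange(-domain_radius, domain_radius + h / 2, h)
    X, Y = np.meshgrid(g, g)
    keep = X**2 + Y**2 <= domain_radius**2
    pts = np.stack([X[keep], Y[keep], np.full(keep.sum(), s)], axis=1)
    # chunk to bound memory
    best = -np.inf
    for chunk in np.array_split(pts, max(1, len(pts) // 2000)):
        d = np.linalg.norm(chunk[:, None, :] - xyz[None, :, :], axis=2) - rad[None, :]
        best = max(best, float(d.min(axis=1).max()))
    return best


@pytest.fixture(scope="session")
def cylinder_atoms() -> AtomSet:
    """Tube of radius 10 Å: analytic maximal-sphere radius 10 − 1.85 = 8.15 Å."""
    return ring_atoms(lambda z: 10.0, -8.0, 8.0)


@pytest.fixture(scope="session")
def hourglass_atoms() -> AtomSet:
    """Tube tapering linearly from 10 Å to 5 Å at z=0: waist radius 3.15 Å."""
    return ring_atoms(lambda z: 5.0 + 5.0 * abs(z) / 8.0, -8.0, 8.0)


@pytest.fixture(scope="session")
def pentamer():
    from oligosym.synth import build_pentamer

    return build_pentamer()


MINI_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
END
"""

# 10 coordinate lines; VAL 2 has two altlocs -> 7 distinct atoms survive
ALTLOC_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.319   4.851  -4.852  1.00  0.00           C
ATOM      4  N  AVAL A   2      12.000   7.000  -4.000  0.40  0.00           N
ATOM      5  N  BVAL A   2      12.100   7.100  -4.100  0.60  0.00           N
ATOM      6  CA AVAL A   2      13.000   7.500  -3.000  0.50  0.00           C
ATOM      7  CA BVAL A   2      13.100   7.600  -3.100  0.50  0.00           C
ATOM      8  C   VAL A   2      14.000   8.000  -2.000  1.00  0.00           C
ATOM      9  CA  GLY B   1       1.000   2.000   3.000  1.00  0.00           C
ATOM     10  CA  GLY B   2       2.000   3.000   4.000  1.00  0.00           C
END
"""
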