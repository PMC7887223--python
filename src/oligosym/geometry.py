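"""Rigid-body geometry: superposition and inter-conformation measurements.

The measurements here are the ones a structural comparison of two channel
conformations needs: least-squares superposition (Kabsch), probe-atom
displacement in an explicit alignment frame, helix tilt angles from principal
axes, the twist component of a rotation about the pore axis, the axial
thickness of the transmembrane domain, and the pairwise inter-subunit RMSD
matrix whose block structure separates rearrangement modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AtomSet, SelectionError, Structure, select

__all__ = [
    "RigidTransform",
    "GeometryError",
    "superpose",
    "apply_transform",
    "displacement",
    "helix_tilt",
    "axis_rotation_angle",
    "thickness_along_axis",
    "estimate_pore_axis",
    "rmsd_matrix",
    "BACKBONE_NAMES",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


class GeometryError(ValueError):
    """Degenerate geometry (too few atoms, collinear points, ...)."""


@dataclass
class RigidTransform:
    rot: np.ndarray  # 3x3 proper rotation
    trans: np.ndarray  # 3-vector, Å

    def __post_init__(self) -> None:
        self.rot = np.asarray(self.rot, dtype=float).reshape(3, 3)
        self.trans = np.asarray(self.trans, dtype=float).reshape(3)
        if not np.allclose(self.rot.T @ self.rot, np.eye(3), atol=1e-8):
            raise GeometryError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(self.rot), 1.0, atol=1e-8):
            raise GeometryError("rotation matrix is not proper (det != +1)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self.rot.T + self.trans

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rot @ other.rot, self.rot @ other.trans + self.trans)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def _coords(x) -> np.ndarray:
    if isinstance(x, AtomSet):
        return x.coords()
    return np.asarray(x, dtype=float).reshape(-1, 3)


def superpose(mobile, reference) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Atom sets must be equal length and index-paired.  Returns the proper
    rotation + translation (Kabsch) and the post-fit RMSD in Å.
    """
    P = _coords(mobile)
    Q = _coords(reference)
    if P.shape != Q.shape:
        raise GeometryError(f"length mismatch: {P.shape[0]} vs {Q.shape[0]} atoms")
    if P.shape[0] < 3:
        raise GeometryError("need at least 3 paired atoms for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    tr = RigidTransform(R, t)
    diff = tr.apply(P) - Q
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return tr, rmsd


def apply_transform(s: Structure, tr: RigidTransform, chains: Sequence[str] | None = None) -> Structure:
    """Return a copy of ``s`` with ``tr`` applied to all (or the named) chains."""
    out = s.copy()
    which = set(chains) if chains is not None else None
    for c in out.chains:
        if which is not None and c.id not in which:
            continue
        for r in c.residues:
            for a in r.atoms:
                a.xyz = tr.apply(a.xyz)
    return out


def displacement(
    a: Structure,
    b: Structure,
    probe: tuple[str, int, str],
    frame: dict | None = None,
) -> float:
    """Displacement (Å) of a probe atom between two conformations.

    ``probe`` is (chain_id, res_seq, atom_name).  ``frame`` is a selection
    keyword dict defining the alignment frame (passed to :func:`select` in
    both structures); ``b`` is superposed onto ``a`` with that frame before
    the probe distance is measured.  Printed displacement values depend on
    the frame, which is therefore always explicit.
    """
    chain_id, res_seq, atom_name = probe

    def probe_xyz(s: Structure) -> np.ndarray:
        sel = select(s, chains=[chain_id], res_range=(res_seq, res_seq), atom_names=[atom_name])
        if len(sel) != 1:
            raise SelectionError(f"probe {probe} matched {len(sel)} atoms in {s.id}")
        return sel.atoms[0].xyz

    if frame is not None:
        from .core import paired_sets

        fa, fb = paired_sets(a, b, **frame)
        tr, _ = superpose(fb, fa)
        xb = tr.apply(probe_xyz(b))
    else:
        xb = probe_xyz(b)
    return float(np.linalg.norm(probe_xyz(a) - xb))


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Principal direction of a centered point cloud, oriented first→last."""
    X = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(X, tol=1e-8) < 1 or len(coords) < 3:
        raise GeometryError("degenerate point cloud for axis fit")
    _, _, Vt = np.linalg.svd(X)
    d = Vt[0]
    if d @ (coords[-1] - coords[0]) < 0:  # orient N-terminal → C-terminal
        d = -d
    return d / np.linalg.norm(d)


def helix_tilt(h1, h2) -> float:
    """Angle in degrees between the principal axes of two Cα helices.

    Axes are oriented N→C; the raw angle lies in [0°, 180°).  For matched
    helices values >90° are usually a sign flip; callers wanting the acute
    supplement can take ``min(a, 180 - a)``.
    """
    c1, c2 = _coords(h1), _coords(h2)
    if len(c1) < 5 or len(c2) < 5:
        raise GeometryError("helix axis fit needs at least 5 Cα atoms")
    d1, d2 = _principal_axis(c1), _principal_axis(c2)
    cosang = float(np.clip(d1 @ d2, -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def axis_rotation_angle(t: RigidTransform, axis: np.ndarray) -> float:
    """Signed twist (degrees) of the rotation of ``t`` about ``axis``.

    Swing–twist decomposition: the rotation is split into a twist about the
    axis and a swing perpendicular to it; the twist angle is returned with
    right-hand-rule sign about ``axis``.  With the axis pointing toward the
    extracellular side, positive = counter-clockwise viewed from outside.
    """
    n = np.asarray(axis, dtype=float)
    n = n / np.linalg.norm(n)
    from scipy.spatial.transform import Rotation

    q = Rotation.from_matrix(t.rot).as_quat()  # (x, y, z, w)
    v, w = q[:3], q[3]
    proj = float(v @ n)
    twist = 2.0 * np.arctan2(proj, w)
    # wrap to (-180, 180]
    ang = np.degrees(twist)
    if ang > 180.0:
        ang -= 360.0
    elif ang <= -180.0:
        ang += 360.0
    return float(ang)


def estimate_pore_axis(
    s: Structure,
    ecd_res_range: tuple[int, int] | None = None,
    atom_name: str = "CA",
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the C5 pseudo-symmetry axis of a pentamer.

    For every residue number shared by all five chains, the centroid of the
    five Cα positions lies (for an ideal ring) on the symmetry axis; the
    axis is the least-squares line through these ring centroids.  The
    direction is oriented so the extracellular domain (``ecd_res_range``,
    when given) has the larger axial coordinate; otherwise the +z-leaning
    orientation is kept.
    """
    if len(s.chains) < 5:
        raise GeometryError(f"pore-axis estimate needs 5 chains, got {len(s.chains)}")
    per_chain: list[dict[int, np.ndarray]] = []
    for c in s.chains[:5]:
        d: dict[int, np.ndarray] = {}
        for r in c.residues:
            for a in r.atoms:
                if a.name == atom_name:
                    d[r.seq] = a.xyz
        per_chain.append(d)
    shared = sorted(set.intersection(*(set(d) for d in per_chain)))
    if len(shared) < 2:
        raise GeometryError("fewer than 2 residue rings shared across chains")
    centroids = np.array([np.mean([d[seq] for d in per_chain], axis=0) for seq in shared])
    point = centroids.mean(axis=0)
    _, _, Vt = np.linalg.svd(centroids - point)
    direction = Vt[0] / np.linalg.norm(Vt[0])
    if ecd_res_range is not None:
        lo, hi = ecd_res_range
        in_ecd = [i for i, seq in enumerate(shared) if lo <= seq <= hi]
        out_ecd = [i for i in range(len(shared)) if i not in in_ecd]
        if in_ecd and out_ecd:
            s_ecd = centroids[in_ecd] @ direction
            s_rest = centroids[out_ecd] @ direction
            if s_ecd.mean() < s_rest.mean():
                direction = -direction
    elif direction[2] < 0:
        direction = -direction
    return point, direction


def thickness_along_axis(
    s: Structure,
    res_top: int,
    res_bottom: int,
    axis: tuple[np.ndarray, np.ndarray] | None = None,
    atom_name: str = "CA",
) -> float:
    """Axial thickness between two residue rings (Å).

    The thickness is |mean axial coordinate of the Cα of ``res_top`` over all
    chains − the same for ``res_bottom``|.  With ``axis=None`` the pore axis
    is estimated from the structure, making the measure invariant to global
    rigid motion.
    """
    if axis is None:
        axis = estimate_pore_axis(s)
    _, direction = axis

    def ring_axial(seq: int) -> float:
        vals = []
        for c in s.chains:
            sel = [a for r in c.residues if r.seq == seq for a in r.atoms if a.name == atom_name]
            if not sel:
                raise SelectionError(f"residue {seq} ({atom_name}) missing in chain {c.id}")
            vals.append(sel[0].xyz @ direction)
        return float(np.mean(vals))

    return abs(ring_axial(res_top) - ring_axial(res_bottom))


def _axis_rotation(point: np.ndarray, direction: np.ndarray, deg: float) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(np.radians(deg) * direction).as_matrix()
    return RigidTransform(R, point - R @ point)


def rmsd_matrix(
    s: Structure,
    region: tuple[int, int],
    atom_names: Sequence[str] = BACKBONE_NAMES,
    align: str = "c5_frame",
) -> np.ndarray:
    """Pairwise inter-subunit RMSD matrix (Å) over a residue region.

    With ``align="c5_frame"`` (default) chain j is mapped onto chain i's ring
    position by the ideal cyclic rotation (360/n degrees per position) about
    the estimated pore axis — both handedness signs are tried and the smaller
    RMSD kept — with no further fitting, so the matrix measures deviation of
    the subunit *arrangements* from exact symmetry.  Two groups of subunits
    perturbed by different rigid modes then show a block structure (small
    within-group, large between-group entries).  ``align="superpose"`` is the
    plain per-pair Kabsch RMSD, which instead measures internal conformational
    differences between subunits.
    """
    sets = []
    for c in s.chains:
        sel = select(s, chains=[c.id], res_range=region, atom_names=list(atom_names))
        sets.append(sel.coords())
    n = len(sets)
    lengths = {len(x) for x in sets}
    if len(lengths) != 1:
        raise GeometryError(f"chains have unequal atom counts in region: {lengths}")
    M = np.zeros((n, n))
    if align == "superpose":
        for i in range(n):
            for j in range(i + 1, n):
                _, r = superpose(sets[i], sets[j])
                M[i, j] = M[j, i] = r
        return M
    if align != "c5_frame":
        raise ValueError(f"unknown align mode {align!r}")
    point, direction = estimate_pore_axis(s)
    step_deg = 360.0 / len(s.chains)
    for i in range(n):
        for j in range(i + 1, n):
            vals = []
            for sign in (1.0, -1.0):
                tr = _axis_rotation(point, direction, sign * step_deg * (i - j))
                diff = tr.apply(sets[j]) - sets[i]
                vals.append(float(np.sqrt((diff**2).sum(axis=1).mean())))
            M[i, j] = M[j, i] = min(vals)
    return M
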