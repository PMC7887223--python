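"""Trajectory analyses: hydration counts, ion permeation, RMSF, helix shape.

A :class:`Trajectory` holds per-frame coordinates for three tagged groups —
protein, ions, waters (water = its oxygen position) — plus the pore axis and
frame spacing.  The on-disk contract is a plain-text frames file (one XYZ
block per frame) with an optional protein metadata table; multi-model PDB is
supported as an adapter.  All axial quantities are coordinates along the
pore axis, positive toward the extracellular side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryError, _principal_axis, superpose

__all__ = [
    "Trajectory",
    "PermeationEvent",
    "count_waters_near",
    "detect_permeations",
    "rmsf",
    "bend_profile",
    "shape_classify",
    "write_frames",
    "read_frames",
]


@dataclass
class Trajectory:
    protein: np.ndarray  # (F, Np, 3)
    ions: np.ndarray  # (F, Ni, 3)
    waters: np.ndarray  # (F, Nw, 3), oxygen positions
    dt_ns: float
    axis: tuple[np.ndarray, np.ndarray]  # (point, unit dir), +dir extracellular
    protein_meta: pd.DataFrame | None = None  # chain, res_seq, res_name, name

    def __post_init__(self) -> None:
        self.protein = np.asarray(self.protein, dtype=float)
        self.ions = np.asarray(self.ions, dtype=float)
        self.waters = np.asarray(self.waters, dtype=float)
        if self.dt_ns <= 0:
            raise ValueError("frame spacing must be positive")
        F = self.protein.shape[0]
        for name, arr in (("ions", self.ions), ("waters", self.waters)):
            if arr.shape[0] != F:
                raise ValueError(f"{name} frame count {arr.shape[0]} != protein {F}")

    @property
    def n_frames(self) -> int:
        return self.protein.shape[0]

    def axial(self, coords: np.ndarray) -> np.ndarray:
        point, direction = self.axis
        return (coords - point) @ direction

    def reversed(self) -> "Trajectory":
        return Trajectory(
            self.protein[::-1].copy(), self.ions[::-1].copy(), self.waters[::-1].copy(),
            self.dt_ns, self.axis, self.protein_meta,
        )

    def tail(self, fraction: float = 0.25) -> "Trajectory":
        """Final-window view (default last quarter of frames), the
        stabilised-system convention for production analyses."""
        n = max(1, int(round(self.n_frames * fraction)))
        return Trajectory(
            self.protein[-n:], self.ions[-n:], self.waters[-n:],
            self.dt_ns, self.axis, self.protein_meta,
        )


@dataclass
class PermeationEvent:
    ion_id: int
    entry_frame: int
    exit_frame: int
    direction: int  # +1 toward extracellular, -1 toward intracellular

    def __post_init__(self) -> None:
        if self.entry_frame >= self.exit_frame:
            raise ValueError("entry_frame must precede exit_frame")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


# ---------------------------------------------------------------------------
# Hydration


def count_waters_near(
    t: Trajectory,
    target_res: Sequence[int],
    cutoff: float = 4.0,
    atom_names: Sequence[str] | None = None,
) -> dict:
    """Waters (by oxygen) within ``cutoff`` Å of the target residues, per frame.

    The target is every atom of the named residues across all chains (or only
    ``atom_names`` of them); a water counts if its oxygen is within the
    cutoff of *any* target atom.  Returns per-frame counts, their mean, and a
    histogram over frames.
    """
    if t.protein_meta is None:
        raise ValueError("trajectory has no protein metadata to resolve residues")
    meta = t.protein_meta
    mask = meta["res_seq"].isin(list(target_res)).to_numpy()
    if atom_names is not None:
        mask &= meta["name"].isin(list(atom_names)).to_numpy()
    if not mask.any():
        raise ValueError(f"target residues {list(target_res)} not found in trajectory")
    counts = np.zeros(t.n_frames, dtype=int)
    if t.waters.shape[1] == 0:
        hist = np.bincount(counts)
        return {"counts": counts, "mean": 0.0, "histogram": hist}
    for f in range(t.n_frames):
        tgt = t.protein[f][mask]  # (Nt, 3)
        wat = t.waters[f]  # (Nw, 3)
        d2 = ((wat[:, None, :] - tgt[None, :, :]) ** 2).sum(axis=2)
        counts[f] = int((d2.min(axis=1) <= cutoff**2).sum())
    return {
        "counts": counts,
        "mean": float(counts.mean()),
        "histogram": np.bincount(counts),
    }


# ---------------------------------------------------------------------------
# Permeation


def detect_permeations(t: Trajectory, slab: tuple[float, float]) -> list[PermeationEvent]:
    """Full slab crossings per ion, via a per-ion three-state machine.

    The slab is an axial interval [z_lo, z_hi] along the pore axis.  An event
    is one ion entering through one boundary and later exiting through the
    other (any dwell time); entering and leaving through the same boundary
    records nothing.  A step jumping straight across the slab counts as a
    crossing.  Ions that start inside the slab have no entry boundary and
    their first exit is discarded.
    """
    z_lo, z_hi = slab
    if not z_lo < z_hi:
        raise ValueError("slab requires z_lo < z_hi")
    events: list[PermeationEvent] = []
    if t.ions.shape[1] == 0:
        return events
    z = np.stack([t.axial(t.ions[f]) for f in range(t.n_frames)])  # (F, Ni)
    region = np.where(z < z_lo, -1, np.where(z > z_hi, 1, 0))
    for ion in range(z.shape[1]):
        entry_side: int | None = None  # -1 entered from below, +1 from above
        entry_frame = -1
        prev = int(region[0, ion])
        if prev == 0:
            entry_side = None  # starts inside: unknown entry boundary
        for f in range(1, t.n_frames):
            cur = int(region[f, ion])
            if cur == prev:
                continue
            if prev != 0 and cur == 0:  # entered the slab
                entry_side, entry_frame = prev, f
            elif prev == 0 and cur != 0:  # left the slab
                if entry_side is not None and cur == -entry_side:
                    events.append(PermeationEvent(ion, entry_frame, f, int(cur)))
                entry_side = None
            else:  # jumped straight across (prev and cur on opposite sides)
                events.append(PermeationEvent(ion, f - 1, f, int(cur)))
                entry_side = None
            prev = cur
    return events


# ---------------------------------------------------------------------------
# Fluctuations


def rmsf(
    t: Trajectory,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) about the mean structure.

    Frames are least-squares superposed onto the mean structure using
    ``fit_selection`` (default: all protein atoms), iterating the mean once,
    which removes any global rigid motion.  ``selection``/``fit_selection``
    are boolean masks or index arrays over protein atoms.
    """
    if t.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    X = t.protein.copy()
    n_atoms = X.shape[1]
    fit_idx = np.arange(n_atoms) if fit_selection is None else np.asarray(fit_selection)
    if fit_idx.dtype == bool:
        fit_idx = np.flatnonzero(fit_idx)
    sel_idx = np.arange(n_atoms) if selection is None else np.asarray(selection)
    if sel_idx.dtype == bool:
        sel_idx = np.flatnonzero(sel_idx)

    ref = X[0]
    for _ in range(2):  # fit to running mean, twice
        for f in range(X.shape[0]):
            tr, _ = superpose(X[f][fit_idx], ref[fit_idx])
            X[f] = tr.apply(X[f])
        ref = X.mean(axis=0)
    dev = X[:, sel_idx, :] - ref[sel_idx]
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# Helix shape


def bend_profile(coords: np.ndarray, window: int = 7, smooth: int = 4) -> dict:
    """Per-residue bend angle of a helix and its kink position.

    Cα positions are first smoothed with a ``smooth``-point moving average
    (≈ one helical turn), cancelling the phase wobble of short-segment axis
    fits on an ideal helix.  At residue ``j`` the bend is then the angle
    between the principal axes of the windows [j-window, j] and
    [j, j+window], both oriented N→C.  The kink is the residue of maximal
    bend (ties break toward the smaller index).  Returned positions are
    indices into ``coords``.
    """
    C = np.asarray(coords, dtype=float)
    L = len(C)
    if L < 2 * window + max(smooth, 1):
        raise GeometryError(f"helix of {L} residues too short for window {window}")
    if smooth > 1:
        Cs = np.stack([C[i : L - smooth + 1 + i] for i in range(smooth)]).mean(axis=0)
        offset = (smooth - 1) / 2.0
    else:
        Cs, offset = C, 0.0
    Ls = len(Cs)
    idx = np.arange(window, Ls - window)
    angles = np.empty(len(idx))
    for k, j in enumerate(idx):
        a1 = _principal_axis(Cs[j - window : j + 1])
        a2 = _principal_axis(Cs[j : j + window + 1])
        angles[k] = np.degrees(np.arccos(np.clip(a1 @ a2, -1.0, 1.0)))
    positions = np.round(idx + offset).astype(int)
    kink = int(positions[int(np.argmax(angles))])
    return {"positions": positions, "bend_deg": angles, "kink_position": kink,
            "kink_angle": float(angles.max())}


def shape_classify(
    m2_coords: Sequence[np.ndarray],
    axis: tuple[np.ndarray, np.ndarray],
    delta: float = 1.0,
    end_n: int = 4,
) -> str:
    """Classify the pore-lining helix bundle profile as 'A', 'H' or 'V'.

    For the five pore-lining (M2) helices, compares the mean ring radius of
    the extracellular-end Cα (r_e) with the intracellular end (r_i):
    'A' if r_e < r_i - delta (funnel narrowing outward), 'V' if
    r_i < r_e - delta, 'H' (parallel) otherwise.
    """
    point, direction = axis
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    r_e_vals, r_i_vals = [], []
    for C in m2_coords:
        C = np.asarray(C, dtype=float)
        s = (C - point) @ direction
        radial = np.linalg.norm((C - point) - np.outer(s, direction), axis=1)
        order = np.argsort(s)
        r_i_vals.append(radial[order[:end_n]].mean())
        r_e_vals.append(radial[order[-end_n:]].mean())
    r_e, r_i = float(np.mean(r_e_vals)), float(np.mean(r_i_vals))
    if r_e < r_i - delta:
        return "A"
    if r_i < r_e - delta:
        return "V"
    return "H"


# ---------------------------------------------------------------------------
# I/O: plain-text frames file


def write_frames(t: Trajectory, path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write the trajectory as a plain-text frames file.

    Header lines carry the frame spacing, group sizes and axis; each frame is
    a ``FRAME i`` line followed by protein, then ion, then water XYZ rows
    (one ``x y z`` triple per line, Å, 3 decimals).
    """
    point, direction = t.axis
    with open(path, "w") as fh:
        fh.write("# oligosym-frames 1\n")
        fh.write(f"# dt_ns {t.dt_ns}\n")
        fh.write(
            f"# groups protein={t.protein.shape[1]} ions={t.ions.shape[1]} "
            f"waters={t.waters.shape[1]}\n"
        )
        fh.write("# axis " + " ".join(f"{v:.6f}" for v in (*point, *direction)) + "\n")
        for f in range(t.n_frames):
            fh.write(f"FRAME {f}\n")
            for block in (t.protein[f], t.ions[f], t.waters[f]):
                for row in block:
                    fh.write(f"{row[0]:.3f} {row[1]:.3f} {row[2]:.3f}\n")
    if meta_path is not None and t.protein_meta is not None:
        t.protein_meta.to_csv(meta_path, sep="\t", index=False)


def read_frames(path: str | Path, meta_path: str | Path | None = None) -> Trajectory:
    """Read a trajectory from the plain-text frames format."""
    dt_ns = 1.0
    sizes = {"protein": 0, "ions": 0, "waters": 0}
    axis_vals: list[float] | None = None
    frames: list[np.ndarray] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[0] == "dt_ns":
                    dt_ns = float(parts[1])
                elif parts[0] == "groups":
                    for kv in parts[1:]:
                        k, v = kv.split("=")
                        sizes[k] = int(v)
                elif parts[0] == "axis":
                    axis_vals = [float(x) for x in parts[1:7]]
                continue
            if line.startswith("FRAME"):
                if rows:
                    frames.append(np.array(rows))
                rows = []
                continue
            rows.append([float(x) for x in line.split()])
    if rows:
        frames.append(np.array(rows))
    if not frames:
        raise ValueError(f"no frames in {path}")
    n_p, n_i, n_w = sizes["protein"], sizes["ions"], sizes["waters"]
    total = n_p + n_i + n_w
    arr = np.stack(frames)
    if arr.shape[1] != total:
        raise ValueError(f"frame rows {arr.shape[1]} != declared group total {total}")
    axis = (np.zeros(3), np.array([0.0, 0.0, 1.0]))
    if axis_vals is not None:
        axis = (np.array(axis_vals[:3]), np.array(axis_vals[3:]))
    meta = pd.read_csv(meta_path, sep="\t") if meta_path is not None else None
    return Trajectory(
        arr[:, :n_p], arr[:, n_p : n_p + n_i], arr[:, n_p + n_i :], dt_ns, axis, meta
    )
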