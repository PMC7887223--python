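"""Synthetic ground-truth inputs for every analysis stage.

The generator emulates, at desk scale, the three data classes the pipeline
consumes:

* an ideal C5 pentamer of four-helix transmembrane bundles (Cα-only), with
  per-subunit rigid perturbations in two modes — "major rotation / minor
  shift" and "minor rotation / major shift" — mirroring the two subunit
  rearrangement modes seen on agonist binding;
* per-subunit class tables drawn from a declared ring-configuration
  distribution with optional misclassification noise, standing in for the
  symmetry-expansion / 3D-classification output;
* ion/water trajectories through a cylindrical pore realizing an exact,
  planned number of full slab crossings plus aborted entries.

Everything is seeded and bitwise reproducible; random streams are
per-purpose so adding one consumer never shifts another's stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AtomRecord, Chain, Residue, Structure
from .geometry import RigidTransform
from .symconfig import canonical_form
from .traj import PermeationEvent, Trajectory

__all__ = [
    "HelixSpec",
    "PentamerSpec",
    "SubunitMode",
    "TrajectorySpec",
    "build_pentamer",
    "apply_subunit_modes",
    "DEFAULT_MODES",
    "DEFAULT_CONFIG_DIST",
    "DEFAULT_DEVIATION_SCALE",
    "two_state_dist",
    "sample_class_table",
    "sample_ion_trajectory",
]

# textbook α-helix: 1.5 Å rise and 100° turn per residue, Cα circle radius 2.3 Å


@dataclass(frozen=True)
class HelixSpec:
    rise: float = 1.5  # Å per residue
    twist: float = 100.0  # degrees per residue
    ca_radius: float = 2.3  # Å, Cα distance from the helix axis
    length: int = 27  # residues; span 39 Å ≈ a lipid-embedded TMD helix


@dataclass(frozen=True)
class PentamerSpec:
    helix: HelixSpec = HelixSpec()
    #: distance of each helix axis from the pore axis, Å (M1..M4; M2 innermost)
    helix_ring_radii: tuple[float, ...] = (12.0, 8.0, 12.0, 16.0)
    #: angular offset of each helix from the subunit centre line, degrees
    helix_angle_offsets: tuple[float, ...] = (-16.0, 0.0, 16.0, 0.0)
    #: first residue number of each helix (author-style numbering, shared
    #: across chains); M2 carries the pore-lining numbering
    helix_first_res: tuple[int, ...] = (221, 251, 281, 311)
    ca_vdw: float = 2.3  # effective pseudo-atom radius for pore clearance
    chain_ids: tuple[str, ...] = ("A", "B", "C", "D", "E")

    @property
    def inner_ca_ring_radius(self) -> float:
        """Closest approach of the pore-lining helix Cα to the pore axis."""
        return self.helix_ring_radii[1] - self.helix.ca_radius


@dataclass(frozen=True)
class SubunitMode:
    """Rigid perturbation of one subunit: twist about its own (vertical)
    bundle axis, radial shift away from the pore axis, extra translation."""

    twist_deg: float = 0.0
    radial_shift: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)


#: the two rearrangement modes: chains A/C major rotation / minor shift,
#: chains B/D/E minor rotation / major shift
DEFAULT_MODES: dict[str, SubunitMode] = {
    "A": SubunitMode(12.0, 0.5),
    "C": SubunitMode(12.0, 0.5),
    "B": SubunitMode(3.0, 2.0),
    "D": SubunitMode(3.0, 2.0),
    "E": SubunitMode(3.0, 2.0),
}

#: Ring-configuration weights for the agonist-bound more/less-open ('M'/'L')
#: alphabet.  Only the top class (LLMLM ≙ 'LMLML', 24 %) is an externally
#: reported population; the rest are package defaults chosen so that
#: non-consecutive M arrangements outweigh consecutive ones of equal M count.
DEFAULT_CONFIG_DIST: dict[str, float] = {
    "LLLLL": 0.10,
    "LLLLM": 0.18,
    "LLLMM": 0.10,  # two consecutive M
    "LLMLM": 0.24,  # two non-consecutive M (consensus arrangement)
    "LLMMM": 0.07,  # three consecutive M
    "LMLMM": 0.15,  # three M, not all consecutive
    "LMMMM": 0.09,
    "MMMMM": 0.07,
}

#: Per-monomer-class deviation scale (Å) for the apo asymmetric classes,
#: a monotone stand-in for the reported ranking A < E < C < D < B.
DEFAULT_DEVIATION_SCALE: dict[str, float] = {
    "A": 0.4,
    "E": 0.8,
    "C": 1.2,
    "D": 1.6,
    "B": 2.0,
}


def two_state_dist(p_symmetric: float = 0.61) -> dict[str, float]:
    """Two-configuration mixture: a symmetric ring vs the consensus
    asymmetric arrangement, at the apo symmetric/asymmetric split (61/39)."""
    return {"LLLLL": p_symmetric, "LLMLM": 1.0 - p_symmetric}


# ---------------------------------------------------------------------------
# Pentamer construction


def _ideal_helix(spec: HelixSpec, phase_deg: float = 0.0) -> np.ndarray:
    i = np.arange(spec.length)
    ang = np.radians(phase_deg + spec.twist * i)
    z = spec.rise * (i - (spec.length - 1) / 2.0)
    return np.stack(
        [spec.ca_radius * np.cos(ang), spec.ca_radius * np.sin(ang), z], axis=1
    )


def build_pentamer(spec: PentamerSpec | None = None) -> Structure:
    """Ideal C5 pentamer of four-helix Cα bundles around the z axis.

    All chains share residue numbering; every Cα carries the effective
    pseudo-atom vdW radius so pore profiles run without a radius table.
    """
    spec = spec or PentamerSpec()
    st = Structure("synthetic-pentamer", axis_hint=(np.zeros(3), np.array([0.0, 0.0, 1.0])))
    serial = 0
    for k, cid in enumerate(spec.chain_ids):
        subunit_angle = 72.0 * k
        chain = Chain(cid)
        for h, (ring_r, ang_off, first_res) in enumerate(
            zip(spec.helix_ring_radii, spec.helix_angle_offsets, spec.helix_first_res)
        ):
            phi = np.radians(subunit_angle + ang_off)
            center = np.array([ring_r * np.cos(phi), ring_r * np.sin(phi), 0.0])
            local = _ideal_helix(spec.helix, phase_deg=subunit_angle + 40.0 * h)
            for j, xyz in enumerate(local + center):
                serial += 1
                res = Residue("ALA", first_res + j, "")
                res.atoms.append(
                    AtomRecord(
                        serial=serial,
                        name="CA",
                        element="C",
                        res_name="ALA",
                        res_seq=first_res + j,
                        chain_id=cid,
                        xyz=xyz,
                        vdw=spec.ca_vdw,
                    )
                )
                chain.residues.append(res)
        st.chains.append(chain)
    return st


def apply_subunit_modes(
    s: Structure, modes: Mapping[str, SubunitMode] | None = None
) -> tuple[Structure, dict[str, RigidTransform]]:
    """Apply per-subunit rigid perturbations; return the perturbed structure
    and the ground-truth transform of each chain.

    The twist acts about the subunit's own vertical bundle axis (through its
    centroid); the radial shift acts outward from the pore (z) axis.
    """
    modes = DEFAULT_MODES if modes is None else modes
    out = s.copy()
    truth: dict[str, RigidTransform] = {}
    for chain in out.chains:
        mode = modes.get(chain.id, SubunitMode())
        coords = np.array([a.xyz for r in chain.residues for a in r.atoms])
        centroid = coords.mean(axis=0)
        th = np.radians(mode.twist_deg)
        c, sn = np.cos(th), np.sin(th)
        R = np.array([[c, -sn, 0.0], [sn, c, 0.0], [0.0, 0.0, 1.0]])
        radial_dir = np.array([centroid[0], centroid[1], 0.0])
        nrm = np.linalg.norm(radial_dir)
        radial_dir = radial_dir / nrm if nrm > 0 else np.zeros(3)
        t = (
            centroid
            - R @ centroid
            + mode.radial_shift * radial_dir
            + np.asarray(mode.translation, dtype=float)
        )
        tr = RigidTransform(R, t)
        truth[chain.id] = tr
        for r in chain.residues:
            for a in r.atoms:
                a.xyz = tr.apply(a.xyz)
    return out, truth


# ---------------------------------------------------------------------------
# Class tables


def sample_class_table(
    n_particles: int,
    config_dist: Mapping[str, float] | None = None,
    confusion: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-subunit class tables from a ring-configuration distribution.

    For each particle a canonical configuration is drawn from ``config_dist``,
    a uniform random ring rotation is applied (the starting subunit of a
    symmetry-expanded particle is arbitrary), and each subunit label is then
    misassigned according to the ``confusion`` row of its true label
    (identity when omitted).  Returns (observed, truth) tables with columns
    particle_id, subunit_index, class_label.
    """
    dist = dict(DEFAULT_CONFIG_DIST if config_dist is None else config_dist)
    configs = sorted(dist)
    probs = np.array([dist[c] for c in configs], dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-9):
        raise ValueError(f"configuration probabilities sum to {probs.sum()}, not 1")
    for c in configs:
        if tuple(c) != canonical_form(tuple(c)):
            raise ValueError(f"distribution key {c!r} is not in canonical form")

    rng_cfg = np.random.default_rng([101, seed])
    rng_rot = np.random.default_rng([102, seed])
    rng_cls = np.random.default_rng([103, seed])

    draw = rng_cfg.choice(len(configs), size=n_particles, p=probs)
    rots = rng_rot.integers(0, 5, size=n_particles)

    labels_all = sorted({l for c in configs for l in c})
    conf_rows: dict[str, tuple[list[str], np.ndarray]] = {}
    if confusion is not None:
        for lab, row in confusion.items():
            targets = sorted(row)
            p = np.array([row[t] for t in targets], dtype=float)
            if not np.isclose(p.sum(), 1.0, atol=1e-9):
                raise ValueError(f"confusion row for {lab!r} sums to {p.sum()}")
            conf_rows[lab] = (targets, p)
        for lab in labels_all:
            if lab not in conf_rows:
                raise ValueError(f"confusion matrix missing row for label {lab!r}")

    recs_obs, recs_true = [], []
    for i in range(n_particles):
        cfg = configs[draw[i]]
        r = int(rots[i])
        ring = cfg[r:] + cfg[:r]
        pid = f"p{i:06d}"
        for pos, lab in enumerate(ring):
            obs = lab
            if conf_rows:
                targets, p = conf_rows[lab]
                obs = targets[int(rng_cls.choice(len(targets), p=p))]
            recs_true.append((pid, pos, lab))
            recs_obs.append((pid, pos, obs))
    cols = ["particle_id", "subunit_index", "class_label"]
    return pd.DataFrame(recs_obs, columns=cols), pd.DataFrame(recs_true, columns=cols)


# ---------------------------------------------------------------------------
# Trajectories


@dataclass(frozen=True)
class TrajectorySpec:
    n_frames: int = 1000  # 200 ns at 0.2 ns spacing
    dt_ns: float = 0.2
    slab: tuple[float, float] = (-20.0, 20.0)  # TMD axial span, Å
    n_up: int = 2  # planned full crossings toward the extracellular side
    n_down: int = 2
    n_aborted: int = 6  # entries that return through the same boundary
    n_idle_ions: int = 4  # reservoir ions that never enter
    noise_sigma: float = 0.5  # Å per-frame positional noise on ion paths
    crossing_frames: int = 12  # ≈ 2.4 ns per crossing at 0.2 ns spacing
    reservoir_depth: float = 15.0  # Å of bulk on each side of the slab
    water_lambda: float = 3.0  # Poisson mean of in-range waters per frame
    water_cutoff: float = 4.0  # Å; matches the hydration analysis default
    n_background_waters: int = 20
    protein_jitter: float = 0.0  # Å iid Gaussian per-axis protein jitter
    seed: int = 0


def _reservoir_walk(rng, n, lo, hi, sigma):
    z = np.empty(n)
    z[0] = rng.uniform(lo, hi)
    steps = rng.normal(0.0, sigma, size=n - 1)
    for i in range(1, n):
        z[i] = z[i - 1] + steps[i - 1]
        # reflect into [lo, hi]
        while z[i] < lo or z[i] > hi:
            if z[i] < lo:
                z[i] = 2 * lo - z[i]
            if z[i] > hi:
                z[i] = 2 * hi - z[i]
    return z


def _monotone_path(rng, n, start, end, sigma):
    """Noisy but strictly monotone path from start to end (inclusive)."""
    u = np.linspace(0.0, 1.0, n) + rng.normal(0.0, sigma / max(abs(end - start), 1e-9), n)
    u = np.maximum.accumulate(u)
    u = (u - u[0]) / max(u[-1] - u[0], 1e-12)
    return start + (end - start) * u


def sample_ion_trajectory(
    spec: TrajectorySpec | None = None,
    pentamer: Structure | None = None,
) -> tuple[Trajectory, list[PermeationEvent]]:
    """Generate a trajectory realizing an exact planned number of crossings.

    Each planned crossing gets its own ion and a private time window: the ion
    waits in one reservoir, traverses the slab on a noisy monotone path (no
    recrossing by construction), and settles in the far reservoir.  Aborted
    entries penetrate at most half-way and return through the same boundary.
    Waters are placed so the count within ``water_cutoff`` of the pore-lining
    gate residues is Poisson(``water_lambda``) per frame, with background
    waters parked in bulk.  Returns the trajectory and ground-truth events.
    """
    spec = spec or TrajectorySpec()
    z_lo, z_hi = spec.slab
    F = spec.n_frames
    rng = np.random.default_rng([201, spec.seed])
    rng_w = np.random.default_rng([202, spec.seed])

    from .core import select

    structure = pentamer if pentamer is not None else build_pentamer()
    prot_atoms = select(structure)
    prot0 = prot_atoms.coords()
    meta = pd.DataFrame(
        {
            "chain": [a.chain_id for a in prot_atoms],
            "res_seq": [a.res_seq for a in prot_atoms],
            "res_name": [a.res_name for a in prot_atoms],
            "name": [a.name for a in prot_atoms],
        }
    )

    n_cross = spec.n_up + spec.n_down
    if n_cross > 0 and spec.crossing_frames * n_cross > F:
        raise ValueError(
            f"plan infeasible: {n_cross} crossings of {spec.crossing_frames} frames "
            f"do not fit in {F} frames"
        )
    n_ions = n_cross + spec.n_aborted + spec.n_idle_ions
    zs = np.zeros((F, max(n_ions, 1)))
    events: list[PermeationEvent] = []

    bottom = (z_lo - spec.reservoir_depth, z_lo - 1.5)
    top = (z_hi + 1.5, z_hi + spec.reservoir_depth)

    directions = [1] * spec.n_up + [-1] * spec.n_down
    rng.shuffle(directions)
    for i, direction in enumerate(directions):
        # private window for this ion's crossing
        w0 = int(round((i + 0.5) * F / max(n_cross, 1))) - spec.crossing_frames // 2
        w0 = max(1, min(F - spec.crossing_frames - 1, w0))
        w1 = w0 + spec.crossing_frames
        src, dst = (bottom, top) if direction == 1 else (top, bottom)
        start = src[1] if direction == 1 else src[0]
        end = dst[0] if direction == 1 else dst[1]
        zs[:w0, i] = _reservoir_walk(rng, w0, *src, spec.noise_sigma)
        zs[w0 - 1, i] = start  # stitch
        zs[w0:w1, i] = _monotone_path(rng, w1 - w0, start, end, spec.noise_sigma)
        zs[w1:, i] = _reservoir_walk(rng, F - w1, *dst, spec.noise_sigma)
        zs[w1, i] = end
        inside = (zs[:, i] >= z_lo) & (zs[:, i] <= z_hi)
        entry = int(np.argmax(inside))
        exit_ = int(len(inside) - np.argmax(inside[::-1]))
        events.append(PermeationEvent(i, max(entry, 1), exit_, direction))

    for j in range(spec.n_aborted):
        i = n_cross + j
        from_below = j % 2 == 0
        w0 = int(round((j + 0.5) * F / max(spec.n_aborted, 1)))
        w0 = max(1, min(F - spec.crossing_frames - 1, w0))
        w1 = w0 + spec.crossing_frames
        res = bottom if from_below else top
        zs[:w0, i] = _reservoir_walk(rng, w0, *res, spec.noise_sigma)
        depth = 0.5 * (z_hi - z_lo)
        u = np.sin(np.pi * np.linspace(0.0, 1.0, w1 - w0))
        base = (z_lo - 1.0) + (depth + 1.0) * u if from_below else (z_hi + 1.0) - (depth + 1.0) * u
        wig = rng.normal(0.0, spec.noise_sigma, size=w1 - w0)
        path = np.clip(base + wig, bottom[0], z_hi - 1.0) if from_below else np.clip(
            base + wig, z_lo + 1.0, top[1]
        )
        zs[w0:w1, i] = path
        zs[w1:, i] = _reservoir_walk(rng, F - w1, *res, spec.noise_sigma)

    for j in range(spec.n_idle_ions):
        i = n_cross + spec.n_aborted + j
        res = bottom if j % 2 == 0 else top
        zs[:, i] = _reservoir_walk(rng, F, *res, spec.noise_sigma)

    xy = rng.normal(0.0, 1.5, size=(F, n_ions, 2)) if n_ions else np.zeros((F, 0, 2))
    ions = np.concatenate([xy, zs[:, :n_ions, None]], axis=2) if n_ions else np.zeros((F, 0, 3))

    # waters: exact in-range placement near the gate ring of the inner helix
    gate_res = int(np.median(meta.loc[meta["res_seq"].between(251, 277), "res_seq"])) if (
        meta["res_seq"].between(251, 277).any()
    ) else int(meta["res_seq"].median())
    tgt_idx = np.flatnonzero((meta["res_seq"] == gate_res).to_numpy())
    n_in = rng_w.poisson(spec.water_lambda, size=F)
    w_max = int(n_in.max(initial=0)) + spec.n_background_waters
    waters = np.zeros((F, w_max, 3))
    park = np.array([0.0, 0.0, z_hi + spec.reservoir_depth + 50.0])
    for f in range(F):
        k = int(n_in[f])
        if k:
            picks = rng_w.integers(0, len(tgt_idx), size=k)
            dirs = rng_w.normal(size=(k, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            dist = rng_w.uniform(0.3, 0.95 * spec.water_cutoff, size=k)
            waters[f, :k] = prot0[tgt_idx[picks]] + dirs * dist[:, None]
        waters[f, k:] = park + rng_w.normal(0.0, 2.0, size=(w_max - k, 3))

    if spec.protein_jitter > 0:
        prot = prot0[None] + rng.normal(0.0, spec.protein_jitter, size=(F, *prot0.shape))
    else:
        prot = np.broadcast_to(prot0, (F, *prot0.shape)).copy()

    traj = Trajectory(
        prot, ions, waters, spec.dt_ns,
        axis=(np.zeros(3), np.array([0.0, 0.0, 1.0])),
        protein_meta=meta,
    )
    return traj, events
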