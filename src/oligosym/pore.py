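"""HOLE-style maximal-sphere pore-radius profile along a channel axis.

At each plane perpendicular to the pore axis the profiler finds the point
``p`` maximizing the clearance

    f(p) = min_i ( ||p - x_i|| - vdw_i )

over the atoms ``x_i`` with van der Waals radii ``vdw_i``; the profile value
R(S) = f(p*) is the radius of the largest sphere centred in that plane that
touches no atom.  Optimization is multi-start local (Nelder–Mead) seeded from
the neighbouring plane's centre plus deterministic pseudo-random offsets, with
an up-then-down sweep whose per-plane best is kept, which resolves hourglass
entrapment.  Radii of interest here span roughly 1–10 Å: a hydrated sodium
ion has radius 2.76 Å, and reported conductance bands are <1.8 Å
(sub-conductive), 1.8–3.3 Å (intermediate) and >3.3 Å (wide).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .core import AtomSet

__all__ = [
    "PoreProfile",
    "PoreSample",
    "PoreOptions",
    "ConstrictionError",
    "compute_profile",
    "min_constriction",
    "classify_profile",
    "HYDRATED_NA_RADIUS",
    "BAND_SUB",
    "BAND_WIDE",
]

#: radius of a hydrated sodium ion, Å
HYDRATED_NA_RADIUS = 2.76
#: conductance-band thresholds, Å
BAND_SUB = 1.8
BAND_WIDE = 3.3


class ConstrictionError(ValueError):
    """No converged sample available in the requested window."""


@dataclass
class PoreSample:
    s: float  # axial coordinate, Å
    center: np.ndarray  # 3-vector
    radius: float  # Å
    converged: bool
    unbounded: bool = False


@dataclass
class PoreOptions:
    step: float = 0.25  # Å between planes
    starts: int = 16  # pseudo-random restarts per plane
    seed: int = 0  # seed for the restart offsets
    max_jump: float = 1.0  # Å; larger centre jumps flag the sample
    track_radius: float = 2.5  # Å restart/acceptance disc around the previous centre
    disc_radius: float = 12.0  # Å hard bound on centre distance from the axis
    r_max: float = 15.0  # Å cap; beyond this the pore is open bulk
    exclude_hydrogens: bool = True


@dataclass
class PoreProfile:
    axis: tuple[np.ndarray, np.ndarray]  # (point, unit dir)
    samples: list[PoreSample] = field(default_factory=list)
    step: float = 0.25

    @property
    def s_values(self) -> np.ndarray:
        return np.array([x.s for x in self.samples])

    @property
    def radii(self) -> np.ndarray:
        return np.array([x.radius for x in self.samples])

    @property
    def converged(self) -> np.ndarray:
        return np.array([x.converged for x in self.samples], dtype=bool)


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _atom_arrays(atoms: AtomSet, exclude_hydrogens: bool) -> tuple[np.ndarray, np.ndarray]:
    xyz = atoms.coords()
    rad = atoms.radii()
    if exclude_hydrogens:
        keep = np.array([a.element.upper() != "H" for a in atoms.atoms], dtype=bool)
        xyz, rad = xyz[keep], rad[keep]
    return xyz, rad


def compute_profile(
    atoms: AtomSet,
    axis: tuple[np.ndarray, np.ndarray],
    s_range: tuple[float, float],
    opts: PoreOptions | None = None,
) -> PoreProfile:
    """Maximal-sphere radius profile of ``atoms`` along ``axis``.

    Planes are placed every ``opts.step`` Å across ``s_range`` (inclusive).
    Within each plane the clearance is maximized by Nelder–Mead from the
    previous plane's centre plus ``opts.starts`` deterministic pseudo-random
    offsets; the sweep runs up then down the axis and keeps the per-plane
    best.  Samples whose best clearance exceeds ``opts.r_max`` are capped and
    flagged unbounded; samples whose centre jumps more than ``opts.max_jump``
    from the neighbouring sample are flagged unconverged.
    """
    opts = opts or PoreOptions()
    if opts.step <= 0:
        raise ValueError("step must be positive")
    point = np.asarray(axis[0], dtype=float)
    direction = np.asarray(axis[1], dtype=float)
    direction = direction / np.linalg.norm(direction)
    u, v = _plane_basis(direction)
    xyz, rad = _atom_arrays(atoms, opts.exclude_hydrogens)
    if len(xyz) == 0:
        raise ValueError("no atoms to profile")
    s_atoms = (xyz - point) @ direction
    lo, hi = float(s_range[0]), float(s_range[1])
    n_planes = int(round((hi - lo) / opts.step)) + 1
    s_grid = lo + opts.step * np.arange(n_planes)

    rng = np.random.default_rng(opts.seed)
    # deterministic restart offsets, drawn once so plane count never shifts them
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(n_planes, opts.starts))
    radii_frac = np.sqrt(rng.uniform(0.0, 1.0, size=(n_planes, opts.starts)))

    axial_cut = opts.r_max + float(rad.max()) + 1.0

    def solve_plane(i: int, prev_xy: np.ndarray) -> tuple[np.ndarray, float]:
        s = s_grid[i]
        near = np.abs(s_atoms - s) <= axial_cut
        if not near.any():
            return prev_xy, np.inf
        ax, ar = xyz[near], rad[near]
        origin = point + s * direction

        def clearance(xy: np.ndarray) -> float:
            p = origin + xy[0] * u + xy[1] * v
            return float(np.min(np.linalg.norm(ax - p, axis=1) - ar))

        def neg_obj(xy: np.ndarray) -> float:
            # keep the track near the previous centre and inside the channel
            pen = max(0.0, float(np.hypot(*(xy - prev_xy))) - opts.track_radius)
            pen += max(0.0, float(np.hypot(*xy)) - opts.disc_radius)
            return -(clearance(xy) - 10.0 * pen)

        best_xy, best_f = prev_xy, clearance(prev_xy)
        offs = np.stack(
            [
                radii_frac[i] * opts.track_radius * np.cos(angles[i]),
                radii_frac[i] * opts.track_radius * np.sin(angles[i]),
            ],
            axis=1,
        )
        for x0 in np.vstack([prev_xy, prev_xy + offs]):
            res = minimize(
                neg_obj, x0, method="Nelder-Mead",
                options={"xatol": 1e-3, "fatol": 1e-5, "maxiter": 150},
            )
            f = clearance(res.x)
            if (
                f > best_f
                and np.hypot(*(res.x - prev_xy)) <= opts.track_radius + 1e-9
                and np.hypot(*res.x) <= opts.disc_radius + 1e-9
            ):
                best_xy, best_f = res.x, f
        return best_xy, best_f

    def sweep(order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centers = np.zeros((n_planes, 2))
        values = np.full(n_planes, -np.inf)
        prev = np.zeros(2)
        for i in order:
            c, f = solve_plane(int(i), prev)
            centers[i], values[i] = c, f
            if np.isfinite(f):
                prev = c
        return centers, values

    up_c, up_f = sweep(np.arange(n_planes))
    dn_c, dn_f = sweep(np.arange(n_planes)[::-1])
    use_dn = dn_f > up_f
    centers = np.where(use_dn[:, None], dn_c, up_c)
    values = np.where(use_dn, dn_f, up_f)

    samples: list[PoreSample] = []
    for i in range(n_planes):
        s = float(s_grid[i])
        c3 = point + s * direction + centers[i, 0] * u + centers[i, 1] * v
        r = float(values[i])
        unbounded = (not np.isfinite(r)) or r > opts.r_max
        if unbounded:
            r = opts.r_max
        converged = not unbounded
        if i > 0:
            jump = float(np.linalg.norm(centers[i] - centers[i - 1]))
            if jump > opts.max_jump:
                converged = False
        samples.append(PoreSample(s, c3, r, converged, unbounded))
    return PoreProfile(axis=(point, direction), samples=samples, step=opts.step)


def min_constriction(
    profile: PoreProfile,
    atoms: AtomSet,
    window: tuple[float, float] | None = None,
    lining_slack: float = 0.5,
    n_lining: int = 3,
) -> dict:
    """Locate the constriction: the converged sample of minimal radius.

    Returns a dict with the axial position ``s``, radius, diameter, and the
    ``n_lining`` residues nearest the maximal sphere (atoms whose distance to
    the sphere surface is within ``lining_slack`` Å of the minimum).  Ties in
    radius break toward the smallest axial coordinate.
    """
    cands = [x for x in profile.samples if x.converged]
    if window is not None:
        lo, hi = window
        cands = [x for x in cands if lo <= x.s <= hi]
    if not cands:
        raise ConstrictionError(f"no converged profile sample in window {window}")
    best = min(cands, key=lambda x: (round(x.radius, 9), x.s))
    xyz = atoms.coords()
    rad = atoms.radii()
    clear = np.linalg.norm(xyz - best.center, axis=1) - rad
    order = np.argsort(clear)
    lining: list[tuple[str, int, str, float]] = []
    seen: set[tuple[str, int]] = set()
    for idx in order:
        if clear[idx] > best.radius + lining_slack and len(lining) >= n_lining:
            break
        a = atoms.atoms[int(idx)]
        key = (a.chain_id, a.res_seq)
        if key in seen:
            continue
        seen.add(key)
        lining.append((a.chain_id, a.res_seq, a.res_name, float(clear[idx])))
        if len(lining) >= n_lining:
            break
    return {
        "s": best.s,
        "radius": best.radius,
        "diameter": 2.0 * best.radius,
        "lining": lining,
    }


def classify_profile(
    profile: PoreProfile,
    band_sub: float = BAND_SUB,
    band_wide: float = BAND_WIDE,
    ion_radius: float = HYDRATED_NA_RADIUS,
) -> list[dict]:
    """Label each sample by conductance band and hydrated-Na⁺ passability.

    Bands are closed on the left: R < band_sub → ``sub-conductive``,
    band_sub ≤ R ≤ band_wide → ``intermediate``, R > band_wide → ``wide``.
    ``passes_hydrated_na`` is R ≥ ion_radius.
    """
    out = []
    for x in profile.samples:
        if x.radius < band_sub:
            band = "sub-conductive"
        elif x.radius <= band_wide:
            band = "intermediate"
        else:
            band = "wide"
        out.append(
            {
                "s": x.s,
                "radius": x.radius,
                "band": band,
                "passes_hydrated_na": bool(x.radius >= ion_radius),
                "converged": x.converged,
            }
        )
    return out


def profile_stack_stats(profiles: Sequence[PoreProfile]) -> dict:
    """Mean ± sd radius per axial position over per-frame profiles."""
    if not profiles:
        raise ValueError("no profiles")
    s = profiles[0].s_values
    R = np.stack([p.radii for p in profiles])
    return {"s": s, "mean": R.mean(axis=0), "sd": R.std(axis=0, ddof=0)}
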