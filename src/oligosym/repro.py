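"""Measurement table for the deposited receptor models.

Given locally supplied coordinate files of the lipid-disc and detergent
5-HT3A receptor models, recomputes the printed comparison quantities: TMD
thickness between the L221 and W426 Cα rings, probe-atom displacements
(W426, W320) between conformations, the extracellular-domain twist about the
pore axis on agonist binding, and the minimum transmembrane pore diameter
with its lining residues.

Because published displacement values depend on the (unstated) superposition
frame, :func:`displacement_frame_scan` evaluates the plausible frames —
same-subunit ECD, whole-pentamer ECD, whole pentamer — and reports each.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import core, geometry, pore

#: ECD span in author numbering (mature sequence; pre-M1 begins ~217)
ECD_RANGE = (10, 200)
#: TMD window in author numbering (L221 at the top of M1, W426 on M4/MA)
TMD_RANGE = (221, 426)

FRAMES = {
    "same_subunit_ecd": "per-chain ECD Cα",
    "whole_ecd": "all-chain ECD Cα",
    "whole_pentamer": "all-chain Cα",
}


def load_model(path: str | Path, accession: str | None = None) -> core.Structure:
    s = core.read_structure(path, id=accession)
    return core.assign_radii(s)


def tmd_thickness(s: core.Structure) -> float:
    return geometry.thickness_along_axis(s, TMD_RANGE[0], TMD_RANGE[1])


def displacement_frame_scan(
    a: core.Structure, b: core.Structure, probe: tuple[str, int, str]
) -> dict[str, float]:
    """Probe displacement under each candidate superposition frame."""
    chain = probe[0]
    out = {}
    frames = {
        "same_subunit_ecd": dict(chains=[chain], res_range=ECD_RANGE, atom_names=["CA"]),
        "whole_ecd": dict(res_range=ECD_RANGE, atom_names=["CA"]),
        "whole_pentamer": dict(atom_names=["CA"]),
    }
    for name, frame in frames.items():
        try:
            out[name] = geometry.displacement(a, b, probe, frame=frame)
        except (core.SelectionError, geometry.GeometryError):
            out[name] = float("nan")
    return out


def ecd_twist(apo: core.Structure, bound: core.Structure) -> float:
    """ECD rotation (degrees) about the pore axis, apo → agonist-bound.

    Positive = counter-clockwise viewed from the extracellular side (the
    axis points extracellular).
    """
    point, direction = geometry.estimate_pore_axis(apo, ecd_res_range=ECD_RANGE)
    fa, fb = core.paired_sets(apo, bound, res_range=ECD_RANGE, atom_names=["CA"])
    tr, _ = geometry.superpose(fa, fb)  # transform taking apo ECD onto bound ECD
    return geometry.axis_rotation_angle(tr, direction)


def tmd_min_diameter(s: core.Structure, seed: int = 0) -> dict:
    """Minimum pore diameter in the TMD window, with lining residues."""
    axis = geometry.estimate_pore_axis(s, ecd_res_range=ECD_RANGE)
    atoms = core.select(s)
    # axial extent of the TMD ring residues defines the search window
    point, direction = axis
    svals = []
    for seq in TMD_RANGE:
        sel = core.select(s, res_range=(seq, seq), atom_names=["CA"])
        svals.append(float(np.mean((sel.coords() - point) @ direction)))
    lo, hi = sorted(svals)
    prof = pore.compute_profile(atoms, axis, (lo, hi), pore.PoreOptions(seed=seed))
    return pore.min_constriction(prof, atoms, window=(lo, hi))


def reproduce_measurements(paths: Mapping[str, str | Path]) -> pd.DataFrame:
    """Full measurement table over the supplied accession → path mapping."""
    models = {acc: load_model(p, acc) for acc, p in paths.items()}
    rows: list[dict] = []

    for acc in ("6Y5A", "6DG8", "6HIN", "6BE1", "6Y59"):
        if acc in models:
            rows.append(
                {"measurement": "tmd_thickness_A", "model": acc,
                 "value": round(tmd_thickness(models[acc]), 3)}
            )

    for acc in ("6Y5A", "6DG8"):
        if acc in models:
            mc = tmd_min_diameter(models[acc])
            rows.append({"measurement": "min_tmd_diameter_A", "model": acc,
                         "value": round(mc["diameter"], 3),
                         "detail": ";".join(f"{c}:{r}:{n}" for c, r, n, _ in mc["lining"])})

    if "6Y59" in models and "6BE1" in models:
        for probe_res in (426, 320):
            for ch in models["6Y59"].chain_ids:
                scan = displacement_frame_scan(models["6Y59"], models["6BE1"], (ch, probe_res, "CA"))
                for frame, val in scan.items():
                    rows.append({"measurement": f"displacement_W{probe_res}_A",
                                 "model": f"6Y59vs6BE1/{ch}", "frame": frame,
                                 "value": round(val, 3)})

    if "6Y5A" in models and "6DG8" in models:
        for ch in models["6Y5A"].chain_ids:
            scan = displacement_frame_scan(models["6Y5A"], models["6DG8"], (ch, 320, "CA"))
            rows.append({"measurement": "displacement_W320_A",
                         "model": f"6Y5Avs6DG8/{ch}", "frame": "same_subunit_ecd",
                         "value": round(scan["same_subunit_ecd"], 3)})

    if "6Y59" in models and "6Y5A" in models:
        rows.append({"measurement": "ecd_twist_deg", "model": "6Y59to6Y5A",
                     "value": round(ecd_twist(models["6Y59"], models["6Y5A"]), 2)})

    return pd.DataFrame(rows)
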