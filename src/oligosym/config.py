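"""Run configuration and the pipeline driver behind the command line.

A :class:`RunConfig` is a strictly validated (unknown keys rejected) flat
per-stage configuration; :func:`run_pipeline` executes the requested stages
and writes TSV/JSON artifacts plus a run log echoing the effective
configuration.  Float formatting in TSVs is fixed (3 decimals for Å, 1 for
degrees) so re-running an identical configuration yields byte-identical
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from . import __version__

__all__ = ["RunConfig", "PoreStage", "CompareStage", "TallyStage", "run_pipeline", "defaults_dict"]

ANG = "{:.3f}"  # Å
DEG = "{:.1f}"  # degrees


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PoreStage(_Strict):
    model: str
    s_range: tuple[float, float] = (-30.0, 60.0)
    step: float = 0.25
    starts: int = 16
    axis: Literal["auto"] | tuple[float, float, float, float, float, float] = "auto"
    radius_table: dict[str, float] | None = None


class CompareStage(_Strict):
    model_a: str
    model_b: str
    probe: str  # "chain:res:atom", e.g. "C:426:CA"
    frame_res_range: tuple[int, int] | None = None
    frame_chains: list[str] | None = None


class TallyStage(_Strict):
    table: str
    group_map: str | None = None
    scale: str | None = None


class RunConfig(_Strict):
    out_dir: str = "results"
    seed: int = 0
    pore: PoreStage | None = None
    compare: CompareStage | None = None
    tally: TallyStage | None = None
    overrides: dict[str, float] = Field(default_factory=dict)


def defaults_dict() -> dict:
    """All stage defaults, as printed by ``oligosym defaults``."""
    from .pore import BAND_SUB, BAND_WIDE, HYDRATED_NA_RADIUS, PoreOptions
    from .core import DEFAULT_RADII, FALLBACK_RADIUS
    from .synth import DEFAULT_CONFIG_DIST, DEFAULT_DEVIATION_SCALE, TrajectorySpec

    po = PoreOptions()
    ts = TrajectorySpec()
    return {
        "version": __version__,
        "radius_table": dict(DEFAULT_RADII),
        "radius_fallback": FALLBACK_RADIUS,
        "pore": {
            "step": po.step,
            "starts": po.starts,
            "max_jump": po.max_jump,
            "disc_radius": po.disc_radius,
            "r_max": po.r_max,
            "bands": {"sub": BAND_SUB, "wide": BAND_WIDE},
            "hydrated_na_radius": HYDRATED_NA_RADIUS,
        },
        "trajectory": {
            "n_frames": ts.n_frames,
            "dt_ns": ts.dt_ns,
            "slab": list(ts.slab),
            "water_cutoff": ts.water_cutoff,
            "analysis_tail_fraction": 0.25,
            "mx_exclusion_res_range": [309, 334],
        },
        "config_dist": dict(DEFAULT_CONFIG_DIST),
        "deviation_scale": dict(DEFAULT_DEVIATION_SCALE),
    }


def _parse_probe(p: str) -> tuple[str, int, str]:
    chain, res, atom = p.split(":")
    return chain, int(res), atom


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a dict of artifact paths."""
    from . import core, geometry, pore, symconfig

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    log_lines = [f"oligosym {__version__}", f"seed {config.seed}",
                 "config " + config.model_dump_json()]

    for stage in ("pore", "compare", "tally"):
        cfg = getattr(config, stage)
        if cfg is None:
            continue
        for path_attr in ("model", "model_a", "model_b", "table", "group_map", "scale"):
            p = getattr(cfg, path_attr, None)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{stage}: input {p!r} does not exist")

    if config.pore is not None:
        c = config.pore
        s = core.read_structure(c.model)
        s = core.assign_radii(s, c.radius_table)
        axis = (
            geometry.estimate_pore_axis(s)
            if c.axis == "auto"
            else (list(c.axis)[:3], list(c.axis)[3:])
        )
        atoms = core.select(s)
        prof = pore.compute_profile(
            atoms, axis, c.s_range,
            pore.PoreOptions(step=c.step, starts=c.starts, seed=config.seed),
        )
        rows = pore.classify_profile(prof)
        tsv = out / "pore_profile.tsv"
        with open(tsv, "w") as fh:
            fh.write("S\tx\ty\tz\tR\tconverged\tband\n")
            for smp, row in zip(prof.samples, rows):
                fh.write(
                    "\t".join(
                        [ANG.format(smp.s)]
                        + [ANG.format(v) for v in smp.center]
                        + [ANG.format(smp.radius), str(int(smp.converged)), row["band"]]
                    )
                    + "\n"
                )
        summary = pore.min_constriction(prof, atoms)
        js = out / "pore_summary.json"
        js.write_text(json.dumps({
            "model": c.model,
            "min_diameter": round(summary["diameter"], 3),
            "s_at_min": round(summary["s"], 3),
            "lining": [[c_, r_, n_] for c_, r_, n_, _ in summary["lining"]],
        }, indent=2))
        artifacts["pore_profile"] = str(tsv)
        artifacts["pore_summary"] = str(js)
        log_lines.append(f"pore: {len(prof.samples)} samples from {c.model}")

    if config.compare is not None:
        c = config.compare
        a = core.read_structure(c.model_a)
        b = core.read_structure(c.model_b)
        probe = _parse_probe(c.probe)
        frame = {}
        if c.frame_res_range is not None:
            frame["res_range"] = tuple(c.frame_res_range)
        if c.frame_chains is not None:
            frame["chains"] = c.frame_chains
        frame.setdefault("atom_names", ["CA"])
        d = geometry.displacement(a, b, probe, frame=frame)
        from .core import paired_sets

        fa, fb = paired_sets(a, b, **frame)
        _, frame_rmsd = geometry.superpose(fb, fa)
        tsv = out / "compare.tsv"
        with open(tsv, "w") as fh:
            fh.write("probe\tdisplacement_A\tframe\trmsd_of_frame\n")
            fh.write(f"{c.probe}\t{ANG.format(d)}\t{fa.expression}\t{ANG.format(frame_rmsd)}\n")
        artifacts["compare"] = str(tsv)
        log_lines.append(f"compare: probe {c.probe} displacement {ANG.format(d)} A")

    if config.tally is not None:
        c = config.tally
        gmap = None
        if c.group_map is not None:
            import pandas as pd

            m = pd.read_csv(c.group_map, sep="\t", header=None, names=["raw", "group"])
            gmap = dict(zip(m["raw"].astype(str), m["group"].astype(str)))
        table = symconfig.read_class_table(c.table, gmap)
        tal = symconfig.tally_configs(table)
        scale = None
        if c.scale is not None:
            import pandas as pd

            sc = pd.read_csv(c.scale, sep="\t", header=None, names=["label", "dev"])
            scale = dict(zip(sc["label"].astype(str), sc["dev"].astype(float)))
        tsv = out / "config_tally.tsv"
        with open(tsv, "w") as fh:
            header = "config\tcount\tfraction"
            if scale:
                header += "\tscore"
            fh.write(header + "\tarrangement_M\n")
            for cfg, row in tal.iterrows():
                line = f"{cfg}\t{int(row['count'])}\t{row['fraction']:.6f}"
                if scale:
                    line += f"\t{symconfig.pentamer_score(tuple(cfg), scale):.3f}"
                line += f"\t{symconfig.consecutive_arrangement(tuple(cfg), 'M')}"
                fh.write(line + "\n")
        artifacts["config_tally"] = str(tsv)
        log_lines.append(f"tally: {int(tal['count'].sum())} particles, {len(tal)} configs")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = str(out / "run.log")
    return artifacts
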