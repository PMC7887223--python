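"""Pentamer-configuration statistics downstream of cryo-EM symmetry expansion.

After symmetry expansion and per-subunit 3D classification, each particle
carries five class labels in ring order.  Because the starting subunit of the
ring is arbitrary, arrangements are compared up to cyclic rotation only —
reflections are *not* identified, since a subunit ring embedded in a membrane
is chiral.  The equivalence classes are necklaces; for a binary more-open /
less-open ('M'/'L') alphabet on a pentamer there are exactly 8 of them.
"""

from __future__ import annotations

from itertools import product
from typing import Mapping, Sequence

import pandas as pd
from sympy import divisors, totient

__all__ = [
    "canonical_form",
    "enumerate_necklaces",
    "necklace_count",
    "tally_configs",
    "pentamer_score",
    "consecutive_arrangement",
    "TableIntegrityError",
    "read_class_table",
    "apply_group_map",
]


class TableIntegrityError(ValueError):
    """A particle does not have exactly one label per ring position."""


def canonical_form(labels: Sequence[str]) -> tuple[str, ...]:
    """Lexicographically minimal cyclic rotation of a ring of labels.

    Plain byte-order comparison on the label strings; reflections are not
    identified.  Idempotent and constant on rotation orbits.
    """
    t = tuple(labels)
    n = len(t)
    if n == 0:
        raise ValueError("empty label tuple")
    return min(t[i:] + t[:i] for i in range(n))


def necklace_count(k: int, n: int) -> int:
    """Number of length-``n`` necklaces over ``k`` letters (Burnside):
    (1/n) Σ_{d|n} φ(d) k^(n/d)."""
    if k < 1 or n < 1:
        raise ValueError("k and n must be >= 1")
    return sum(int(totient(d)) * k ** (n // d) for d in divisors(n)) // n


def enumerate_necklaces(alphabet: Sequence[str] | int, n: int = 5) -> list[tuple[str, ...]]:
    """All distinct canonical ring configurations, sorted.

    ``alphabet`` is a list of labels or an integer k (labels then being the
    first k uppercase letters).  Enumeration is by brute-force
    canonicalization of all k^n tuples; the count equals the Burnside
    necklace number, which tests verify independently.
    """
    if isinstance(alphabet, int):
        letters: list[str] = [chr(ord("A") + i) for i in range(alphabet)]
    else:
        letters = list(alphabet)
    return sorted({canonical_form(t) for t in product(letters, repeat=n)})


def read_class_table(path, group_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a per-subunit class table (TSV with particle_id, subunit_index,
    class_label columns), optionally collapsing raw classes into groups."""
    df = pd.read_csv(path, sep="\t", dtype={"particle_id": str, "class_label": str})
    required = {"particle_id", "subunit_index", "class_label"}
    missing = required - set(df.columns)
    if missing:
        raise TableIntegrityError(f"class table missing columns: {sorted(missing)}")
    if group_map is not None:
        df = apply_group_map(df, group_map)
    return df


def apply_group_map(table: pd.DataFrame, group_map: Mapping[str, str]) -> pd.DataFrame:
    """Map raw classification class labels onto groups (e.g. 16 classes → M/L).

    The map must cover every raw label present in the table.
    """
    present = set(table["class_label"].unique())
    uncovered = present - set(group_map)
    if uncovered:
        raise TableIntegrityError(f"group map does not cover labels: {sorted(uncovered)}")
    out = table.copy()
    out["class_label"] = out["class_label"].map(group_map)
    return out


def tally_configs(table: pd.DataFrame, ring_size: int = 5) -> pd.DataFrame:
    """Tally canonical ring configurations over particles.

    Each particle's labels are assembled in subunit_index order,
    canonicalized, and counted.  Returns a DataFrame indexed by the canonical
    configuration string with ``count`` and ``fraction`` columns, sorted by
    descending count then configuration.
    """
    bad: list[str] = []
    configs: list[str] = []
    for pid, grp in table.groupby("particle_id", sort=True):
        idx = sorted(grp["subunit_index"].tolist())
        if len(grp) != ring_size or idx != list(range(ring_size)):
            bad.append(str(pid))
            continue
        ordered = grp.sort_values("subunit_index")["class_label"].tolist()
        configs.append("".join(canonical_form(ordered)))
    if bad:
        raise TableIntegrityError(
            f"{len(bad)} particle(s) without exactly one label per ring position: "
            + ", ".join(bad[:10])
        )
    counts = pd.Series(configs, dtype=str).value_counts()
    out = counts.to_frame("count")
    out["fraction"] = out["count"] / out["count"].sum()
    out = out.sort_values(["count"], ascending=False).sort_index(kind="stable")
    out = out.sort_values("count", ascending=False, kind="stable")
    out.index.name = "config"
    return out


def pentamer_score(labels: Sequence[str], scale: Mapping[str, float]) -> float:
    """Asymmetry score of a ring: sum of per-subunit deviation values.

    ``scale`` maps each class label to its deviation from the symmetric
    reference (e.g. backbone RMSD to the C5 pentamer, Å).  The sum is
    invariant under cyclic rotation of the ring.
    """
    missing = [l for l in labels if l not in scale]
    if missing:
        raise KeyError(f"labels missing from deviation scale: {sorted(set(missing))}")
    total = float(sum(scale[l] for l in labels))
    if any(v < 0 for v in scale.values()):
        raise ValueError("deviation values must be >= 0")
    return total


def consecutive_arrangement(labels: Sequence[str], target: str) -> str:
    """Classify the placement of ``target`` labels on the ring.

    Returns ``"consecutive"`` if all target positions form one contiguous arc
    (ring adjacency wraps the seam), ``"non_consecutive"`` otherwise, and
    ``"degenerate"`` for 0, 1 or all positions (where the distinction is
    meaningless).
    """
    t = tuple(labels)
    n = len(t)
    pos = [i for i, l in enumerate(t) if l == target]
    if len(pos) in (0, 1, n):
        return "degenerate"
    # one contiguous arc <=> exactly one transition target -> non-target
    transitions = sum(1 for i in range(n) if t[i] == target and t[(i + 1) % n] != target)
    return "consecutive" if transitions == 1 else "non_consecutive"
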