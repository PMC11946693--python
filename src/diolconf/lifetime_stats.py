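"""Run-length lifetime statistics for conformations and families.

The trajectory is sampled at a fixed recording stride (1 ps in the typical
setup), so the shortest resolvable lifetime is one stride: a conformation
seen in a single frame lived for one stride, and each further consecutive
frame with the same designation adds one stride.  Lifetimes are attributed
to the canonical label, so a flip between two symmetry-equivalent raw
labels does not break a run.  Family-level runs are computed on the family
sequence directly: hydroxyl rotations that change the label but not the
main chain do not interrupt a family run, which is why family lifetimes
are typically an order of magnitude longer than label lifetimes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import groupby

import numpy as np
import pandas as pd

from .conformation_space import FAMILIES, enumerate_unique
from .state_series import MISSING, StateSeries

__all__ = ["RunLengthRecord", "run_length_encode", "truncation_policy", "lifetime_table"]


@dataclass(frozen=True)
class RunLengthRecord:
    """One maximal constant run of a molecule's label (or family) sequence."""

    molecule: int
    label: str
    start_ps: float
    duration_ps: float
    truncated: bool  # touches the first or last frame of the series


def run_length_encode(series: StateSeries, level: str = "label") -> list[RunLengthRecord]:
    """Maximal constant runs per molecule, at label or family level.

    A run of k consecutive frames has duration k times the stride.  Runs of
    the missing marker are emitted too (so conservation checks can account
    for every frame); :func:`lifetime_table` excludes them.  Runs never
    bridge a missing frame.
    """
    if level == "label":
        seq = series.canonical
    elif level == "family":
        seq = series.family
    else:
        raise ValueError(f"level must be 'label' or 'family', got {level!r}")
    n_frames, n_mol = seq.shape
    stride = series.stride_ps
    runs: list[RunLengthRecord] = []
    for m in range(n_mol):
        pos = 0
        for value, grp in groupby(seq[:, m]):
            k = sum(1 for _ in grp)
            runs.append(
                RunLengthRecord(
                    molecule=m,
                    label=str(value),
                    start_ps=float(series.times[pos]),
                    duration_ps=k * stride,
                    truncated=(pos == 0) or (pos + k == n_frames),
                )
            )
            pos += k
    return runs


def truncation_policy(
    runs: list[RunLengthRecord], policy: str = "include"
) -> list[RunLengthRecord]:
    """Filter runs that touch the trajectory boundary.

    ``include`` (default) keeps them; ``exclude_boundary`` drops any run
    containing the first or last frame, at the cost of the conservation
    property (run durations no longer sum to the observed span).
    """
    if policy == "include":
        return list(runs)
    if policy == "exclude_boundary":
        return [r for r in runs if not r.truncated]
    raise ValueError(f"unknown truncation policy {policy!r}")


def lifetime_table(runs: list[RunLengthRecord], level: str = "label") -> pd.DataFrame:
    """Average and maximum lifetimes per label (or family).

    One row per canonical label c_1..c_25 (or per family), columns
    (label, t_av_ps, t_max_ps, n_runs); labels never observed report zero.
    Missing-marker runs are excluded.
    """
    durations: dict[str, list[float]] = {}
    for r in runs:
        if r.label == MISSING:
            continue
        durations.setdefault(r.label, []).append(r.duration_ps)
    if level == "label":
        universe = [str(l) for l in enumerate_unique()]
    elif level == "family":
        universe = list(FAMILIES)
    else:
        raise ValueError(f"level must be 'label' or 'family', got {level!r}")
    extras = [k for k in durations if k not in universe]
    rows = []
    for name in universe + sorted(extras):
        d = durations.get(name, [])
        rows.append(
            {
                "label": name,
                "t_av_ps": float(np.mean(d)) if d else 0.0,
                "t_max_ps": float(np.max(d)) if d else 0.0,
                "n_runs": len(d),
            }
        )
    return pd.DataFrame(rows)
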