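"""Per-molecule conformation time series: the direct labeling step.

Every target molecule in every frame is assigned a raw four-letter torsion
label from its measured dihedrals, the label is folded to its canonical
symmetry representative, and the canonical label determines the family
(TT / TG / GG / GG′).  The result is a :class:`StateSeries`: aligned
per-molecule sequences of (raw, canonical, family) at the trajectory's
recording stride, from which occupancy fractions and (in
:mod:`diolconf.lifetime_stats`) lifetimes are computed.

Frames where a molecule's geometry is degenerate (a collinear bond triple
makes a dihedral undefined) carry an explicit missing marker; they are
excluded from the configuration count rather than interpolated, so
lifetimes never bridge fabricated states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conformation_space import (
    ConformationLabel,
    FAMILIES,
    canonicalize,
    enumerate_unique,
    family_of,
    label_from_torsions,
)
from .geometry import DegenerateGeometryError, SITE_NAMES, SiteCoords, intra_OO, torsion_quad
from .trajectory_io import Topology, TrajectoryStream

__all__ = ["MISSING", "StateSeries", "label_trajectory", "occupancy", "family_distance_track"]

logger = logging.getLogger(__name__)

#: Marker used for molecule-frames whose label could not be determined.
MISSING = "-"


@dataclass
class StateSeries:
    """Aligned per-molecule label sequences at a fixed stride.

    ``raw``, ``canonical`` and ``family`` are (n_frames, n_molecules)
    string arrays; missing molecule-frames hold :data:`MISSING` in all
    three.  ``n_conf`` counts the labelled (non-missing) configurations.
    """

    stride_ps: float
    times: np.ndarray
    raw: np.ndarray
    canonical: np.ndarray
    family: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.raw.shape, self.canonical.shape, self.family.shape}
        if len(shapes) != 1 or self.raw.shape[0] != len(self.times):
            raise ValueError("misaligned state-series arrays")

    @property
    def n_frames(self) -> int:
        return self.raw.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.raw.shape[1]

    @property
    def n_conf(self) -> int:
        return int(np.sum(self.canonical != MISSING))

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.canonical == MISSING))

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: molecule, time_ps, raw, canonical, family."""
        n_f, n_m = self.raw.shape
        return pd.DataFrame(
            {
                "molecule": np.tile(np.arange(n_m), n_f),
                "time_ps": np.repeat(self.times, n_m),
                "raw": self.raw.ravel(),
                "canonical": self.canonical.ravel(),
                "family": self.family.ravel(),
            }
        )


def label_trajectory(stream: TrajectoryStream, topology: Topology) -> StateSeries:
    """Label every target molecule in every frame of a trajectory.

    Returns one canonical label (and its raw precursor and family) per
    molecule per frame.  Degenerate-geometry molecule-frames are marked
    missing and logged, never silently dropped.
    """
    times: list[float] = []
    raw_rows: list[list[str]] = []
    can_rows: list[list[str]] = []
    fam_rows: list[list[str]] = []
    n_skipped = 0
    # cache: raw letter word -> (canonical string, family string)
    fold: dict[tuple[str, ...], tuple[str, str]] = {}
    for frame in stream:
        raw_row, can_row, fam_row = [], [], []
        for mol in topology.molecules:
            try:
                sites = SiteCoords(
                    np.array([frame.position(mol[s]) for s in SITE_NAMES]),
                    box=frame.box,
                )
                quad = torsion_quad(sites)
            except (DegenerateGeometryError, ValueError) as exc:
                n_skipped += 1
                logger.warning("t=%.3f ps: skipping molecule (%s)", frame.time_ps, exc)
                raw_row.append(MISSING)
                can_row.append(MISSING)
                fam_row.append(MISSING)
                continue
            raw = label_from_torsions(quad)
            key = raw.letters
            if key not in fold:
                can = canonicalize(raw)
                fold[key] = (str(can), family_of(can))
            can_str, fam_str = fold[key]
            raw_row.append(str(raw))
            can_row.append(can_str)
            fam_row.append(fam_str)
        times.append(frame.time_ps)
        raw_rows.append(raw_row)
        can_rows.append(can_row)
        fam_rows.append(fam_row)
    if not times:
        raise ValueError("empty trajectory stream")
    if n_skipped:
        logger.info("degenerate-geometry skips: %d molecule-frames", n_skipped)
    return StateSeries(
        stride_ps=stream.stride_ps,
        times=np.asarray(times),
        raw=np.array(raw_rows, dtype=object),
        canonical=np.array(can_rows, dtype=object),
        family=np.array(fam_rows, dtype=object),
    )


def occupancy(series: StateSeries) -> pd.DataFrame:
    """Occupancy fractions phi (percent of all configurations) per label.

    Returns one row per canonical label c_1..c_25 with columns
    (index, label, family, count, phi_percent) plus the per-family sums in
    ``DataFrame.attrs['families']`` and the missing fraction in
    ``attrs['missing_percent']``.  Fractions are percentages of the
    labelled configuration count N_conf, so label fractions sum to 100
    (family fractions likewise).
    """
    if series.n_conf == 0:
        raise ValueError("state series has no labelled configurations")
    flat = series.canonical.ravel()
    labels, counts = np.unique(flat[flat != MISSING], return_counts=True)
    count_of = dict(zip(labels, counts))
    n_conf = series.n_conf
    rows = []
    for i, lbl in enumerate(enumerate_unique(), start=1):
        c = int(count_of.get(str(lbl), 0))
        rows.append(
            {
                "index": f"c_{i}",
                "label": str(lbl),
                "family": family_of(lbl),
                "count": c,
                "phi_percent": 100.0 * c / n_conf,
            }
        )
    out = pd.DataFrame(rows)
    fam = out.groupby("family", sort=False)["phi_percent"].sum()
    out.attrs["families"] = fam.reindex(list(FAMILIES)).rename_axis("family")
    total = series.n_conf + series.n_missing
    out.attrs["missing_percent"] = 100.0 * series.n_missing / total
    return out


def family_occupancy(series: StateSeries) -> pd.Series:
    """Per-family occupancy percentages (sums of member-label fractions)."""
    return occupancy(series).attrs["families"]


def family_distance_track(
    stream: TrajectoryStream, topology: Topology, series: StateSeries
) -> pd.DataFrame:
    """Per-frame mean intramolecular O...O distance for each family.

    For every frame and family, averages the O1...O2 minimum-image distance
    over the molecules currently labelled into that family; NaN when the
    family is unoccupied at that time.  Also reports the all-molecule mean
    in column ``all``.  Index: time_ps; columns: TT, TG, GG, GG′, all.
    """
    records = []
    for fi, frame in enumerate(stream):
        if fi >= series.n_frames:
            break
        dists = np.empty(topology.n_target)
        for mi, mol in enumerate(topology.molecules):
            sites = SiteCoords(
                np.array([frame.position(mol[s]) for s in SITE_NAMES]),
                box=frame.box,
            )
            dists[mi] = intra_OO(sites)
        row = {"time_ps": frame.time_ps}
        fams = series.family[fi]
        for fam in FAMILIES:
            mask = fams == fam
            row[fam] = float(np.mean(dists[mask])) if np.any(mask) else np.nan
        row["all"] = float(np.mean(dists[fams != MISSING])) if np.any(fams != MISSING) else np.nan
        records.append(row)
    return pd.DataFrame(records).set_index("time_ps")
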