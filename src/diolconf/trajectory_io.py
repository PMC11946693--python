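"""Trajectory and topology input/output.

Reads MD trajectory frames from two plain-text dialects — the LAMMPS
"atom"-style text dump (``ITEM: TIMESTEP`` / ``BOX BOUNDS`` / ``ATEMS``
blocks) and multi-frame XYZ / extended-XYZ — together with a structured
YAML config naming, for each target diol molecule, the atom ids of its
seven sites (H1, O1, C1, C2, C3, O2, H2).

Frames are streamed lazily: a :class:`TrajectoryStream` re-opens its file
on every iteration, so memory use is independent of trajectory length and
the same stream can feed several analysis passes.

Only orthorhombic boxes are supported; triclinic dumps are rejected loudly.
Dump files store integer step counts, not physical time, so the reader
converts via a configured MD timestep (ps per step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np
import yaml

from .geometry import SITE_NAMES

__all__ = [
    "Frame",
    "Topology",
    "TrajectoryStream",
    "TrajectoryParseError",
    "read_topology",
    "read_lammps_dump",
    "read_xyz",
    "write_lammps_dump",
    "write_xyz",
]


class TrajectoryParseError(ValueError):
    """Malformed trajectory or topology input; message carries file/line."""


@dataclass
class Frame:
    """One trajectory snapshot.

    ``box`` is the three orthorhombic edge lengths (Angstrom) and
    ``origin`` the lower bounds; ``coords`` is an (n_atoms, 3) array and
    ``ids`` the matching atom ids.
    """

    time_ps: float
    box: np.ndarray
    coords: np.ndarray
    ids: np.ndarray
    origin: np.ndarray | None = None
    _index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.ids = np.asarray(self.ids, dtype=int)
        if np.any(self.box <= 0):
            raise ValueError(f"non-positive box edge in {self.box}")
        self._index = {int(a): i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate atom ids in frame")

    def position(self, atom_id: int) -> np.ndarray:
        try:
            return self.coords[self._index[atom_id]]
        except KeyError:
            raise KeyError(f"atom id {atom_id} not present in frame") from None

    @property
    def n_atoms(self) -> int:
        return len(self.ids)


@dataclass
class Topology:
    """Site maps for the target diol molecules.

    ``molecules`` is a list of dicts mapping each site name in
    :data:`diolconf.geometry.SITE_NAMES` to an atom id; maps must be
    complete and pairwise disjoint.
    """

    molecules: list[dict[str, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for k, mol in enumerate(self.molecules):
            missing = [s for s in SITE_NAMES if s not in mol]
            if missing:
                raise ValueError(f"molecule {k}: missing sites {missing}")
            extra = [s for s in mol if s not in SITE_NAMES]
            if extra:
                raise ValueError(f"molecule {k}: unknown sites {extra}")
            ids = set(int(v) for v in mol.values())
            if len(ids) != len(SITE_NAMES):
                raise ValueError(f"molecule {k}: repeated atom id within molecule")
            clash = seen & ids
            if clash:
                raise ValueError(f"molecule {k}: atom ids {sorted(clash)} already assigned")
            seen |= ids
        self.molecules = [{s: int(m[s]) for s in SITE_NAMES} for m in self.molecules]

    @property
    def n_target(self) -> int:
        return len(self.molecules)

    def all_atom_ids(self) -> list[int]:
        return [m[s] for m in self.molecules for s in SITE_NAMES]


@dataclass
class TrajectoryStream:
    """Lazy, re-iterable sequence of frames at a fixed recording stride."""

    format: str
    stride_ps: float
    _open: Callable[[], Iterator[Frame]] = field(repr=False)

    def __iter__(self) -> Iterator[Frame]:
        last = -math.inf
        for frame in self._open():
            if frame.time_ps < last:
                raise TrajectoryParseError(
                    f"frames out of time order: {frame.time_ps} ps after {last} ps"
                )
            last = frame.time_ps
            yield frame

    def n_frames(self) -> int:
        return sum(1 for _ in self)


def from_frames(frames: list[Frame], stride_ps: float = 1.0) -> TrajectoryStream:
    """Wrap an in-memory frame list as a re-iterable stream."""
    return TrajectoryStream(format="memory", stride_ps=stride_ps, _open=lambda: iter(frames))


def read_topology(source) -> Topology:
    """Read a site-topology map from YAML (path, text, or parsed dict).

    Two layouts are accepted:

    * explicit — ``molecules: [{H1: 1, O1: 2, ...}, ...]``
    * template — ``sites: {H1: 1, ...}`` for the first molecule plus
      ``stride_atoms`` (per-molecule atom-id offset) and ``n_molecules``.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, str):
        doc = yaml.safe_load(source)
    else:
        doc = source
    if not isinstance(doc, dict):
        raise TrajectoryParseError("topology document must be a mapping")
    if "molecules" in doc:
        return Topology([dict(m) for m in doc["molecules"]])
    if "sites" in doc:
        sites = doc["sites"]
        stride = int(doc.get("stride_atoms", len(SITE_NAMES)))
        count = int(doc.get("n_molecules", 1))
        mols = [
            {s: int(sites[s]) + k * stride for s in SITE_NAMES} for k in range(count)
        ]
        return Topology(mols)
    raise TrajectoryParseError("topology needs either 'molecules' or 'sites'")


def _parse_lammps_frames(path: str | Path, timestep_ps: float) -> Iterator[Frame]:
    path = Path(path)
    with open(path) as fh:
        lines = iter(enumerate(fh, start=1))

        def fail(lineno: int, msg: str):
            raise TrajectoryParseError(f"{path}:{lineno}: {msg}")

        while True:
            try:
                lineno, line = next(lines)
            except StopIteration:
                return
            if not line.strip():
                continue
            if not line.startswith("ITEM: TIMESTEP"):
                fail(lineno, f"expected 'ITEM: TIMESTEP', got {line.strip()!r}")
            lineno, line = next(lines)
            step = int(line.strip())

            lineno, line = next(lines)
            if not line.startswith("ITEM: NUMBER OF ATOMS"):
                fail(lineno, "expected 'ITEM: NUMBER OF ATOMS'")
            lineno, line = next(lines)
            n_atoms = int(line.strip())

            lineno, line = next(lines)
            if not line.startswith("ITEM: BOX BOUNDS"):
                fail(lineno, "expected 'ITEM: BOX BOUNDS'")
            if any(t in line.split() for t in ("xy", "xz", "yz")):
                fail(lineno, "triclinic box bounds are not supported")
            lo = np.empty(3)
            hi = np.empty(3)
            for ax in range(3):
                lineno, line = next(lines)
                parts = line.split()
                if len(parts) < 2:
                    fail(lineno, "box bounds line needs two floats")
                lo[ax], hi[ax] = float(parts[0]), float(parts[1])

            lineno, line = next(lines)
            if not line.startswith("ITEM: ATOMS"):
                fail(lineno, "expected 'ITEM: ATOMS'")
            columns = line.split()[2:]
            if "id" not in columns:
                fail(lineno, "ATOMS section lacks an 'id' column")
            scaled = all(c in columns for c in ("xs", "ys", "zs"))
            unscaled = all(c in columns for c in ("x", "y", "z"))
            if not scaled and not unscaled:
                fail(lineno, "ATOMS section needs x,y,z or xs,ys,zs columns")
            names = ("x", "y", "z") if unscaled else ("xs", "ys", "zs")
            idx_id = columns.index("id")
            idx_xyz = [columns.index(c) for c in names]

            ids = np.empty(n_atoms, dtype=int)
            coords = np.empty((n_atoms, 3))
            for a in range(n_atoms):
                lineno, line = next(lines)
                parts = line.split()
                if len(parts) != len(columns):
                    fail(lineno, f"expected {len(columns)} columns, got {len(parts)}")
                ids[a] = int(parts[idx_id])
                coords[a] = [float(parts[j]) for j in idx_xyz]
            if len(np.unique(ids)) != n_atoms:
                fail(lineno, "duplicate atom ids in frame")
            box = hi - lo
            if scaled:
                coords = lo + coords * box
            order = np.argsort(ids)
            yield Frame(
                time_ps=step * timestep_ps,
                box=box,
                coords=coords[order],
                ids=ids[order],
                origin=lo,
            )


def read_lammps_dump(
    path: str | Path,
    topology: Topology | None = None,
    timestep_ps: float = 0.001,
    stride_ps: float = 1.0,
) -> TrajectoryStream:
    """Stream a LAMMPS text dump.

    ``timestep_ps`` converts the dump's integer TIMESTEP counters into
    picoseconds.  Scaled (xs, ys, zs) coordinates are unscaled via the box
    bounds; atoms are re-sorted by id.  If a topology is given, every frame
    is checked to contain all of its atom ids.
    """
    def opener() -> Iterator[Frame]:
        for frame in _parse_lammps_frames(path, timestep_ps):
            if topology is not None:
                for atom_id in topology.all_atom_ids():
                    frame.position(atom_id)
            yield frame

    return TrajectoryStream(format="lammps-dump", stride_ps=stride_ps, _open=opener)


def _parse_lattice(comment: str) -> np.ndarray | None:
    # extended-XYZ: Lattice="ax ay az bx by bz cx cy cz"
    key = "Lattice="
    pos = comment.find(key)
    if pos < 0:
        return None
    rest = comment[pos + len(key):]
    quote = rest[0] if rest[:1] in ("'", '"') else None
    if quote:
        rest = rest[1:rest.index(quote, 1)]
    else:
        rest = rest.split()[0]
    vals = np.array([float(v) for v in rest.split()])
    if vals.size != 9:
        raise TrajectoryParseError(f"Lattice needs 9 numbers, got {vals.size}")
    cell = vals.reshape(3, 3)
    off = cell - np.diag(np.diag(cell))
    if np.any(np.abs(off) > 1e-8):
        raise TrajectoryParseError("non-orthorhombic Lattice is not supported")
    return np.diag(cell).copy()


def _parse_xyz_frames(path: str | Path, box, stride_ps: float) -> Iterator[Frame]:
    path = Path(path)
    fixed_box = None if box is None else np.asarray(box, dtype=float)
    with open(path) as fh:
        lineno = 0
        index = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header:
                return
            if not header.strip():
                continue
            try:
                n_atoms = int(header.strip())
            except ValueError:
                raise TrajectoryParseError(
                    f"{path}:{lineno}: expected atom count, got {header.strip()!r}"
                )
            comment = fh.readline()
            lineno += 1
            frame_box = _parse_lattice(comment)
            if frame_box is None:
                frame_box = fixed_box
            if frame_box is None:
                raise TrajectoryParseError(
                    f"{path}:{lineno}: no box: supply one in the config or "
                    "an extended-XYZ Lattice comment"
                )
            ids = np.arange(1, n_atoms + 1)
            coords = np.empty((n_atoms, 3))
            for a in range(n_atoms):
                line = fh.readline()
                lineno += 1
                parts = line.split()
                if len(parts) < 4:
                    raise TrajectoryParseError(
                        f"{path}:{lineno}: atom-count mismatch: frame header "
                        f"promised {n_atoms} atoms"
                    )
                coords[a] = [float(v) for v in parts[1:4]]
            yield Frame(
                time_ps=index * stride_ps, box=frame_box, coords=coords, ids=ids
            )
            index += 1


def read_xyz(
    path: str | Path,
    box=None,
    topology: Topology | None = None,
    stride_ps: float = 1.0,
) -> TrajectoryStream:
    """Stream a multi-frame XYZ / extended-XYZ file.

    The periodic box comes from an extended-XYZ ``Lattice`` comment when
    present, else from the ``box`` argument; lacking both is an error.
    Atom ids are assigned 1..n in file order, frame times as index times
    ``stride_ps``.
    """
    def opener() -> Iterator[Frame]:
        for frame in _parse_xyz_frames(path, box, stride_ps):
            if topology is not None:
                for atom_id in topology.all_atom_ids():
                    frame.position(atom_id)
            yield frame

    return TrajectoryStream(format="xyz", stride_ps=stride_ps, _open=opener)


def write_lammps_dump(
    frames: Iterable[Frame], path: str | Path, timestep_ps: float = 0.001
) -> int:
    """Write frames as a LAMMPS atom-style text dump; returns frame count."""
    n = 0
    with open(path, "w") as fh:
        for frame in frames:
            step = int(round(frame.time_ps / timestep_ps))
            lo = np.zeros(3) if frame.origin is None else frame.origin
            hi = lo + frame.box
            fh.write("ITEM: TIMESTEP\n%d\n" % step)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % frame.n_atoms)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for ax in range(3):
                fh.write("%.10g %.10g\n" % (lo[ax], hi[ax]))
            fh.write("ITEM: ATOMS id x y z\n")
            for atom_id, xyz in zip(frame.ids, frame.coords):
                fh.write("%d %.8f %.8f %.8f\n" % (atom_id, xyz[0], xyz[1], xyz[2]))
            n += 1
    return n


def write_xyz(frames: Iterable[Frame], path: str | Path, element: str = "X") -> int:
    """Write frames as extended-XYZ with a Lattice comment; returns count.

    Atom ids must be 1..n contiguous (XYZ has no id column; order is id
    order).
    """
    n = 0
    with open(path, "w") as fh:
        for frame in frames:
            if not np.array_equal(frame.ids, np.arange(1, frame.n_atoms + 1)):
                raise ValueError("XYZ output requires contiguous atom ids 1..n")
            b = frame.box
            fh.write("%d\n" % frame.n_atoms)
            fh.write(
                'Lattice="%.10g 0 0 0 %.10g 0 0 0 %.10g" Properties=species:S:1:pos:R:3 Time=%.6g\n'
                % (b[0], b[1], b[2], frame.time_ps)
            )
            for xyz in frame.coords:
                fh.write("%s %.8f %.8f %.8f\n" % (element, xyz[0], xyz[1], xyz[2]))
            n += 1
    return n
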