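"""Ground-truth synthetic trajectories for exercising the analysis stack.

Real MD input is expensive to produce and carries no ground truth, so this
module generates trajectories whose per-frame conformation of every
molecule is known exactly:

* torsion dynamics — each of the four torsion slots of each molecule
  evolves as an independent discrete Markov chain over the three rotamer
  bins (G, T, G′) at the recording stride; the realised angle is the bin
  centre plus truncated-Gaussian jitter that can never cross a bin
  boundary, so the generated label is recoverable exactly;
* geometry — a molecule with prescribed torsions is built by sequential
  internal-to-Cartesian chain extension (NeRF) from template bond lengths
  and angles, then given a random rigid pose inside the periodic box.

The chains are test instruments, not physical kinetics: their stationary
distributions and geometric dwell times are analytic, which is what makes
occupancy and lifetime recovery checkable.  An optional post-processing
step repositions molecule pairs to a prescribed intermolecular O...O
contact distance, emulating intermolecular hydrogen bonds without touching
any torsion — the construction behind the RDF first-peak bias
demonstration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .conformation_space import ConformationLabel, canonicalize
from .geometry import SITE_NAMES
from .trajectory_io import Frame, Topology

__all__ = [
    "BIN_LETTERS",
    "BIN_CENTERS",
    "GeometryTemplate",
    "TorsionChainModel",
    "SimulatedSeries",
    "simulate_labels",
    "build_coordinates",
    "default_topology",
    "inject_intermolecular_contacts",
]

#: Rotamer-bin letters in state-index order (bin k covers [120k, 120k+120)).
BIN_LETTERS = ("G", "T", "Gp")
#: Bin-centre angles, degrees.
BIN_CENTERS = np.array([60.0, 180.0, 300.0])


@dataclass
class GeometryTemplate:
    """Internal coordinates of the seven-site chain H1-O1-C1-C2-C3-O2-H2.

    Defaults are standard organic geometry (O-H 0.96 A, C-O 1.43 A,
    C-C 1.53 A; tetrahedral-ish angles).  Only the torsions carry
    conformational signal, so these values merely set the distance scale —
    in particular the family-specific intramolecular O...O distances.
    """

    bond_lengths: tuple[float, ...] = (0.96, 1.43, 1.53, 1.53, 1.43, 0.96)
    bond_angles: tuple[float, ...] = (108.5, 109.5, 112.0, 109.5, 108.5)

    def __post_init__(self) -> None:
        if len(self.bond_lengths) != 6 or len(self.bond_angles) != 5:
            raise ValueError("need 6 bond lengths and 5 bond angles for a 7-site chain")
        if any(b <= 0 for b in self.bond_lengths):
            raise ValueError("bond lengths must be positive")
        if any(not 0.0 < a < 180.0 for a in self.bond_angles):
            raise ValueError("bond angles must lie in (0, 180) degrees")


@dataclass
class TorsionChainModel:
    """Per-slot Markov dynamics of the four torsions.

    ``matrices`` is a (4, 3, 3) stack of per-step transition matrices in
    :data:`BIN_LETTERS` state order (one per torsion slot; a single (3, 3)
    matrix is broadcast to all slots).  ``jitter_sd`` is the s.d. (degrees)
    of the truncated-Gaussian angle noise about bin centres and
    ``jitter_max`` its hard truncation half-width; the truncation keeps
    every generated angle strictly inside its 120-degree bin, so analyzer
    labels must agree with the generator's ground truth exactly.
    """

    matrices: np.ndarray
    stride_ps: float = 1.0
    jitter_sd: float = 10.0
    jitter_max: float = 30.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.shape == (3, 3):
            m = np.broadcast_to(m, (4, 3, 3)).copy()
        if m.shape != (4, 3, 3):
            raise ValueError(f"matrices must be (3,3) or (4,3,3), got {m.shape}")
        if np.any(m < 0) or not np.allclose(m.sum(axis=2), 1.0, atol=1e-10):
            raise ValueError("each transition-matrix row must be non-negative and sum to 1")
        if not 0 < self.jitter_max < 60.0:
            raise ValueError("jitter_max must lie in (0, 60) degrees to stay inside a bin")
        self.matrices = m

    @classmethod
    def uniform(cls, stay: float = 0.75, **kw) -> "TorsionChainModel":
        """Symmetric chain: stay with probability ``stay``, else split evenly."""
        off = (1.0 - stay) / 2.0
        m = np.full((3, 3), off) + np.eye(3) * (stay - off)
        return cls(matrices=m, **kw)

    @classmethod
    def solution_like(cls) -> "TorsionChainModel":
        """Default model emulating a dilute aqueous diol solution.

        Chain slots strongly favour trans (per-slot stationary weight 0.866
        on T), giving family fractions near TT 75%, TG 23%, GG+GG′ ~2%;
        hydroxyl slots are uniform with a mean dwell of 4 steps.  Both use
        reversible matrices P_ij = a * pi_j (i != j), which have the chosen
        pi as stationary distribution by detailed balance.
        """
        def reversible(pi: np.ndarray, a: float) -> np.ndarray:
            m = a * np.tile(pi, (3, 1))
            np.fill_diagonal(m, 0.0)
            np.fill_diagonal(m, 1.0 - m.sum(axis=1))
            return m

        pi_chain = np.array([0.067, 0.866, 0.067])
        pi_hydroxyl = np.full(3, 1.0 / 3.0)
        chain = reversible(pi_chain, 0.25)
        hydroxyl = reversible(pi_hydroxyl, 0.375)
        return cls(matrices=np.stack([hydroxyl, chain, chain, hydroxyl]))

    def stationary(self) -> np.ndarray:
        """Per-slot stationary distributions, shape (4, 3)."""
        out = np.empty((4, 3))
        for s in range(4):
            w, v = np.linalg.eig(self.matrices[s].T)
            k = int(np.argmin(np.abs(w - 1.0)))
            pi = np.real(v[:, k])
            out[s] = pi / pi.sum()
        return out


@dataclass
class SimulatedSeries:
    """Ground truth of one synthetic run.

    ``states`` is (n_frames, n_molecules, 4) of bin indices, ``quads`` the
    matching jittered torsion angles in degrees.
    """

    states: np.ndarray
    quads: np.ndarray
    stride_ps: float

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.states.shape[1]

    def raw_label(self, frame: int, molecule: int) -> ConformationLabel:
        return ConformationLabel(
            tuple(BIN_LETTERS[s] for s in self.states[frame, molecule])
        )

    def ground_truth(self) -> pd.DataFrame:
        """Tidy ground-truth table: molecule, time_ps, raw, canonical."""
        rows = []
        cache: dict[tuple, tuple[str, str]] = {}
        for f in range(self.n_frames):
            for m in range(self.n_molecules):
                key = tuple(self.states[f, m])
                if key not in cache:
                    raw = ConformationLabel(tuple(BIN_LETTERS[s] for s in key))
                    cache[key] = (str(raw), str(canonicalize(raw)))
                raw_s, can_s = cache[key]
                rows.append((m, f * self.stride_ps, raw_s, can_s))
        return pd.DataFrame(rows, columns=["molecule", "time_ps", "raw", "canonical"])


def series_from_simulation(sim: "SimulatedSeries"):
    """Ground-truth :class:`diolconf.state_series.StateSeries` of a simulation.

    Bypasses geometry entirely: the generator's states are binned letters
    already.  Useful as the exact reference against analyzer output, and
    for occupancy/lifetime recovery studies at lengths where building
    coordinates would be wasteful.
    """
    from .conformation_space import family_of
    from .state_series import StateSeries

    n_f, n_m = sim.n_frames, sim.n_molecules
    cache: dict[tuple, tuple[str, str, str]] = {}
    raw = np.empty((n_f, n_m), dtype=object)
    can = np.empty((n_f, n_m), dtype=object)
    fam = np.empty((n_f, n_m), dtype=object)
    for f in range(n_f):
        for m in range(n_m):
            key = tuple(sim.states[f, m])
            if key not in cache:
                lbl = ConformationLabel(tuple(BIN_LETTERS[s] for s in key))
                c = canonicalize(lbl)
                cache[key] = (str(lbl), str(c), family_of(c))
            raw[f, m], can[f, m], fam[f, m] = cache[key]
    return StateSeries(
        stride_ps=sim.stride_ps,
        times=np.arange(n_f) * sim.stride_ps,
        raw=raw,
        canonical=can,
        family=fam,
    )


def _truncated_normal(rng: np.random.Generator, sd: float, bound: float, size) -> np.ndarray:
    """Gaussian(0, sd) truncated to [-bound, bound], by resampling."""
    out = rng.normal(0.0, sd, size=size)
    bad = np.abs(out) > bound
    while np.any(bad):
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) > bound
    return out


def simulate_labels(
    model: TorsionChainModel,
    n_molecules: int,
    n_frames: int,
    seed: int | np.random.Generator = 0,
) -> SimulatedSeries:
    """Run the per-slot Markov chains and emit ground-truth states + angles.

    Molecules are independent; each slot starts from its chain's stationary
    distribution.  Reproducible for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = model.stationary()
    cum = np.cumsum(model.matrices, axis=2)  # (4, 3, 3)
    states = np.empty((n_frames, n_molecules, 4), dtype=np.int8)
    for s in range(4):
        states[0, :, s] = rng.choice(3, size=n_molecules, p=pi[s])
    for f in range(1, n_frames):
        u = rng.random((n_molecules, 4))
        for s in range(4):
            c = cum[s][states[f - 1, :, s]]  # (n_mol, 3)
            states[f, :, s] = (u[:, s][:, None] > c).sum(axis=1)
    jitter = _truncated_normal(
        rng, model.jitter_sd, model.jitter_max, size=states.shape
    )
    quads = BIN_CENTERS[states] + jitter
    return SimulatedSeries(states=states, quads=quads % 360.0, stride_ps=model.stride_ps)


def _nerf_extend(a, b, c, r, theta_deg, phi_deg):
    """Place the next chain atom D from A, B, C plus (|CD|, angle BCD, torsion ABCD).

    Batched: a, b, c are (M, 3); r, theta, phi are scalars or (M,).  The
    sign is fixed so that the measured right-handed dihedral A-B-C-D equals
    ``phi_deg``.
    """
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    r = np.broadcast_to(np.asarray(r, float), a.shape[:1])
    theta = np.broadcast_to(theta, a.shape[:1])
    phi = np.broadcast_to(phi, a.shape[:1])

    bc = c - b
    bc /= np.linalg.norm(bc, axis=1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -r * np.cos(theta),
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
        ],
        axis=1,
    )
    return c + (
        bc * d_local[:, 0:1] + m * d_local[:, 1:2] + n * d_local[:, 2:3]
    )


def _build_chain_batch(quads: np.ndarray, template: GeometryTemplate) -> np.ndarray:
    """Build (M, 7, 3) site coordinates for M torsion quads, untranslated."""
    M = quads.shape[0]
    L = template.bond_lengths
    A = template.bond_angles
    pos = np.zeros((M, 7, 3))
    pos[:, 1, 0] = L[0]  # O1 along +x from H1
    ang = np.radians(180.0 - A[0])
    pos[:, 2] = pos[:, 1] + L[1] * np.array([np.cos(ang), np.sin(ang), 0.0])
    for k in range(3, 7):
        pos[:, k] = _nerf_extend(
            pos[:, k - 3],
            pos[:, k - 2],
            pos[:, k - 1],
            L[k - 1],
            A[k - 2],
            quads[:, k - 3],
        )
    return pos


def default_topology(n_molecules: int) -> Topology:
    """Topology matching the builder's atom layout: 7 ids per molecule, 1-based."""
    return Topology(
        [
            {s: 7 * m + i + 1 for i, s in enumerate(SITE_NAMES)}
            for m in range(n_molecules)
        ]
    )


def build_coordinates(
    quads: np.ndarray,
    template: GeometryTemplate | None = None,
    box: tuple[float, float, float] = (30.0, 30.0, 30.0),
    seed: int | np.random.Generator = 0,
    stride_ps: float = 1.0,
) -> list[Frame]:
    """Turn torsion quads into trajectory frames.

    ``quads`` has shape (n_frames, n_molecules, 4) in degrees.  Each
    molecule-frame is built by NeRF chain extension from the template and
    then given an independent random rigid pose (uniform rotation, uniform
    translation in the box).  Measured torsions equal the prescribed ones
    to well below 1e-6 degrees; coordinates are left unwrapped (downstream
    geometry applies minimum image).
    """
    template = template or GeometryTemplate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    quads = np.asarray(quads, dtype=float)
    if quads.ndim != 3 or quads.shape[2] != 4:
        raise ValueError(f"quads must be (n_frames, n_molecules, 4), got {quads.shape}")
    n_frames, n_mol = quads.shape[:2]
    box_arr = np.asarray(box, dtype=float)

    flat = quads.reshape(-1, 4)
    sites = _build_chain_batch(flat, template)  # (M, 7, 3)
    center = sites.mean(axis=1, keepdims=True)
    sites = sites - center
    rots = Rotation.random(num=len(flat), random_state=rng)
    sites = np.einsum("mij,maj->mai", rots.as_matrix(), sites)
    trans = rng.random((len(flat), 1, 3)) * box_arr
    sites = sites + trans
    sites = sites.reshape(n_frames, n_mol, 7, 3)

    ids = np.arange(1, 7 * n_mol + 1)
    frames = []
    for f in range(n_frames):
        frames.append(
            Frame(
                time_ps=f * stride_ps,
                box=box_arr,
                coords=sites[f].reshape(-1, 3),
                ids=ids,
                origin=np.zeros(3),
            )
        )
    return frames


def inject_intermolecular_contacts(
    frames: list[Frame],
    topology: Topology,
    n_pairs: int,
    target: float = 2.8,
    seed: int | np.random.Generator = 0,
) -> list[Frame]:
    """Reposition molecule pairs to a prescribed intermolecular O...O contact.

    Pairs (0,1), (2,3), ... are used in order.  In every frame the second
    molecule of each pair is rigidly translated so that its O1 sits exactly
    ``target`` Angstrom (in minimum image) from the first molecule's O2,
    along a random direction.  No internal coordinate changes, so every
    conformation label is preserved by construction.  Returns new frames.
    """
    if n_pairs < 0 or 2 * n_pairs > topology.n_target:
        raise ValueError(
            f"cannot form {n_pairs} disjoint pairs from {topology.n_target} molecules"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half_min = min(f.box.min() for f in frames) / 2.0 if frames else np.inf
    if target >= half_min:
        raise ValueError("contact distance must be below half the box edge")
    out = []
    for frame in frames:
        coords = frame.coords.copy()
        index = {int(a): i for i, a in enumerate(frame.ids)}
        for p in range(n_pairs):
            mol_a = topology.molecules[2 * p]
            mol_b = topology.molecules[2 * p + 1]
            anchor = coords[index[mol_a["O2"]]]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            new_o1 = anchor + target * direction
            shift = new_o1 - coords[index[mol_b["O1"]]]
            for s in SITE_NAMES:
                coords[index[mol_b[s]]] += shift
        out.append(
            Frame(
                time_ps=frame.time_ps,
                box=frame.box.copy(),
                coords=coords,
                ids=frame.ids.copy(),
                origin=None if frame.origin is None else frame.origin.copy(),
            )
        )
    return out
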