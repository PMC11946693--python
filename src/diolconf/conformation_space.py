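"""Algebra of torsion-letter conformation labels for 1,3-diols.

A conformation of a 1,3-diol (HO-CH2-CH2-CH2-OH) is described by four
torsion angles along the heavy-atom chain H1-O1-C1-C2-C3-O2-H2:

    chi1 = H1-O1-C1-C2   (hydroxyl end 1)
    chi2 = O1-C1-C2-C3   (main chain)
    chi3 = C1-C2-C3-O2   (main chain)
    chi4 = C2-C3-O2-H2   (hydroxyl end 2)

Each angle, measured on [0, 360), is binned into one of three staggered
rotamer states: gauche+ (G, around 60 deg), trans (T, around 180 deg) and
gauche- (G-prime, around 300 deg / -60 deg).  Torsions that involve a
hydroxyl hydrogen are written in lowercase by convention, so a conformation
is a four-letter word such as ``tGG′g``.

The bare 3**4 = 81 letter words over-count physically distinct
conformations: the molecule's two ends are chemically equivalent (reading
the word backwards describes the same conformation) and a mirror image
(which exchanges G and G-prime at every position) is energetically
indistinguishable.  These two operations generate an order-4 group whose
orbits on the 81 raw words give exactly 25 unique conformations, grouped
into four families by their main-chain letter pair: TT, TG, GG and GG′.

This module implements the binning rule, the symmetry group and orbits, a
deterministic canonical representative for each orbit, the enumeration of
the 25 unique labels, and the standard (idealised) torsion values for any
label.  The group action itself is written for letter words of arbitrary
length with configurable chain positions; the diol-specific constants are
defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PRIME",
    "TorsionQuad",
    "ConformationLabel",
    "FAMILIES",
    "SYMMETRY_OPS",
    "bin_angle",
    "label_from_torsions",
    "apply_symmetry",
    "orbit",
    "canonicalize",
    "family_of",
    "enumerate_unique",
    "enumerate_raw",
    "standard_torsions",
    "registry",
]

#: Unicode prime used when rendering gauche-minus letters.
PRIME = "′"

# Internal letter symbols.  "Gp" is gauche-minus (G-prime); case is a
# rendering concern only (chain positions upper, hydroxyl positions lower).
_LETTERS = ("T", "G", "Gp")

# Sort order used everywhere a representative or a listing order is needed:
# t < g < g-prime, compared position by position.
_LETTER_ORDER = {"T": 0, "G": 1, "Gp": 2}

# Bin centres in degrees, by letter.
_BIN_CENTER = {"G": 60.0, "T": 180.0, "Gp": 300.0}

#: The four conformation families, in canonical listing order.
FAMILIES = ("TT", "TG", "GG", "GG" + PRIME)

#: Identifiers of the four symmetry operations.
SYMMETRY_OPS = ("identity", "reverse", "mirror", "reverse_mirror")

# Chain-letter pairs considered canonical for each family.  Stage one of
# canonicalization keeps only orbit members whose chain pair is canonical;
# e.g. a GG chain is preferred over its mirror G'G' twin.
_CANONICAL_CHAIN = {
    ("T", "T"): ("T", "T"),
    ("T", "G"): ("T", "G"),
    ("G", "T"): ("T", "G"),
    ("T", "Gp"): ("T", "G"),
    ("Gp", "T"): ("T", "G"),
    ("G", "G"): ("G", "G"),
    ("Gp", "Gp"): ("G", "G"),
    ("G", "Gp"): ("G", "Gp"),
    ("Gp", "G"): ("G", "Gp"),
}

_FAMILY_NAME = {
    ("T", "T"): "TT",
    ("T", "G"): "TG",
    ("G", "G"): "GG",
    ("G", "Gp"): "GG" + PRIME,
}


class TorsionQuad(tuple):
    """The four diol torsions (chi1, chi2, chi3, chi4) in degrees on [0, 360).

    chi1 and chi4 are the hydroxyl torsions H1-O1-C1-C2 and C2-C3-O2-H2;
    chi2 and chi3 are the main-chain torsions O1-C1-C2-C3 and C1-C2-C3-O2.
    Angles outside [0, 360) are normalised on construction.
    """

    def __new__(cls, chi1: float, chi2: float, chi3: float, chi4: float):
        angles = []
        for chi in (chi1, chi2, chi3, chi4):
            if not math.isfinite(chi):
                raise ValueError(f"non-finite torsion angle: {chi!r}")
            angles.append(float(chi) % 360.0)
        return super().__new__(cls, angles)

    @property
    def chi1(self) -> float:
        return self[0]

    @property
    def chi2(self) -> float:
        return self[1]

    @property
    def chi3(self) -> float:
        return self[2]

    @property
    def chi4(self) -> float:
        return self[3]


def _render_letter(letter: str, position: str) -> str:
    base = letter[0]
    out = base.lower() if position == "hydroxyl" else base.upper()
    if letter.endswith("p"):
        out += PRIME
    return out


def _parse_letters(text: str) -> tuple[str, ...]:
    """Tokenise a label string into internal letters.

    Accepts the Unicode prime, an ASCII apostrophe, or a trailing ``p``
    (``gp``/``Gp``) as the gauche-minus marker; case is ignored.
    """
    letters: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.upper() not in ("T", "G"):
            raise ValueError(f"cannot parse conformation label {text!r} at {ch!r}")
        base = ch.upper()
        i += 1
        if base == "G" and i < len(text) and text[i] in (PRIME, "'", "p"):
            base = "Gp"
            i += 1
        letters.append(base)
    return tuple(letters)


@dataclass(frozen=True, order=False)
class ConformationLabel:
    """A four-letter torsion-state word, e.g. ``gGGg′``.

    ``letters`` holds the case-free internal symbols ("T", "G", "Gp");
    positions 1 and 4 are hydroxyl torsions (rendered lowercase), positions
    2 and 3 the main chain (rendered uppercase).  ``canonical`` marks the
    unique orbit representative chosen by :func:`canonicalize`.
    """

    letters: tuple[str, ...]
    canonical: bool = False

    def __post_init__(self) -> None:
        if len(self.letters) != 4:
            raise ValueError(f"expected 4 letters, got {self.letters!r}")
        for letter in self.letters:
            if letter not in _LETTERS:
                raise ValueError(f"unknown torsion letter {letter!r}")

    @classmethod
    def parse(cls, text: str) -> "ConformationLabel":
        return cls(_parse_letters(text))

    @property
    def chain(self) -> tuple[str, str]:
        """The main-chain letter pair (positions 2 and 3)."""
        return (self.letters[1], self.letters[2])

    def __str__(self) -> str:
        positions = ("hydroxyl", "chain", "chain", "hydroxyl")
        return "".join(_render_letter(l, p) for l, p in zip(self.letters, positions))

    def ascii(self) -> str:
        """Shell-safe rendering with ``p`` in place of the prime."""
        return str(self).replace(PRIME, "p")

    def _sort_key(self) -> tuple[int, ...]:
        return tuple(_LETTER_ORDER[l] for l in self.letters)

    def __lt__(self, other: "ConformationLabel") -> bool:
        return self._sort_key() < other._sort_key()


def bin_angle(angle: float, position: str) -> str:
    """Bin one torsion angle into its letter.

    The circle is split into three equal half-open 120-degree segments:
    [0, 120) is gauche+ (G/g), [120, 240) is trans (T/t) and [240, 360) is
    gauche- (G′/g′).  ``position`` ("chain" or "hydroxyl") selects the
    rendered case.
    """
    if position not in ("chain", "hydroxyl"):
        raise ValueError(f"position must be 'chain' or 'hydroxyl', got {position!r}")
    if not math.isfinite(angle):
        raise ValueError(f"non-finite torsion angle: {angle!r}")
    a = float(angle) % 360.0
    if a < 120.0:
        letter = "G"
    elif a < 240.0:
        letter = "T"
    else:
        letter = "Gp"
    return _render_letter(letter, position)


def _bin_internal(angle: float) -> str:
    a = float(angle) % 360.0
    return "G" if a < 120.0 else ("T" if a < 240.0 else "Gp")


def label_from_torsions(quad: TorsionQuad | Sequence[float]) -> ConformationLabel:
    """Bin all four torsions of a quad into a raw (not yet canonical) label."""
    if not isinstance(quad, TorsionQuad):
        quad = TorsionQuad(*quad)
    return ConformationLabel(tuple(_bin_internal(chi) for chi in quad))


_MIRROR = {"T": "T", "G": "Gp", "Gp": "G"}


def apply_symmetry(op: str, label: ConformationLabel) -> ConformationLabel:
    """Apply one of the four symmetry operations to a label.

    ``reverse`` reads the word end-for-end (the two hydroxyl ends of the
    molecule are equivalent); ``mirror`` swaps G and G-prime at every
    position (mirror image); ``reverse_mirror`` composes the two (the order
    does not matter, the group is abelian).
    """
    letters = label.letters
    if op == "identity":
        out = letters
    elif op == "reverse":
        out = letters[::-1]
    elif op == "mirror":
        out = tuple(_MIRROR[l] for l in letters)
    elif op == "reverse_mirror":
        out = tuple(_MIRROR[l] for l in letters[::-1])
    else:
        raise ValueError(f"unknown symmetry operation {op!r}")
    return ConformationLabel(out)


def orbit(label: ConformationLabel) -> frozenset[ConformationLabel]:
    """The set of labels symmetry-equivalent to ``label`` (size 1, 2 or 4)."""
    return frozenset(apply_symmetry(op, label) for op in SYMMETRY_OPS)


def canonicalize(label: ConformationLabel) -> ConformationLabel:
    """Return the unique canonical representative of ``label``'s orbit.

    Two-stage rule: first keep only the orbit members whose main-chain
    letter pair is the family-canonical one (TT; TG rather than GT, TG′ or
    G′T; GG rather than G′G′; GG′ rather than G′G), then take the
    lexicographic minimum under the letter order t < g < g′ compared
    position by position.  Idempotent and constant on orbits.
    """
    members = orbit(label)
    target_chain = _CANONICAL_CHAIN[label.chain]
    candidates = [m for m in members if m.chain == target_chain]
    best = min(candidates)
    return ConformationLabel(best.letters, canonical=True)


def family_of(label: ConformationLabel) -> str:
    """The conformation family (TT, TG, GG or GG′) of a label.

    The family is the main-chain letter pair of the canonical form;
    non-canonical input is canonicalized first.
    """
    if not label.canonical:
        label = canonicalize(label)
    return _FAMILY_NAME[label.chain]


def enumerate_raw() -> list[ConformationLabel]:
    """All 81 raw letter words, in lexicographic order (t < g < g′)."""
    out = []
    for a in _LETTERS:
        for b in _LETTERS:
            for c in _LETTERS:
                for d in _LETTERS:
                    out.append(ConformationLabel((a, b, c, d)))
    out.sort()
    return out


def enumerate_unique() -> list[ConformationLabel]:
    """The 25 unique canonical labels, indexed c_1 ... c_25.

    Listing order: families TT, TG, GG, GG′; within a family, lexicographic
    under t < g < g′.  This yields tTTt at c_1 through g′GG′g at c_25.
    """
    unique = {canonicalize(lbl) for lbl in enumerate_raw()}
    family_rank = {name: i for i, name in enumerate(FAMILIES)}
    return sorted(unique, key=lambda l: (family_rank[family_of(l)], l._sort_key()))


def standard_torsions(label: ConformationLabel) -> TorsionQuad:
    """Idealised staggered torsions for a label: T -> 180, G -> 60, G′ -> 300.

    Round-trips: ``label_from_torsions(standard_torsions(x)) == x`` (up to
    the canonical flag) for every label.
    """
    return TorsionQuad(*(_BIN_CENTER[l] for l in label.letters))


def registry() -> pd.DataFrame:
    """The 25-label registry as a tidy table.

    Columns: index (c_1..c_25), label, family, orbit_size, orbit_members
    (space-separated), chi1..chi4 standard torsions.
    """
    rows = []
    for i, lbl in enumerate(enumerate_unique(), start=1):
        orb = sorted(orbit(lbl))
        chi = standard_torsions(lbl)
        rows.append(
            {
                "index": f"c_{i}",
                "label": str(lbl),
                "family": family_of(lbl),
                "orbit_size": len(orb),
                "orbit_members": " ".join(str(m) for m in orb),
                "chi1": chi.chi1,
                "chi2": chi.chi2,
                "chi3": chi.chi3,
                "chi4": chi.chi4,
            }
        )
    return pd.DataFrame(rows)
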