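"""Torsion-letter algebra: binning, symmetry group, canonical labels."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from diolconf.conformation_space import (
    PRIME,
    ConformationLabel,
    FAMILIES,
    SYMMETRY_OPS,
    TorsionQuad,
    apply_symmetry,
    bin_angle,
    canonicalize,
    enumerate_raw,
    enumerate_unique,
    family_of,
    label_from_torsions,
    orbit,
    registry,
    standard_torsions,
)

# The 25 unique conformation names with their published indices, frozen as
# the reference the enumeration must reproduce character for character.
TABLE_NAMES = [
    "tTTt", "tTTg", "gTTg", "gTTg′",
    "tTGt", "tTGg", "tTGg′", "gTGt", "gTGg", "gTGg′", "g′TGt", "g′TGg", "g′TGg′",
    "tGGt", "tGGg", "tGGg′", "gGGg", "gGGg′", "g′GGg′",
    "tGG′t", "tGG′g", "tGG′g′", "gGG′g", "gGG′g′", "g′GG′g",
]

labels_st = st.builds(
    ConformationLabel,
    st.tuples(*[st.sampled_from(["T", "G", "Gp"])] * 4),
)


class TestBinning:
    @pytest.mark.parametrize(
        "angle,position,expected",
        [
            (67.6, "hydroxyl", "g"),       # crystal-structure chi1
            (180.0, "chain", "T"),
            (-82.5, "hydroxyl", "g" + PRIME),  # crystal chi4, normalised to 277.5
            (0.0, "chain", "G"),
            (119.999, "hydroxyl", "g"),
            (120.0, "chain", "T"),         # boundary goes to the upper bin
            (240.0, "chain", "G" + PRIME),
            (359.999, "hydroxyl", "g" + PRIME),
        ],
    )
    def test_examples(self, angle, position, expected):
        assert bin_angle(angle, position) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bin_angle(float("nan"), "chain")
        with pytest.raises(ValueError):
            TorsionQuad(float("inf"), 0, 0, 0)

    @given(st.floats(min_value=0.0, max_value=359.999999))
    @settings(max_examples=200, deadline=None)
    def test_total_on_circle_with_120_degree_bins(self, angle):
        """Every angle falls in exactly one of three 120-degree intervals."""
        letter = bin_angle(angle, "chain")
        lo = {"G": 0.0, "T": 120.0, ("G" + PRIME): 240.0}[letter]
        assert lo <= angle < lo + 120.0


class TestWorkedLabeling:
    def test_crystal_structure_torsions(self):
        """The published crystal torsions of 1,3-propanediol label as gGGg′."""
        assert str(label_from_torsions((67.6, 61.5, 69.4, -82.5))) == "gGGg" + PRIME

    def test_gas_phase_optimised_torsions_label_identically(self):
        assert str(label_from_torsions((65.2, 46.2, 49.1, -76.0))) == "gGGg" + PRIME

    def test_all_trans(self):
        assert str(label_from_torsions((180, 180, 180, 180))) == "tTTt"


class TestSymmetryGroup:
    def test_elementary_ops(self):
        assert str(apply_symmetry("reverse", ConformationLabel.parse("tTTg"))) == "gTTt"
        assert (
            str(apply_symmetry("mirror", ConformationLabel.parse("tGG′g")))
            == "tG′Gg′"
        )
        assert (
            str(apply_symmetry("reverse_mirror", ConformationLabel.parse("gGGg′")))
            == "gG′G′g′"
        )

    @given(labels_st)
    @settings(max_examples=100, deadline=None)
    def test_involutions(self, lbl):
        for op in ("reverse", "mirror"):
            assert apply_symmetry(op, apply_symmetry(op, lbl)) == lbl

    @given(labels_st)
    @settings(max_examples=100, deadline=None)
    def test_commutation(self, lbl):
        a = apply_symmetry("mirror", apply_symmetry("reverse", lbl))
        b = apply_symmetry("reverse", apply_symmetry("mirror", lbl))
        assert a == b == apply_symmetry("reverse_mirror", lbl)

    def test_orbit_sizes(self):
        assert len(orbit(ConformationLabel.parse("tTTg"))) == 4
        assert orbit(ConformationLabel.parse("tTTt")) == {
            ConformationLabel.parse("tTTt")
        }
        assert {str(l) for l in orbit(ConformationLabel.parse("g′GGg′"))} == {
            "g′GGg′",
            "gG′G′g",
        }

    def test_burnside_partition(self):
        """Orbits partition the 81 raw words; sizes follow Burnside's count."""
        orbits = {frozenset(orbit(l)) for l in enumerate_raw()}
        sizes = sorted(len(o) for o in orbits)
        assert sum(sizes) == 81
        assert len(orbits) == 25
        # fixed points: reverse has 9 palindromes, mirror 9 self-conjugates,
        # their composition 1 => (81 + 9 + 9 + 1) / 4 = 25
        assert sizes.count(1) == 1
        assert 1 + 2 * sizes.count(2) + 4 * sizes.count(4) == 81


class TestCanonicalization:
    @pytest.mark.parametrize(
        "raw,canon",
        [
            ("g′GGg′", "g′GGg′"),  # chain GG preferred over its G′G′ mirror
            ("gTTt", "tTTg"),
            ("g′GG′t", "tGG′g"),
            ("gG′G′g", "g′GGg′"),
            ("tG′Tg", "g′TGt"),
        ],
    )
    def test_examples(self, raw, canon):
        got = canonicalize(ConformationLabel.parse(raw))
        assert str(got) == canon.replace("′", PRIME)
        assert got.canonical

    @given(labels_st)
    @settings(max_examples=200, deadline=None)
    def test_idempotent_and_constant_on_orbits(self, lbl):
        c = canonicalize(lbl)
        assert canonicalize(c) == c
        for member in orbit(lbl):
            assert canonicalize(member) == c

    def test_ascii_alias_round_trip(self):
        lbl = ConformationLabel.parse("gGGgp")
        assert str(lbl) == "gGGg" + PRIME
        assert ConformationLabel.parse(lbl.ascii()) == lbl
        assert ConformationLabel.parse("gGGg'") == lbl


class TestEnumeration:
    def test_reproduces_published_names_in_order(self):
        assert [str(l) for l in enumerate_unique()] == TABLE_NAMES

    def test_family_partition_sizes(self):
        fams = [family_of(l) for l in enumerate_unique()]
        counts = {f: fams.count(f) for f in FAMILIES}
        assert counts == {"TT": 4, "TG": 9, "GG": 6, "GG" + PRIME: 6}

    def test_orbits_tile_the_raw_space_disjointly(self):
        seen: set = set()
        for lbl in enumerate_unique():
            o = orbit(lbl)
            assert not (o & seen)
            seen |= o
        assert len(seen) == 81

    @pytest.mark.parametrize(
        "label,family",
        [("tGG′g", "GG′"), ("tTTt", "TT"), ("gTGg′", "TG"), ("gG′G′g", "GG")],
    )
    def test_family_of(self, label, family):
        assert family_of(ConformationLabel.parse(label)) == family.replace("′", PRIME)


class TestStandardTorsions:
    def test_examples(self):
        assert tuple(standard_torsions(ConformationLabel.parse("tGG′g"))) == (
            180.0, 60.0, 300.0, 60.0,
        )
        assert tuple(standard_torsions(ConformationLabel.parse("tTTt"))) == (180.0,) * 4

    def test_round_trip_over_all_unique(self):
        for lbl in enumerate_unique():
            back = label_from_torsions(standard_torsions(lbl))
            assert back.letters == lbl.letters


def test_registry_export(tmp_path):
    reg = registry()
    assert len(reg) == 25
    assert reg["orbit_size"].sum() == 81
    assert list(reg["index"]) == [f"c_{i}" for i in range(1, 26)]
    path = tmp_path / "registry.csv"
    reg.to_csv(path, index=False)
    import pandas as pd

    back = pd.read_csv(path)
    assert list(back["label"]) == TABLE_NAMES
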