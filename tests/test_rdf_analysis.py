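"""Radial distribution function: normalisation, oracle equivalence, peak fits."""

import numpy as np
import pytest

from diolconf import synthetic_data as syn
from diolconf import trajectory_io as tio
from diolconf.conformation_space import PRIME
from diolconf.rdf_analysis import (
    RDFCurve,
    compute_rdf,
    decompose_peaks,
    rdf_conformer_estimate,
)
from diolconf.state_series import label_trajectory, occupancy
from diolconf.trajectory_io import Frame, Topology


def ideal_gas_frames(rng, n_mol, box, n_frames):
    """Frames whose 'oxygens' are uniform random points (labels irrelevant)."""
    frames = []
    ids = np.arange(1, 7 * n_mol + 1)
    for f in range(n_frames):
        coords = rng.random((7 * n_mol, 3)) * box
        frames.append(Frame(time_ps=float(f), box=np.full(3, box), coords=coords, ids=ids))
    return frames


def brute_force_histogram(frames, topology, selection, edges):
    """Naive all-pairs reference: explicit double loop per frame."""
    counts = np.zeros(len(edges) - 1)
    for frame in frames:
        oxy = []
        for m, mol in enumerate(topology.molecules):
            oxy.append((m, frame.position(mol["O1"])))
            oxy.append((m, frame.position(mol["O2"])))
        for a in range(len(oxy)):
            for b in range(a + 1, len(oxy)):
                ma, pa = oxy[a]
                mb, pb = oxy[b]
                if selection == "inter" and ma == mb:
                    continue
                if selection == "intra" and ma != mb:
                    continue
                delta = pb - pa
                delta -= frame.box * np.round(delta / frame.box)
                d = np.linalg.norm(delta)
                k = np.searchsorted(edges, d, side="right") - 1
                if 0 <= k < len(counts) and d < edges[-1]:
                    counts[k] += 1
    return counts / len(frames)


class TestComputeRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(42)
        frames = ideal_gas_frames(rng, n_mol=40, box=20.0, n_frames=60)
        top = syn.default_topology(40)
        curve = compute_rdf(tio.from_frames(frames), top, selection="all",
                            bin_width=0.25, r_max=9.0)
        # skip the first few bins (tiny shell volume -> large relative noise)
        sel = curve.r > 2.0
        assert np.abs(curve.g[sel] - 1.0).mean() < 0.05
        assert np.max(np.abs(curve.g[sel] - 1.0)) < 0.3

    @pytest.mark.parametrize("selection", ["all", "inter", "intra"])
    def test_matches_brute_force_oracle(self, selection):
        rng = np.random.default_rng(3)
        model = syn.TorsionChainModel.solution_like()
        sim = syn.simulate_labels(model, n_molecules=5, n_frames=3, seed=rng)
        frames = syn.build_coordinates(sim.quads, box=(22, 22, 22), seed=rng)
        top = syn.default_topology(5)
        curve = compute_rdf(tio.from_frames(frames), top, selection=selection,
                            bin_width=0.1, r_max=8.0)
        edges = np.arange(0, 8.0 + 0.1 / 2, 0.1)
        ref = brute_force_histogram(frames, top, selection, edges)
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        n_pairs = {"all": 45, "intra": 5, "inter": 40}[selection]
        ideal = n_pairs * shell / 22.0**3
        np.testing.assert_allclose(curve.g, ref / ideal, atol=1e-10)

    def test_fixed_pair_occupies_single_bin(self):
        ids = np.array([1, 2, 3, 4, 5, 6, 7])
        coords = np.zeros((7, 3))
        coords[5] = [3.0, 0, 0]  # O2 exactly 3 A from O1
        coords[:5] = np.linspace(0, 1, 5)[:, None] * np.array([0, 1.0, 0])
        frame = Frame(time_ps=0.0, box=np.full(3, 40.0), coords=coords, ids=ids)
        top = syn.default_topology(1)
        curve = compute_rdf(tio.from_frames([frame]), top, selection="intra",
                            bin_width=0.05, r_max=10.0)
        occupied = np.nonzero(curve.g)[0]
        assert len(occupied) == 1
        assert curve.r[occupied[0]] == pytest.approx(3.025)

    def test_r_max_beyond_half_box_rejected(self):
        rng = np.random.default_rng(1)
        frames = ideal_gas_frames(rng, 4, 15.0, 1)
        with pytest.raises(ValueError, match="half the smallest box edge"):
            compute_rdf(tio.from_frames(frames), syn.default_topology(4), r_max=9.0)


def synthetic_three_peak_curve(shape="gaussian", noise=0.01, seed=0):
    """A known mixture (areas 10/30/60 %) sampled on an RDF grid."""
    rng = np.random.default_rng(seed)
    r = np.arange(2.0, 6.0, 0.02)
    centers = (2.8, 3.7, 4.8)
    widths = (0.12, 0.2, 0.25)
    fractions = (0.10, 0.30, 0.60)
    g = np.zeros_like(r)
    for c, w, frac in zip(centers, widths, fractions):
        if shape == "gaussian":
            amp = frac / (w * np.sqrt(2 * np.pi))
            g += amp * np.exp(-0.5 * ((r - c) / w) ** 2)
        else:
            amp = frac / (w * np.pi)
            g += amp / (1 + ((r - c) / w) ** 2)
    g += rng.normal(0, noise * g.max(), size=r.shape)
    curve = RDFCurve(r=r, g=np.clip(g, 0, None), bin_width=0.02, r_max=6.0,
                     n_frames=1, selection="all")
    return curve, np.array(fractions) * 100


class TestDecomposePeaks:
    def test_recovers_known_gaussian_areas(self):
        curve, truth = synthetic_three_peak_curve("gaussian", seed=11)
        decomp = decompose_peaks(curve, n_components=3, shape="gaussian")
        np.testing.assert_allclose(decomp.area_fractions, truth, atol=2.0)
        assert np.all(np.diff(decomp.centers) > 0)
        assert decomp.area_fractions.sum() == pytest.approx(100.0)

    def test_single_component_is_everything(self):
        curve, _ = synthetic_three_peak_curve("gaussian", seed=2)
        # restrict to the isolated first peak
        mask = curve.r < 3.2
        sub = RDFCurve(r=curve.r[mask], g=curve.g[mask], bin_width=0.02,
                       r_max=3.2, n_frames=1, selection="all")
        decomp = decompose_peaks(sub, n_components=1, shape="gaussian",
                                 window=(2.0, 3.15))
        assert decomp.area_fractions[0] == pytest.approx(100.0)

    def test_lorentzian_and_gaussian_bracket_truth(self):
        """Fitting the wrong shape shifts fractions but stays in a sane band."""
        curve, truth = synthetic_three_peak_curve("gaussian", seed=7)
        gau = decompose_peaks(curve, 3, "gaussian")
        lor = decompose_peaks(curve, 3, "lorentzian")
        assert not np.allclose(gau.area_fractions, lor.area_fractions)
        np.testing.assert_allclose(gau.area_fractions, truth, atol=2.0)
        np.testing.assert_allclose(lor.area_fractions, truth, atol=10.0)

    def test_too_few_maxima_rejected(self):
        r = np.arange(2.0, 5.0, 0.02)
        g = np.exp(-0.5 * ((r - 3.0) / 0.2) ** 2)
        curve = RDFCurve(r=r, g=g, bin_width=0.02, r_max=5.0, n_frames=1,
                         selection="all")
        with pytest.raises(ValueError, match="local maxima"):
            decompose_peaks(curve, n_components=3)


class TestConformerEstimate:
    def test_identity_mapping(self):
        curve, _ = synthetic_three_peak_curve("gaussian", seed=4)
        decomp = decompose_peaks(curve, 3, "gaussian")
        est = rdf_conformer_estimate(
            decomp, {0: "GG" + PRIME, 1: "TG", 2: "TT"}
        )
        np.testing.assert_allclose(
            [est["GG" + PRIME], est["TG"], est["TT"]], decomp.area_fractions
        )

    @pytest.fixture(scope="class")
    def solution_frames(self):
        rng = np.random.default_rng(2024)
        model = syn.TorsionChainModel.solution_like()
        sim = syn.simulate_labels(model, 12, 200, seed=rng)
        frames = syn.build_coordinates(sim.quads, box=(30, 30, 30), seed=rng)
        return frames, syn.default_topology(12)

    # initial centres: family O..O distances of the builder's geometry
    INIT = np.array([2.6, 4.25, 4.85])

    def test_clean_system_estimate_tracks_direct_fractions(self, solution_frames):
        """Without intermolecular contacts the intramolecular RDF areas
        approximate the direct family fractions (to fit-shape tolerance)."""
        frames, top = solution_frames
        curve = compute_rdf(tio.from_frames(frames), top, selection="intra",
                            bin_width=0.03, r_max=7.0)
        decomp = decompose_peaks(curve, 3, "gaussian", init_centers=self.INIT,
                                 window=(2.2, 5.2))
        est = rdf_conformer_estimate(
            decomp, {0: "GG" + PRIME, 1: "TG", 2: "TT"}
        )
        series = label_trajectory(tio.from_frames(frames), top)
        direct = occupancy(series).attrs["families"]
        for fam in ("TT", "TG", "GG" + PRIME):
            assert est[fam] == pytest.approx(direct[fam], abs=10.0)

    def test_contact_injection_inflates_first_peak_only(self, solution_frames):
        """Intermolecular O...O contacts at 2.8 A inflate the short-distance
        peak area while the direct torsion-label fractions are untouched."""
        frames, top = solution_frames
        first_peak = []
        direct = []
        for n_pairs in (0, 2, 4):
            mod = syn.inject_intermolecular_contacts(frames, top, n_pairs, seed=9)
            series = label_trajectory(tio.from_frames(mod), top)
            occ = occupancy(series).attrs["families"]
            direct.append(occ)
            curve = compute_rdf(tio.from_frames(mod), top, selection="all",
                                bin_width=0.05, r_max=7.0)
            decomp = decompose_peaks(curve, 3, "gaussian", init_centers=self.INIT,
                                     window=(2.0, 5.6), baseline=True)
            first_peak.append(decomp.area_fractions[0])

        assert first_peak[0] < first_peak[1] < first_peak[2]
        for occ in direct[1:]:
            np.testing.assert_allclose(occ.values, direct[0].values, atol=1e-12)
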