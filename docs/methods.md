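# Methods

## The problem

Small flexible diols such as 1,3-propanediol (HO–CH₂–CH₂–CH₂–OH) populate
many conformations in solution, and the traditional way of estimating
their relative populations from molecular-dynamics trajectories — fitting
peaks of the hydroxyl-oxygen radial distribution function g_OO(r) — is
ambiguous: intermolecular hydrogen-bonded O…O contacts fall in the same
distance range (~2.8 Å) as the intramolecular contact of the most folded
conformers, so short-distance peak area conflates two distinct phenomena.
`diolconf` implements the direct alternative: classify every molecule in
every frame by its torsion angles, then derive populations, lifetimes and
distance statistics from the resulting discrete state series, using the
RDF route only as the audited baseline.

## Conformation labels and symmetry

A conformation is the four-letter word of binned torsions along
H1–O1–C1–C2–C3–O2–H2:

| slot | torsion | rendered |
|------|-------------------|----------|
| χ₁ | H1–O1–C1–C2 | lowercase (hydroxyl) |
| χ₂ | O1–C1–C2–C3 | uppercase (chain) |
| χ₃ | C1–C2–C3–O2 | uppercase (chain) |
| χ₄ | C2–C3–O2–H2 | lowercase (hydroxyl) |

Each angle on [0°, 360°) is binned into three equal half-open segments:
[0, 120) → G/g (gauche+), [120, 240) → T/t (trans), [240, 360) → G′/g′
(gauche−). Boundary angles (exactly 120° or 240°) go to the upper bin; the
choice is arbitrary but deterministic and of measure zero for real
trajectories.

The 3⁴ = 81 raw words over-count physical conformations. Two operations
generate an abelian group of order 4 acting on words: *reversal* (the two
molecule ends are chemically equivalent) and *mirror* (G ↔ G′ everywhere;
enantiomeric conformations are indistinguishable). By Burnside's lemma the
number of orbits is (81 + 9 + 9 + 1)/4 = 25: reversal fixes the 9
palindromes, mirror the 9 self-conjugate words, and their composition only
tTTt. The orbits split into four families by main-chain letters: TT (4
labels), TG (9), GG (6), GG′ (6).

**Canonical representative.** The literature fixes conventional names for
the 25 conformations but no selection rule, and a plain whole-word
lexicographic minimum does not reproduce them (it would prefer gG′G′g over
the conventional g′GGg′). `canonicalize` therefore uses a two-stage rule
of this package's own construction that does reproduce every conventional
name: (1) keep only orbit members whose chain pair is the family-canonical
one (TT; TG rather than GT/TG′/G′T; GG rather than G′G′; GG′ rather than
G′G); (2) among those, take the lexicographic minimum under the letter
order t < g < g′ compared position by position. The registry order (c_1 =
tTTt … c_25 = g′GG′g) lists families TT, TG, GG, GG′ and sorts
lexicographically within each, which again matches the conventional
indices, so outputs are directly comparable with published tables.

Prime letters are rendered with U+2032; ASCII aliases (`g'`, `gp`) are
accepted on input so labels survive shells and CSV round trips.

## Geometry

Dihedrals use the atan2 formulation of the right-handed (IUPAC-sign)
torsion, mapped from (−180°, 180°] to [0°, 360°). The sign convention is
pinned by the worked crystal-structure example: the published torsions
(67.6, 61.5, 69.4, −82.5)° must label gGGg′, which forces −82.5° → 277.5°
→ g′. Bond triples with cross-product norm < 1e−10 Å² (far below thermal
noise) are treated as degenerate: the molecule-frame is marked missing,
logged, and excluded from all statistics rather than interpolated — a
lifetime must never bridge a fabricated state.

All distances use the minimum-image convention in orthorhombic boxes.
Molecules are unwrapped along their bonded chain before any dihedral is
evaluated, so wrapped and unwrapped trajectories give identical labels. A
bonded-neighbour sanity bound (default 2.0 Å) catches mis-assigned
topologies early.

## State series, occupancy, lifetimes

`label_trajectory` produces one raw and one canonical label per molecule
per frame. Occupancy φ is the percentage of labelled configurations
(N_conf = frames × molecules, minus missing markers, which are reported
separately) carrying each canonical label; family fractions are sums over
member labels, so both levels total 100%.

Lifetimes are maximal constant runs of the per-molecule sequence at the
recording stride (1 ps in the standard setup, hence a minimum resolvable
lifetime of 1 ps; a run of k frames lives k × stride). Conventions:

- runs are attributed to the **canonical** label, so a flip between two
  symmetry-equivalent raw labels does not break a run;
- **family-level** runs are encoded on the family sequence directly, so
  hydroxyl rotations within a family do not break family runs — which is
  why family lifetimes exceed label lifetimes by roughly an order of
  magnitude when hydroxyl dynamics are fast;
- boundary-touching runs are **included** by default (policy
  `exclude_boundary` is available). Including them preserves the exact
  conservation property Σ durations = n_frames × stride per molecule,
  which the test suite uses; for run counts ≫ 1 the two policies agree.

Summary exports round t_av to 0.1 ps (the conventional reporting
precision); machine-readable outputs keep full precision.

## Radial distribution functions

`compute_rdf` histograms minimum-image hydroxyl-O pair distances
(selection: all pairs, intermolecular only, or intramolecular only) and
normalises by the ideal-gas expectation n_pairs·4πr²Δr/V using the actual
pair count of the selection, so every selection satisfies g → 1 for
uniform random positions. Defaults: bin width 0.05 Å, r_max = min(10 Å,
half the smallest box edge); r_max above the half-edge is rejected.

`decompose_peaks` fits a sum of Gaussians or Lorentzians by bounded
least squares (scipy `curve_fit`/TRF). Numerical choices:

- initial centres from the most prominent local maxima unless supplied;
- the fit window runs from the first populated bin to the first local
  minimum after the last component, excluding the long-range g ≈ 1
  plateau, unless supplied;
- centres may shift at most 0.5 Å from their initial values and widths
  are capped at 0.6 Å — without these bounds a component can detach from
  its peak and degenerate into a second baseline on noisy curves;
- an optional fitted non-negative constant baseline (off by default)
  absorbs the unstructured intermolecular plateau when fitting "all-pair"
  curves; baseline area is excluded from peak areas;
- areas are integrated analytically (A·w·√(2π) for Gaussians, A·w·π for
  Lorentzians) and reported as percentages of their sum;
- non-convergence raises with the window and shape in the message; there
  is no silent fallback.

`rdf_conformer_estimate` maps component area fractions to family
hypotheses — the naive estimate the direct method audits.

## Synthetic data: what it emulates and what it does not

The generator replaces an MD engine for testing purposes. Each of the
four torsion slots of each molecule evolves as an independent first-order
Markov chain over the three bins at the recording stride; realised angles
are bin centre + truncated-Gaussian jitter (s.d. 10°, hard truncation
±30°). The truncation guarantees a generated angle never crosses a bin
boundary, making end-to-end label agreement an exact test, not a
statistical one. Stationary distributions and geometric dwell times
(mean 1/(1−p_stay) steps) are analytic, which is what makes occupancy and
lifetime recovery quantitatively checkable.

Two stock models:

- `uniform(stay)` — symmetric chains, uniform stationary law; used for
  recovery tests (stay = 0.75 gives the 4 ps mean dwell checked in the
  acceptance suite).
- `solution_like()` — chain slots favour trans with stationary weight
  0.866 (giving family fractions near TT 75%, TG 23%, GG+GG′ ≈ 2%, the
  regime of a dilute aqueous diol solution), hydroxyl slots uniform with
  mean dwell 4 steps; built from reversible matrices P_ij = a·π_j (i≠j).
  The default demonstration size, 8 molecules × 5000 frames = 40,000
  configurations, matches the smallest production-scale analysis.

Coordinates come from sequential internal-to-Cartesian chain extension
(NeRF) with standard organic bond lengths/angles (O–H 0.96 Å, C–O 1.43 Å,
C–C 1.53 Å; angles 108.5–112°), followed by a uniform random rigid pose in
the box. With this geometry the family intramolecular O…O distances are
≈ 4.84 Å (TT), 4.23 Å (TG), 3.48 Å (GG) and 2.60 Å (GG′), giving the
well-separated multi-peak structure the RDF analysis needs.
`inject_intermolecular_contacts` rigidly translates the second molecule of
chosen pairs so one intermolecular O…O distance equals a target (default
2.8 Å) without touching any torsion — the construction behind the
first-peak bias demonstration.

What the generator does **not** emulate: water and solvent structure,
correlated torsion dynamics (a joint 81-state chain would be needed;
slots are independent by design to keep ground truth analytic), realistic
transition kinetics or barriers, thermal bond/angle vibration (only
torsions fluctuate, so intramolecular distance peaks are much narrower
than in real MD — the RDF control test uses 0.03 Å bins for this reason),
and excluded volume between molecules (poses are independent). Passing
tests therefore validate the *analysis machinery*, not any force field.

## Problem sizes used in the shipped checks

Enumeration checks are exhaustive (81 words). The end-to-end pipeline
check uses 8 molecules × 5000 frames; Markov recovery uses a single
molecule over 10⁵ steps with 3-standard-error tolerances (integrated
autocorrelation time (1+λ)/(1−λ), λ = 0.625, is used to deflate the
effective sample size); RDF checks use 12–40 molecules over 60–200
frames. These sizes give comfortable statistical margins while keeping
the full suite in the minutes range.

## Reproducing a production analysis

The solution-composition and lifetime tables for a real dilute aqueous
solution require a nanosecond-scale all-atom MD trajectory (e.g. OPLS-AA
diol in TIP4P-Ew water under NPT at 298.15 K, coordinates recorded every
1 ps) — input this package deliberately does not generate.
`examples/reference_analysis.yaml` is the exact analysis configuration to
apply to such a trajectory: pointing it at a production LAMMPS dump and
running `diolconf analyze` yields the per-label φ/t_av table, the t_max
table and the per-family lifetime table for that system.

## Known limitations

- Orthorhombic boxes only; triclinic dumps are rejected loudly.
- Labels are hard assignments; no core-set/committor smoothing of bin
  crossings, so real MD at high temperature will show some boundary
  recrossing noise in lifetimes (the original 1 ps-stride convention).
- The RDF peak decomposition is a generic bounded mixture fit; strongly
  overlapping peaks (e.g. a GG shoulder between TG and GG′) are absorbed
  by neighbours when fewer components are requested than families exist.
- No hydrogen-bond criterion is implemented; "contact" means an O…O
  distance, not an energetic assignment.
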