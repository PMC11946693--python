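# Reference analysis configuration for a production MD trajectory of
# 1,3-propanediol in dilute aqueous solution (64 diol molecules, cubic box,
# coordinates recorded every 1 ps, e.g. a LAMMPS NPT run at 298.15 K).
#
# Pointing `trajectory` at such a dump and running
#
#     diolconf analyze examples/reference_analysis.yaml -o results/
#
# produces the per-label occupancy table (phi, t_av), the per-label t_max
# table and the per-family lifetime table for the solution, in the layout
# produced by `diolconf analyze` for any system.
trajectory: trajectory.lammpstrj   # replace with the production dump path
format: lammps-dump
timestep_ps: 0.001                 # 1 fs MD timestep -> dump TIMESTEP * 0.001 ps
stride_ps: 1.0                     # coordinates recorded every 1 ps
topology:
  # seven named diol sites of the first molecule, then a fixed atom-id
  # stride per molecule; water atom ids fall outside these ranges and are
  # ignored by the analysis
  sites: {H1: 1, O1: 2, C1: 3, C2: 4, C3: 5, O2: 6, H2: 7}
  stride_atoms: 7
  n_molecules: 64
labels: true
lifetimes: true
truncation: include
rdf: true
rdf_selection: all
rdf_bin_width: 0.05
rdf_r_max: null                    # min(10 A, half the smallest box edge)
seed: 0
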