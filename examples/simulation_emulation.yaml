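# Simulation-emulation preset: Brownian multi-chain ensembles analyzed with
# the 4.6 ns MSD window, finite-size and isotope corrections, cluster
# statistics at 6/7 Å, and the sphere-confined EISF fixture.
workflow: trajectory
seed: 1
outdir: runs/simulation
hydro:
  temperature: 298.0
  isotope: D2O
traj_options:
  n_replicates: 5
  window: [0.0, 4.6]
  cutoffs: [6.0, 7.0]
  truth:
    n_chains: 10
    D_t: 15.0
    box_edge: 100.0
    dt: 0.1
    n_steps: 200
  eisf:
    n_atoms: 64
    radius: 1.2
    n_steps: 2000
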