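# Experiment-emulation preset: synthetic instrument-like spectra at the
# measured 50 mg/mL, 298 K condition, fitted per-q and globally.
workflow: qens
seed: 1
outdir: runs/experiment
concentration: 50.0
hydro:
  temperature: 298.0
  isotope: D2O
  salt_molarity: 0.15
qens_options:
  n_starts: 5
  solvent_policy:
    mode: fixed
    width: 50.0
  truth:
    D_apparent: 16.8
    D_int: 30.0
    tau: 0.02
    noise_scale: 0.02
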