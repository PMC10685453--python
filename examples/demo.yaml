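# Demo pipeline: 2D membrane landscape, both protomers, ~1 minute on one CPU.
# Any omitted key falls back to the package defaults (see memperm.pipeline).
seed: 2024
temperature: 310.0

landscape:
  dimensionality: 2
  interfacial_min_depth: 15.0     # kJ/mol below bulk water
  interfacial_min_position: 5.0   # Å
  core_barrier_height: 6.0        # kJ/mol above the interfacial minimum
  widths: {well: 2.0, barrier: 3.0, coupling: 1.5}
  coupling_strength: 25.0         # ring–tail separation penalty, kJ/mol
  z_max: 15.0                     # reflective walls, Å

protomer:
  core_penalty: 30.0              # charged-species core destabilisation, kJ/mol
  pKa: 10.4
  pH: 7.0

diffusion: {form: constant, D_bulk: 0.5, D_core: 0.5, transition_width: 3.0}

metad:
  dt: 0.02                        # ps
  n_steps: 600000                 # 12 ns per protomer
  w0: 1.2                         # initial hill height, kJ/mol
  sigma: 0.5                      # hill width, Å
  pace: 2.0                       # deposition period, ps
  bias_factor_neutral: 20.0
  bias_factor_charged: 25.0
  grid_spacing: 0.1               # bias grid, Å
  record_every: 10

fes:
  burn_in: 0.1111111111111111
  bin_width: 0.5                  # histogram bins, Å
  n_blocks: 3
  bulk_cut: 12.0                  # |z| >= this is bulk water, Å

mfep: {n_images: 48, tol: 0.5, max_iter: 2000}

permeability:
  window_k: 10.0                  # restraint spring, kJ/mol/Å²
  n_windows: 9
  window_steps: 150000
  window_dt: 0.01
  window_record_every: 5
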