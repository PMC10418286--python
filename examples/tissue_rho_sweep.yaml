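# Sweep source-detector separation for a tissue-like medium imaged with
# an Orca-Flash-class camera: 3-px speckles, unpolarized light, 100x100
# pixel frames. Reduce epsilon_N / grid for a quick look.
medium:
  mu_a: 0.1          # 1/cm
  mu_s_prime: 10.0   # 1/cm
  n_index: 1.33
  alpha_Db: 1.0e-8   # cm^2/s
  wavelength: 785.0  # nm
detector: orca_flash
optics:
  speckle_diameter: 3
  beta: 0.5
geometry:
  rho: [1.0, 2.0, 3.0]     # cm
  exposures: [5.0e-3]      # s
  source_irradiance: 1.0   # W/cm^3
  frames_per_tauc: 10
sampling:
  grid: [64, 64]
  epsilon_N: 20
  n_draws: 500
master_seed: 1
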