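# Default generative band model for the fluorescein-like two-species probe.
#
# Bands are Gaussians in wavenumber space: value(nu) = peak * exp(-(nu-center)^2 / (2 width^2)).
# Absorption band triples are (center cm^-1, width cm^-1, peak molar extinction M^-1 cm^-1);
# emission triples carry a dimensionless shape amplitude instead of an extinction.
# Centers place the dianion main band at 490 nm and the monoanion doublet at
# 475/454 nm; the minor zwitterion band sits near 437 nm with low extinction.
spectral:
  pKa_at_25C: 6.45
  dH_true: 7400.0            # J mol^-1, van't Hoff enthalpy of M -> D + H+
  noise_rel: 0.005           # multiplicative relative noise per spectral point
  total_dye_M: 8.0e-06       # mol L^-1
  path_cm: 1.0
  phi_ratio_D_over_M: 2.5    # fluorescence quantum-yield ratio dianion/monoanion
  grid_nm: [400.0, 560.0, 0.5]           # absorption axis: start, stop, step
  emission_grid_nm: [480.0, 700.0, 0.5]  # emission axis
  bands_cm:
    D:
      - [20408.16, 700.0, 88000.0]   # 490 nm main dianion band
      - [21900.0, 900.0, 30000.0]    # vibronic shoulder
    M:
      - [21052.63, 800.0, 33000.0]   # 475 nm
      - [22026.43, 900.0, 29000.0]   # 454 nm
    Z:
      - [22883.30, 1100.0, 12000.0]  # 437 nm, minor form
  emission_bands_cm:
    D:
      - [19531.25, 750.0, 1.0]       # 512 nm
    M:
      - [19230.77, 850.0, 1.0]       # 520 nm
  # Band-center displacement model: centers shift by
  #   dnu_dT * (T - 298.15) + dnu_ddeltaf * (deltaf - deltaf_water).
  # dnu_ddeltaf is set so that the 50% w/w glycerol medium (see media.yaml)
  # moves the absorption maximum 4 nm to the red relative to buffer at 25 degC.
  shift_dnu_dT: -1.2         # cm^-1 K^-1 (bathochromic on heating)
  shift_dnu_ddeltaf: 6323.12 # cm^-1 per unit orientation-polarizability deltaf

box:
  box_edge: 4.0        # nm, cubic
  n_water: 200
  n_cosolvent: 20
  cosolvent: GLY
  enrichment: 1.0      # local cosolvent weighting inside the shell (1 = bulk)
  shell_radius: 1.0    # nm, sphere around the solute centroid
  hbond_fraction: 0.0  # fraction of frames with a forced donor per acceptor
  n_frames: 20
  min_center_distance: 0.15  # nm, rejection-sampling clash cutoff
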