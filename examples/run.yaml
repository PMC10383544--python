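# Example end-to-end pipeline configuration.
# Unspecified keys take the defaults materialized into resolved-config.yaml.
mode: full
seed: 1
spectral:
  noise_rel: 0.005
media:
  - {name: buffer, cosolvent: none, mass_fraction_percent: 0.0,
     dH_true: 7400.0, pKa_at_25C: 6.45}
  - {name: sucrose30, cosolvent: sucrose, mass_fraction_percent: 30.0,
     dH_true: 4600.0, pKa_at_25C: 6.55}
  - {name: glycerol40, cosolvent: glycerol, mass_fraction_percent: 40.0,
     dH_true: 3700.0, pKa_at_25C: 6.43}
box:
  n_water: 200
  n_cosolvent: 20
  cosolvent: GLY
  enrichment: 5.0
  n_frames: 20
analysis:
  lamp_ratio: 1.3
  r_cut_nm: 0.8
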