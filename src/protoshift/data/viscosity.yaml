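# Coefficients of the binary-mixture viscosity correlations.
#
# glycerol-water: Cheng, N.-S. (2008) "Formula for the viscosity of a
# glycerol-water mixture", Ind. Eng. Chem. Res. 47, 3285-3288.  Exponential
# mixing rule eta = eta_w^alpha * eta_g^(1-alpha) with
#   alpha = 1 - Cm + a*b*Cm*(1-Cm) / (a*Cm + b*(1-Cm)),
#   a = 0.705 - 0.0017 t,  b = (4.9 + 0.036 t) a^2.5   (t in degC, Cm mass fraction),
#   eta_w = 1.790 exp((-1230 - t) t / (36100 + 360 t))  cP,
#   eta_g = 12100 exp((-1233 + t) t / (9900 + 70 t))    cP.
#
# sucrose-water: Genotelle, J. (1978) mole-fraction correlation for aqueous
# sucrose (Ind. Alim. Agric. 95, 747-755), decimal-log form
#   log10 eta = 22.46 N - 0.114 + phi (1.1 + 43.1 N^1.25),
#   N = mole fraction of sucrose, phi = (30 - t)/(91 + t),
# applied here as a relative viscosity eta(w,t)/eta(0,t) anchored to the same
# water curve eta_w(t) used for glycerol, so the w=0 limit is shared.
glycerol:
  water_curve: {A: 1.790, B: -1230.0, C: 36100.0, D: 360.0}
  glycerol_curve: {A: 12100.0, B: -1233.0, C: 9900.0, D: 70.0}
  a: {c0: 0.705, c1: -0.0017}
  b: {c0: 4.9, c1: 0.036, exponent: 2.5}
  w_max_percent: 60.0
sucrose:
  molar_mass_sucrose: 342.2965   # g mol^-1
  molar_mass_water: 18.01528     # g mol^-1
  coeffs: {c_N: 22.46, c_0: -0.114, c_phi0: 1.1, c_phi1: 43.1, n_exp: 1.25}
  phi: {t0: 30.0, t1: 91.0}
  w_max_percent: 60.0
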