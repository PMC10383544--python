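# protoshift

Analysis pipeline for a ratiometric fluorescent pH probe (fluorescein) in
viscous aqueous media: how temperature and cosolvents (glycerol, sucrose)
perturb the monoanion–dianion protolytic equilibrium that the probe's
signal reports, and how the probe's solvation shell reorganizes around it.

## The science

Fluorescein near neutral pH is a mixture of its monoanion (M) and dianion
(D), interconverting with pKa ≈ 6.4. The two forms absorb differently
(M around 454/475 nm, D around 490 nm) and differ ~2.5× in fluorescence
quantum yield, so the ratio of integrated emission intensities under
dianion-selective (488 nm) and monoanion-selective (435 nm) excitation,

    R = I⁴⁸⁸ / I⁴³⁵,

is a concentration- and instrument-robust readout of the equilibrium.
The package implements the full chain of analyses used to characterize
such a probe:

* **Spectral decomposition** — a mixture absorption spectrum is fit as
  A(λ) = l·(c_M ε_M(λ) + c_D ε_D(λ)) by non-negative least squares,
  with the pH-5 monoanion reference corrected for its residual 3% dianion
  and 4% zwitterion content. The apparent constant follows by mass action,
  Ka_app = [D]·10⁻ᵖᴴ/[M].
* **van't Hoff analysis** — OLS of −ln Ka_app against 1/T gives the molar
  dissociation enthalpy ΔH = slope × R; the implied linear pKa(T)
  sensitivity over 10–80 °C follows from the exact van't Hoff curve.
* **Ratiometric channel** — xenon-lamp intensity correction, mean-path
  inner-filter (reabsorption) correction, trapezoidal band integration,
  and the OLS sensitivity of R to temperature or viscosity.
* **Excited-state shift** — the Förster–Weller cycle
  ΔpKa\* = hc(ν̃₀₀ᴰ − ν̃₀₀ᴹ)/(ln10·kT) from 0-0 origins estimated as
  half-sums of absorption- and emission-maximum wavenumbers.
* **Medium descriptors** — Lippert–Mataga polarity factor
  Δf = (ε−1)/(2ε+1) − (n²−1)/(2n²+1) and binary-mixture viscosity
  correlations for glycerol–water and sucrose–water.
* **Solvation statistics** — from coordinate frames: geometric hydrogen
  bonds to the probe's ring oxygens O1/O2/O3 (acceptor–donor ≤ 0.35 nm,
  angle at the donor ≤ 30°), per-acceptor occupancies by donor species,
  minimum-distance distribution functions (MDDF), and
  preferential-interaction coefficients
  Γ = n_cosolvent(r) − (N_c/N_w)·n_water(r).

Because the analyses need inputs with known truth, the package ships a
first-class synthetic-data module: two-species Gaussian band systems whose
fractions follow mass action with a van't Hoff Ka(T), bathochromic band
shifts with temperature and polarity, multiplicative photometric noise,
and periodic solvent boxes with controllable cosolvent enrichment around a
rigid labelled solute.

## Worked example

```sh
python analysis/01_simulate_spectra.py --seed 1   # synthesize spectra
python analysis/02_decompose_equilibrium.py       # c_M, c_D, Ka(T)
python analysis/03_thermodynamics.py              # van't Hoff, pKa shifts
python analysis/04_ratiometric_sensitivity.py     # R(T) slopes
python analysis/05_solvation.py --seed 1          # H-bonds, MDDF, Γ
```

which prints, among other lines:

```
buffer: dH = 7.39 kJ/mol (r^2 0.9999), pKa shift -0.00384 /degC (from dH alone: -0.00384), pKa(25) = 6.450, eta = 0.89 cP
glycerol40: dH = 3.68 kJ/mol (r^2 0.9999), pKa shift -0.00191 /degC (from dH alone: -0.00192), pKa(25) = 6.430, eta = 3.14 cP
glycerol_enriched: Gamma(GLY) = +7.36 (size-corrected +6.70), Gamma(WAT) = -73.63
```

Reading: the 0.5%-noise spectra simulated with ΔH = 7.4 (buffer) and
3.7 kJ/mol (40% glycerol) are decomposed and refit to within 1% of those
enthalpies; the pKa-vs-T slope measured from the decomposed series agrees
with the slope implied by the fitted enthalpy alone; and in the enriched
box the cosolvent shows positive preferential interaction while water is
expelled from the solute surface (negative Γ).

The same steps run from one config through the CLI:

```sh
protoshift run --config examples/run.yaml --out runs/demo
protoshift deltaf --n 1.3325 --eps 78.36
protoshift viscosity --cosolvent glycerol --w 50 --temp-c 25
```

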