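# Methods

This note records the models, estimators, numerical choices and known
limitations of the package, in the spirit of a methods appendix.

## Protolytic equilibrium model

The probe is treated as a strict two-state system at the working pH:
monoanion M and dianion D with

    Ka_app = [D][H⁺]/[M],   [H⁺] = 10^-pH  (no activity corrections),

so the dianion fraction is the Henderson–Hasselbalch form
f_D = 1/(1 + 10^(pKa−pH)). Temperature enters through the exact van't Hoff
line

    pKa(T) = pKa(298.15 K) + (ΔH / (ln10·R)) (1/T − 1/298.15 K),

with R = 8.314462618 J mol⁻¹ K⁻¹ and ΔH assumed
temperature-independent. The zwitterion Z appears only as a contaminant of
the pH-5 monoanion reference (default fractions f_D = 0.03, f_Z = 0.04);
it is never part of the two-component mixture fit.

Ionic-strength/activity corrections to Ka are deliberately out of scope;
all constants are apparent.

## Synthetic spectra

Species extinction curves are sums of Gaussian bands in wavenumber,
ε(ν) = Σ p_i exp(−(ν−c_i)²/2σ_i²), with defaults (see
`src/protoshift/data/defaults.yaml`) placing the dianion main band at
490 nm (ε_max 88 000 M⁻¹cm⁻¹, vibronic shoulder at 21 900 cm⁻¹), the
monoanion doublet at 475/454 nm and a weak zwitterion band at 437 nm.
Gaussians were chosen for smoothness and analytic maxima, not spectro-
scopic fidelity; no attempt is made to reproduce true vibronic structure.

All band centers shift rigidly by

    δν = (dν/dT)(T − 298.15 K) + (dν/dΔf)(Δf − Δf_water),

with defaults dν/dT = −1.2 cm⁻¹ K⁻¹ (bathochromic on heating, a few nm
over the 10–80 °C range) and dν/dΔf = +6323 cm⁻¹ per unit Δf, the latter
calibrated once so the 50% w/w glycerol medium (Δf = 0.2939 from the
shipped (n, ε) table) moves the mixture absorption maximum 4 nm to the
red relative to buffer at 25 °C.

Absorbance obeys Beer–Lambert with path 1 cm and total dye 8 μM. Emission
spectra are single Gaussian shapes per species (D at 512 nm, M at 520 nm)
with intensity ∝ ε_s(λ_ex)·c_s·Φ_s and Φ_D/Φ_M = 2.5; a lamp-intensity
asymmetry multiplies the raw 435-excited channel by 1/lamp_ratio, which
`ratiometric.lamp_correct` undoes. Measurement noise is multiplicative
Gaussian per spectral point (default relative s.d. 0.5%, matching
photometric relative error); every generator draws from
`numpy.random.default_rng(seed)` and is bit-reproducible.

Grid defaults (absorption 400–560 nm, emission 480–700 nm, step 0.5 nm)
are package decisions; a real instrument's sampling is not modelled.

## Decomposition and equilibrium estimation

The mixture fit minimizes Σ_λ [A(λ) − l(c_M ε_M + c_D ε_D)]² subject to
c_M, c_D ≥ 0 over the default 400–540 nm window (covering both ionic
bands). Because the model is linear in the concentrations, the bounded
problem is solved exactly with active-set NNLS rather than an iterative
descent; coefficients below 10⁻¹² of the dominant one are snapped to the
constraint since they are round-off, not concentration. References are
linearly interpolated onto the mixture grid (sub-grid structure is not
modelled), R² is reported over the fitted range only, and the covariance
of (c_M, c_D) is the Gauss–Markov estimate σ²(XᵀX)⁻¹. No baseline offset
is floated.

A pH-titration series is aggregated to one pKa by the median across
spectra, which is robust to edge-of-titration points where one species is
nearly absent. `compute_Ka` refuses c_M = 0 or c_D = 0: the constant is
undefined on the boundary.

Band maxima are located by the exact parabola through the top three
samples (error far below the 0.5 nm grid step for bands hundreds of
cm⁻¹ wide); a maximum on the grid boundary is an error. 0-0 origins are
half-sums of the absorption- and emission-maximum wavenumbers.

## Thermodynamic and photophysical estimators

* van't Hoff: unweighted OLS of −ln Ka on 1/T (no per-point error
  propagation); ΔH = slope·R, with the OLS slope standard error scaled
  the same way.
* pKa temperature sensitivity: the exact van't Hoff curve is sampled at
  n evenly spaced temperatures (default 15 over 10–80 °C) and fit by OLS
  against t/°C. The 1/T curvature makes this slightly shallower than the
  25 °C point derivative — e.g. ΔH = 7.4 kJ/mol gives −0.00385 °C⁻¹
  versus a point derivative of −0.00390 °C⁻¹ at 25 °C.
* Förster–Weller: ΔpKa* = hc(ν̃₀₀ᴰ−ν̃₀₀ᴹ)/(ln10·kT) with CODATA
  h = 6.62607015×10⁻³⁴ J s, c = 2.99792458×10¹⁰ cm s⁻¹,
  k = 1.380649×10⁻²³ J K⁻¹. The conventional printed factor "2.3" is
  implemented as ln 10 = 2.302585…, of which it is a rounding.
* Lippert–Mataga: Δf = (ε−1)/(2ε+1) − (n²−1)/(2n²+1). The shipped (n, ε)
  table for water/glycerol/sucrose mixtures at 25 °C holds representative
  literature values interpolated linearly in mass fraction; users with
  measured values for their buffers should supply them. The ~0.02–0.03
  decrease of Δf on cosolvent addition drives the generator's polarity
  shift.
* Viscosity: glycerol–water via Cheng's (2008) exponential mixing rule
  between water and glycerol endmember curves; sucrose–water via
  Génotelle's (1978) mole-fraction correlation in its decimal-log form,
  applied as a relative viscosity anchored to the same water curve so
  both cosolvents share the w = 0 limit (1.005 cP at 20 °C). Validity is
  restricted to w ≤ 60% w/w and 0–100 °C. These are binary-mixture
  correlations: a heavily salted buffer (e.g. 1 M phosphate) is more
  viscous than the binary value, so such numbers are sanity references,
  not predictions.

## Synthetic solvent boxes

A rigid 10-atom planar fragment with labelled oxygens O1 (hydroxyl-like),
O2 (ring heteroatom) and O3 (carbonyl-like) sits at the centre of a cubic
periodic box. Water (3 atoms, 104.5° H-O-H), glycerol (C + 3 OH) and
sucrose (2 C + 5 OH) stand-ins carry an explicit hydrogen on every
hydroxyl; donor pairing follows the naming convention "O* immediately
followed by H*". Molecule centres are drawn uniformly, subject to a
0.15 nm minimum-centre-distance rejection-sampling constraint (bounded
retries, error on packing failure); each molecule gets an independent
random rigid rotation, and atoms are wrapped into the box.

Cosolvent enrichment e re-weights placement into a sphere of radius
`shell_radius` around the solute: the in-shell probability is
e·p₀/(e·p₀ + (1−p₀)) with p₀ the sphere's volume fraction, so e = 1
reproduces uniform placement exactly, e = 0 excludes the shell, and large
e concentrates cosolvent near the solute. Optionally a known fraction of
frames gets one water per acceptor repositioned into ideal H-bond
geometry (0.30 nm, 0°), for occupancy ground truth.

What the boxes do *not* emulate: any energetics or correlation structure
(no excluded volume beyond the centre constraint, no orientational
preference, no realistic molecular geometry). Passing tests therefore
validate the *estimators* — counting, normalization, periodic imaging —
not force-field physics, and the absolute magnitudes of occupancies and
Γ carry no meaning for the real dye.

## Solvation estimators

Hydrogen bonds use the geometric criteria acceptor–donor distance
≤ 0.35 nm and acceptor–donor–hydrogen angle ≤ 30°, both
boundary-inclusive, evaluated under the orthorhombic minimum image. The
triplet angle is measured **at the donor heavy atom** between the
donor→hydrogen and donor→acceptor directions — conventions differ across
tools, so this is stated prominently. All hydroxyl hydrogens of water and
cosolvent act as donors.

MDDF: for each solvent molecule the minimum over all
(solvent atom, solute atom) distances (hydrogens included) is
histogrammed (default bin 0.02 nm up to half the smallest box edge). Each
bin is normalized by the mean count from N_ref = 10 uniform random
re-placements (position and orientation) of the same molecules in the
same box — an ideal reference chosen because minimum-distance shells
around an arbitrary solute have no closed-form volume. Molecules split by
the periodic boundary are unwrapped about their first atom before
re-placement.

Preferential interaction: Γ_s(r) = n_s(r) − (N_s/N_ref)·n_ref(r) from the
mean cumulative counts, by default the cosolvent against water at
r_cut = 0.8 nm, with a warning when Γ(r) has not plateaued (>10% change
over the preceding 0.1 nm). One subtlety is documented and exposed
explicitly: because the estimator counts by minimum distance, a species
with larger molecular extent reaches any cutoff from farther-out centres,
so even a compositionally uniform box yields Γ_cosolvent > 0 by roughly
ρ_c·(V_c(r)−V_w(r)). The correct zero point for "no preferential
interaction" with finite-size molecules is therefore the same formula
evaluated on the ideal re-placement counts, available as
`PreferentialInteraction.gamma_ideal_baseline` (and the corrected value
as `.gamma_excess`); the null-box tests use it, while the raw Γ retains
the conventional definition.

## Pipeline

`protoshift.pipeline.run` executes the staged analysis from a single YAML
config with all defaults materialized into the resolved config written to
the run directory (unknown keys are rejected with a spelling suggestion).
Per-medium it reports the standard characterization columns — ratiometric
temperature sensitivity, pKa_app at 25 °C, pKa temperature shift, ΔH and
ΔpKa* — each traceable to a stage CSV. Reports contain no timestamps, so
a fixed config + seed reproduces byte-identical output; an occupied
output directory is never overwritten (a suffixed sibling is created).

## Problem sizes

The shipped analyses and tests run at desk scale by design: spectra on a
0.5 nm grid, 8–15 temperatures, 25–50 noise replicates for recovery
statistics, and solvent boxes of up to 500 molecules × 200 frames for the
null-calibration checks. These sizes were chosen so the recovery
tolerances quoted in the tests (pKa within ±0.02, ΔH within 2%) are
comfortably resolved by the sampling noise they entail.

## Known limitations

* Two-species spectral model only; no baseline/scatter fitting, no
  excited-state spectral decomposition, no quantum-yield modelling.
* The reabsorption correction is the mean-path inner-filter
  approximation with fixed half-paths; detector spectral sensitivity
  defaults to unity.
* Binary-mixture viscosities ignore dissolved electrolytes.
* The solvation stand-ins carry no physics (above); GRO input is
  single-frame, and only orthorhombic boxes are supported.
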