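# Methods

This note documents the models implemented in `covnuc`, their assumptions,
the defaults that matter, and what the synthetic-data tests do and do not
demonstrate.

## Equilibrium competition (tight-binding affinity estimation)

**Model.** Two ligands (GDP and a nucleotide analogue) compete reversibly
for one protein site. The percentage-based estimator assumes the
tight-binding regime: both K_D values (picomolar) are many orders of
magnitude below the reactant concentrations (tens of micromolar), so the
protein is fully nucleotide-bound and the total protein concentration equals
the GDP pool it carried in (`protein_total ≡ gdp_total`). Under those
assumptions the derivation chain is pure arithmetic:

1. `GDP_total = (%GDP / %analogue)_t0 × analogue_total` — the t = 0 bound-pool
   composition encodes the GDP carried over relative to the added analogue.
2. Bound species at equilibrium are the equilibrium percentages of
   `GDP_total`; free species follow by conservation.
3. `K_relA = (bound_analogue × free_GDP) / (free_analogue × bound_GDP)`.
4. `K_A = K_relA / K_D(GDP)`, `K_D = 1 / K_A`, with the reference
   K_D(GDP) = 2.5 pM.

**Precision convention.** The implementation computes at full precision. The
conventional printed values round K_relA to two decimals before the
conversion (0.34 → 7.4 pM; 0.28 → 8.9 pM); the full-precision chain gives
7.39 and 9.02 pM. Tests compare to printed values at printed precision and
`covnuc.io.printed` renders the 2–3-significant-figure convention alongside
full-precision JSON numbers.

**Exact solver.** `solve_competitive_equilibrium` reduces the n-ligand
mass-action system to one monotone scalar equation in the free-protein
concentration, `p + Σ Ltot_i·p/(Kd_i+p) = Ptot`, bracketed on (0, Ptot] and
solved with Brent's method at machine tolerance. Internally concentrations
are µM and K_D values are converted from pM at the boundary (explicit ×1e−6,
never inferred). The solver serves three roles: validation oracle for the
simplified estimator (round-trip agreement within 2% across the tight-binding
regime, K_D ≤ 1 nM and totals ≥ 10 µM), the opt-in `mode="exact"` estimator
(numerical inversion for the analogue K_D reproducing the observed bound
ratio), and the occupancy term of the labelling model.

**Percent-sum tolerance.** Assay percentage pairs must sum to 100 within 0.1;
inputs may be given as 0–1 fractions via `CompetitionAssay.from_fractions`
or `percent_unit: fraction` in CSV reading, and are canonicalized to 0–100.
An analogue whose HPLC peak overlaps GDP is representable with
`quantifiable=False` and yields a flagged, not silently computed, estimate.

## Stopped-flow association kinetics

**Model.** Two parallel reversible bimolecular channels,

    d[Rm]/dt = kon_r·[R][m] − koff_r·[Rm]
    d[RN]/dt = kon_c·[R][N] − koff_c·[RN]

with [R], [m], [N] eliminated by conservation, so mass balance holds by
construction. This two-channel competitive scheme is the minimal model
consistent with the experimental description (the original analysis used a
proprietary fitting package whose internal scheme is cited to prior work).
The observation model is linear: `signal = baseline + amplitude·[Rm]`.

**Integration.** `solve_ivp` with LSODA at rtol 1e−8 / atol 1e−12 µM — the
contract for a system that is stiff in principle (picomolar dissociation
against micromolar-scale association). Against the closed-form irreversible
bimolecular solution the integrator agrees to better than 1e−6 relative.
A stopped-flow dead time is accepted as a config parameter (default 0; none
is stated for the instrument).

**Global fit.** Shared kinetic parameters are optimized in log10 space by
Levenberg–Marquardt; per-curve baseline/amplitude are profiled out by linear
least squares at every iteration (variable projection), which keeps the
nonlinear dimension at one or two parameters and makes replicate studies
cheap. The reporter rate kon_r is by default staged — fitted on the
competitor-free curve, then fixed across the global fit, mirroring the
experimental design; joint fitting is available by listing `kon_reporter` in
`fit_params`. Five log-spaced multi-starts (seeded jitter) guard against
local minima. Dissociation rates default to the K_D-derived values rather
than zero: at ~1e−5 s⁻¹ they are negligible on the seconds timescale but
retained for correctness. Standard errors come from the Jacobian of the
reduced problem, propagated from log space. Fitting kon_c with no
competitor-containing curve returns a flagged, non-converged result rather
than a number.

**Unit conversion.** `koff_from_kd(kd_pM, kon_µM⁻¹s⁻¹)` returns
kd × 1e−6 × kon in s⁻¹.

## Covalent labelling

**Model.** The observed pseudo-first-order modification rate factorizes as

    k_obs = k_chem × f_thiolate(pH) × occupancy

* `f_thiolate = 1/(1+10^(pKa−pH))`, Henderson–Hasselbalch with reference
  cysteine pKa 8.6. The experiments do not separate ionization from possible
  conformational pH effects; the model attributes the pH dependence entirely
  to ionization, and this assumption is recorded in
  `covnuc.labelling.MODEL_ASSUMPTION`.
* `occupancy` is the fraction of unmodified protein reversibly bound to the
  warhead nucleotide, from the exact competitive equilibrium with the
  GDP/GTP pools, treated as quasi-static (reversible binding re-equilibrates
  much faster than the hours-scale chemistry) and with warhead depletion
  neglected (accurate at ≥10× excess; a warning is emitted below 1× protein).
* `k_chem` is the intrinsic covalent rate at full ionization — a free
  scenario parameter per linker geometry (no rate law is available for the
  chemistry itself; orderings such as eda > pda > bda are scenario
  configurations, not claims of the package).

This factorization is the minimal model reproducing the qualitative
observations: labelling accelerates with pH, slows with competing
GDP/GTP, and saturates at complete modification. `fit_kobs` inverts
`1 − exp(−k_obs·t)` by least squares and flags unidentifiable inputs
(< 3 points, or no fraction above 0.2).

Downstream hydrolysis of a covalently attached triphosphate and off-target
labelling of a second protein species are representable but off by default.

## GTP hydrolysis

Single-exponential decay `f(t) = f0·exp(−kt)` fitted by least squares with a
log-linear initial guess; `t_1/2 = ln 2 / k`. The amplitude f0 is fitted, not
fixed at 1, because t = 0 samples can show partial conversion. No
bi-exponential option: ten sampling points (0–120 min grid) cannot identify
one. Non-decaying input (second-half mean ≥ first-half mean) is flagged
rather than fitted.

## Synthetic data

Generators emulate the four data shapes at the corresponding experimental
conditions, which are the defaults: 50 µM protein:GDP + 50 µM analogue
competition mixes; 1 µM protein + 2 µM reporter + {0, 1, 2, 6} µM competitor
stopped-flow series (3 s, 151 points); labelling sampled at 1–24 h with
5 µM protein and 36 µM warhead; hydrolysis on the 0–120 min 10-point grid.
Noise defaults — 2% multiplicative signal noise, 0.02 absolute fraction
noise, 1 percentage-point jitter — are plausible instrument-level choices
declared arbitrary: no measured noise magnitudes are available. Fraction
noise is drawn truncated to [0, 1] by resampling, with the number of redrawn
samples recorded (`SyntheticSpec.truncation_counts`) so the truncation bias
near 0/1 is visible rather than silent. All generators are deterministic
under (seed, stream).

**What passing tests show.** Estimator correctness under the stated
mass-action models and noise assumptions — not robustness to instrument
artifacts absent from the generators: photophysics/inner-filter effects,
mixing dead time, baseline drift, HPLC integration bias, or isomer mixtures
(2′/3′ attachment) with distinct affinities.

## Numerical and design choices

* Equilibrium root solve: Brent, bracket (0, Ptot], rtol 4·eps; residual
  guard at 1e−9 µM.
* ODE: LSODA, rtol 1e−8, atol 1e−12 µM; trajectories are solved from t = 0
  even when the first requested sample is later.
* Global fit: log10 parameterization (positivity without constraints),
  variable projection for signal parameters, LM with xtol/ftol 1e−12.
* Exponential fits: `scipy.optimize.curve_fit` with data-derived starts.
* Replicate study sizes (50 stopped-flow fits, 100 hydrolysis fits in the
  test suite) keep full-suite runtime under a minute while giving stable
  medians.
* The CLI is a thin layer over the library; reports are versioned JSON with
  full-precision numbers plus a "printed" rendering, and identical
  config + seed produces identical report bytes.

## Known limitations

* The t = 0 assay compositions are taken exactly as recorded; whether the
  HPLC readout at t = 0 reflects the free or total pool is not documented,
  and the estimator adopts the total-pool convention consistent with the
  published arithmetic.
* Replicate-averaged affinities (e.g. 8.6 ± 1.3 pM) cannot be reproduced from
  a single percentage table; the package reproduces the single-assay worked
  chain and treats the averaged values as replicate means supplied externally.
* The labelling model's pH term conflates ionization with any conformational
  contribution; k_chem absorbs all structure-dependent reactivity.
* No chromatogram, mass-spectral, or photophysical modeling: inputs are
  already percentages, fractions, or fluorescence series.
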