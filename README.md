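# covnuc

Quantitative analysis for **covalent, nucleotide-competitive inhibitors of
small GTPases** — nucleotide analogues that bind the active site reversibly
with picomolar affinity and then react irreversibly (Michael addition) with
an engineered or oncogenic P-loop cysteine such as KRasG13C.

The package is aimed at biochemists characterizing such inhibitors from
standard bench readouts: HPLC peak integrals, stopped-flow fluorescence
traces, and ESI-MS modification fractions. It covers four workflows:

1. **Equilibrium competition affinity** (`covnuc.equilibrium`). A GTPase
   saturated with GDP is mixed with an equimolar nucleotide analogue; after
   re-equilibration the bound pool is quantified as %GDP / %analogue. In the
   tight-binding regime (K_D ≪ reactant concentrations) the relative
   association constant is

       K_relA = K_A(analogue) / K_A(GDP) = ([P:A][GDP]) / ([A][P:GDP])

   and the absolute affinity follows from the reference K_D(GDP) = 2.5 pM via
   K_A = K_relA / K_D(GDP), K_D = 1/K_A. An exact n-ligand mass-action solver
   (`exact_competition_oracle`, `solve_competitive_equilibrium`) validates
   the simplified arithmetic and powers an opt-in "exact" estimation mode.

2. **Stopped-flow association kinetics** (`covnuc.kinetics`). Nucleotide-free
   GTPase + fluorescent reporter (mantdGDP) ± competitor, modeled as two
   reversible bimolecular channels R+m ⇌ Rm, R+N ⇌ RN and fitted globally
   across a competitor series (0/1/2/6 µM) for the competitor's k_on, with
   per-curve signal parameters profiled out linearly. k_off on the
   much slower dissociation timescale is derived as k_off = K_D · k_on.

3. **Covalent labelling kinetics** (`covnuc.labelling`). Pseudo-first-order
   modification with k_obs = k_chem · f_thiolate(pH) · occupancy, where
   f_thiolate = 1/(1+10^(pKa−pH)) (reference cysteine pKa 8.6) and the
   warhead occupancy comes from the exact competitive equilibrium with
   GDP/GTP pools.

4. **GTP hydrolysis** (`covnuc.hydrolysis`). Single-exponential fit
   f(t) = f0·e^(−kt) of triphosphate-fraction time courses; t_1/2 = ln 2 / k.

`covnuc.synthetic` generates seeded synthetic datasets for all four data
shapes at the corresponding experimental conditions, and `covnuc.presets`
transcribes the published input tables so the full chain runs without raw
instrument files.

## Worked example

```pycon
>>> from covnuc import estimate_affinity
>>> from covnuc.presets import PAPER_COMPETITION_ASSAYS
>>> for assay in PAPER_COMPETITION_ASSAYS[:2]:
...     est = estimate_affinity(assay)
...     print(assay.analogue_id, round(est.k_rel_a, 2), round(est.k_d, 1))
pdaGDP 0.34 7.4
bdaGDP 0.28 9.0
```

`K_relA = 0.34` means the propylenediamine-linked GDP analogue binds with
34% of GDP's association constant; with K_D(GDP) = 2.5 pM that corresponds
to a ~7.4 pM dissociation constant — the linker barely perturbs affinity.
(The full-precision chain gives 9.0 pM for the butylenediamine analogue;
carrying the 2-decimal K_relA through instead yields the conventional 8.9.)

The same chain is available on the command line:

```sh
covnuc equilibrium-kd                         # published table, JSON out
covnuc simulate --scenario stopped-flow --seed 1 --out data/
covnuc fit-hydrolysis --input hydrolysis.csv
covnuc report --out report.json               # Table-style kinetic summary
```

`covnuc report` prints a summary with columns K_D [pM], k_on [µM⁻¹s⁻¹],
k_off [s⁻¹], combining the equilibrium estimates with the measured
association rates (e.g. GDP: 2.5 pM, 4.22 µM⁻¹s⁻¹, 1.1×10⁻⁵ s⁻¹).

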