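# Methods

## Model

`phytoalloc` implements a steady-state, coarse-grained allocation model of
a phytoplankton cell growing on nitrate, alongside Monod kinetics as the
phenomenological reference. All quantities are intensive: quotas are mol C
(or mol N) per mol cell C, so the total C quota is 1 by definition and the
total N quota equals the cellular N:C ratio. Rates are day⁻¹,
concentrations µM, irradiance µmol photons m⁻² s⁻¹.

Three constitutive relations tie the growth machinery to the growth rate
mu:

1. **Photosynthesis and chlorophyll.** Per-chlorophyll C fixation
   saturates with irradiance, `P(I) = P_max_chl (1 − e^(−O_I I))`. At
   balanced growth, gross fixation must cover net growth, a biosynthetic
   excretion/cost overhead `E`, and maintenance `m`, so the chlorophyll
   quota is `QC_chl = (mu(1+E) + m) / P(I)` — affine and increasing in mu.
2. **Protein.** Photosynthetic protein maintains a fixed machinery
   composition, `A_pho · QC_chl`; biosynthetic protein scales with the
   synthesis flux, `k_bio · mu`; an essential floor `Q_pro_ess_C` is
   growth-independent.
3. **RNA.** `QC_rna = Q_rna_min_C + A_rna · mu · QC_pro`, the linear
   RNA–protein–growth coupling observed across microbes.

DNA and "other" C are constant; thylakoid lipid tracks chlorophyll
(`A_plip · QC_chl`); storage pools close the budgets (below). The
carbohydrate fraction is folded into the "other C" constant rather than
resolved as its own pool.

### The two limiting regimes

**C limitation.** Setting C storage to zero and summing all pools to 1
gives, after substituting the relations above, a quadratic
`a_C mu² + b_C mu + c_C = 0`. The mu² term exists only through the
RNA coupling (`a_C = A_rna · dQC_pro/dmu`); `c_C` is the mu = 0 pool sum
minus 1, negative for any feasible cell. Among real roots, those whose
reconstructed state has every pool in [0, 1] are retained and the largest
is taken (growth uses the full C budget); for feasible parameters there is
exactly one positive root. Its value `mu_C` is independent of nitrate.

**N limitation.** Nitrogen enters by diffusion-limited uptake
`V_N = A_N [NO3⁻]` and is diluted by growth at `mu · Q_N(mu)`, where
`Q_N` sums the N in protein, RNA, DNA and chlorophyll via fixed
stoichiometric ratios `Y_*_NC` (N storage is empty when N limits). `Q_N`
is quadratic in mu, so the steady-state balance is a cubic
`a_N mu³ + b_N mu² + c_N mu + d_N = 0` with `d_N = −A_N [NO3⁻]`. Because
all mu-side coefficients are positive, `mu · Q_N(mu)` is strictly
increasing and the physical root — the branch continuous from mu = 0 at
zero nitrate — is the unique non-negative real root.

**Realized growth** is `min(mu_C, mu_N)`. Under N limitation the C-budget
residual accumulates as C storage and the N-storage pools are empty; past
the crossover C storage is zero, N storage sits at its replete constant
`Q_nsto_C`, and growth is exactly flat in nitrate. The crossover
concentration follows in closed form from the balance at `mu_C`:
`no3* = mu_C · Q_N(mu_C) / A_N`.

## Parameter defaults

Defaults describe a generic light-replete eukaryote-like cell and were
chosen once for physiological realism; every property test is written to
hold for any feasible parameter set, so nothing in the test suite depends
on these exact numbers.

| parameter | default | units | rationale |
|---|---|---|---|
| `P_max_chl` | 7.0 | day⁻¹ | order of measured per-chl-C fixation at saturation |
| `O_I` | 0.01 | (µmol photons m⁻² s⁻¹)⁻¹ | ~70% light saturation near 120 µmol m⁻² s⁻¹ |
| `I` | 200 | µmol photons m⁻² s⁻¹ | typical culture irradiance; set per experiment |
| `E` | 0.2 | – | ~20% biosynthetic overhead/excretion |
| `m` | 0.05 | day⁻¹ | small maintenance respiration |
| `A_pho` | 3.56 | – | photosynthetic protein : chl C mass ratio (fitted) |
| `A_plip` | 0.12 | – | thylakoid lipid C per chl C |
| `k_bio` | 0.25 | day | biosynthetic protein per unit growth |
| `r_bio_pho` | 14.24 | – | frozen A_pho/k_bio ratio used during fitting |
| `Q_pro_ess_C` | 0.12 | mol C/mol C | essential protein floor |
| `A_rna` | 0.2 | day | RNA–protein–growth slope |
| `Q_rna_min_C` | 0.005 | mol C/mol C | RNA floor |
| `Q_dna_C` | 0.005 | mol C/mol C | genome is a small C fraction |
| `Q_oth_C` | 0.08 | mol C/mol C | structural carbohydrate/lipid remainder |
| `Q_nsto_C` | 0.0 | mol C/mol C | replete N-storage C; zero keeps the plateau flat |
| `Y_pro_NC` | 1/4.49 | mol N/mol C | protein C:N of 4.49 |
| `Y_rna_NC` | 0.395 | mol N/mol C | average ribonucleotide N₃.₇₅C₉.₅ |
| `Y_dna_NC` | 0.385 | mol N/mol C | average deoxyribonucleotide |
| `Y_chl_NC` | 4/55 | mol N/mol C | chlorophyll a C₅₅N₄ |
| `Y_nsto_NC` | 0.45 | mol N/mol C | amide-like N storage |
| `A_N` | 0.02 | mol N (mol C)⁻¹ d⁻¹ µM⁻¹ | puts the crossover near 5–6 µM (fitted) |

These give `mu_C ≈ 0.57 day⁻¹` and a crossover near 5.7 µM — within the
range spanned by published nitrate-limited growth experiments.
Maintenance respiration is treated as added C demand in the chlorophyll
sizing (rather than subtracted from fixation); the two placements are
algebraically equivalent up to the sign convention in the budget
coefficients.

## Inference

The likelihood is iid Gaussian on growth rates with fixed error scale
`sigma` (default 0.05 day⁻¹; the generator's noise and the likelihood
share this model). Parameters are sampled on the log scale — which
enforces positivity — under flat priors within broad bounds (10⁻⁶–10⁶).
The sampler is random-walk Metropolis–Hastings with independent Gaussian
steps per coordinate; a pre-run adaptive phase (blocks of 100 iterations,
scale multiplied by `exp(acceptance − 0.3)`) tunes the step sizes and is
discarded, after which the main chain runs with fixed scales (default
6000 iterations, first 20% treated as burn-in for posterior summaries).
The point estimate is the chain state with the highest recorded
log-posterior; posterior means and central 95% intervals come from the
post-burn-in samples. The allocation-model fit has exactly two free
parameters, `A_pho` and `A_N`, with `k_bio = A_pho / r_bio_pho` held at
the default ratio; each dataset's experimental irradiance is imposed on
the model before fitting. Initial guesses are order-invariant functions
of the data (max growth for `mu_max`, median nitrate for `Ks`, the median
low-nitrate uptake balance for `A_N`), so permuting data rows leaves a
seeded fit unchanged.

## Synthetic data

The generator emulates compiled growth-versus-nitrate experiments: 6–12
concentrations spanning zero to ~4× the saturation scale (4·Ks for Monod,
4× the crossover for the allocation model), mean curves from the
respective model, additive homoscedastic Gaussian noise truncated at zero,
all seeded. It does not emulate features of real literature data:
heteroscedastic or multiplicative error, nitrate depletion during
incubations, acclimation transients, inter-study methodological offsets,
or digitization error. Passing recovery and coverage tests therefore
demonstrates the correctness and calibration of the pipeline under its
own statistical assumptions, not robustness to those real-world effects.

## Numerical choices

* Balance residual tolerance 1e-9; oracle-agreement tolerance 1e-8
  (bisection oracles re-solve both balances from the raw quota relations,
  independent of the closed-form budget coefficients).
* The quadratic is solved in closed form; the cubic via `numpy.roots`
  followed by three Newton polish steps so the steady-state residual
  reaches solver precision, with a bracketing bisection fallback if root
  ordering is ever ambiguous. Curve evaluation and fitting use a
  vectorized safeguarded-Newton solver started from the upper bound
  `A_N [NO3⁻]/q0` (the balance is increasing and convex, so convergence is
  monotone from above); it is asserted against the scalar route in tests.
* Monod growth is computed as `mu_max * (S/(Ks+S))` so the half-saturation
  identity `mu(Ks) = mu_max/2` is exact in floating point.
* Infeasible parameter sets (constant pools ≥ 1 at mu = 0, or any pool
  outside [0, 1] at a requested state) are rejected eagerly with the
  violated pool named. mu is clamped at 0; growth observations are
  truncated at 0 to match the generator.

## Scope and limitations

Steady state only — no dynamic simulation of the N quota equation.
Phosphorus, temperature, pH and iron dependencies are out of scope, as is
variable stoichiometry within macromolecules. Convergence diagnostics are
limited to acceptance rates and trace export (no R-hat); the
interval-coverage check in the acceptance suite is the calibration
evidence for the default chain settings. Problem sizes in the shipped
checks (100 random parameter sets for oracle agreement, 100 replicate
fits of 12-point datasets for coverage, 3000–6000-iteration chains) were
chosen so the whole suite runs comfortably on a laptop while keeping
Monte-Carlo error well below the asserted margins.
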