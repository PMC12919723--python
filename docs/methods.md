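# Methods

## Model and assumptions

`parsimech` infers microkinetic models — ordered sets of irreversible
elementary steps with mass-action rate laws — from concentration–time
data. The working assumptions are:

* **Net stoichiometry representation.** A mechanism is an integer matrix
  of *net* per-step coefficients. A step like `A + B -> 2B` is therefore
  indistinguishable from `A -> B`; rate laws derive only from the negative
  entries. This keeps the search space finite and matches the matrix
  formalism the translation phase expects.
* **Irreversible steps, isothermal, isochoric.** No reversible-step
  notation and no temperature dependence inside candidate models (the
  fructose benchmark evaluates its Arrhenius expression once, outside the
  candidate space).
* **Mass action.** Step *j* with reactant multiplicities `m_ij` has rate
  `r_j = k_j · Π_i C_i^{m_ij}`; the species balance is `dC/dt = νᵀ r`.
* **Homoscedastic Gaussian errors.** The estimation objective is the
  unweighted SSE over all experiments, sampling times and observed
  species; the AIC uses the concentrated Gaussian likelihood (below).

## Feasibility rules

A candidate matrix is feasible when all of the following hold:

1. every row has at least one negative and one positive entry, with at
   most `max_reactant_molecules` (default 2) total reactant molecules and
   `max_product_molecules` (default 2) product molecules, entries within
   `[entry_min, entry_max]` (default `[-2, 2]`) — i.e. the four
   elementary-reaction archetypes A→B, A+B→C, A→B+C, A+B→C+D, with the
   limits raiseable for higher-order chemistry;
2. every column sums to the species' overall coefficient (zero for
   intermediates);
3. **intermediate availability**: scanning rows top to bottom, the running
   sum of an intermediate column never goes negative — an intermediate
   cannot be consumed before, or in larger amount than, it has been
   produced. This is deliberately the cumulative-quantity form rather
   than a weaker "first sign seen" rule;
4. **intermediate usage**: a declared intermediate column is nonzero
   somewhere — adding a species the mechanism never touches is not a
   distinct mechanism;
5. **terminal products**: a species with positive overall coefficient is
   never consumed by any step. Overall reactants may, however, appear as
   products (nothing forbids partial regeneration).

Rules 3–5 were fixed by calibrating against exhaustive enumeration on
small instances where the expected candidate sets can be reasoned out by
hand (the 2-step `4A → B+C` skeleton admits exactly the two orderings of
`{2A→B, 2A→C}`; its 3-step/one-intermediate extension admits 31; the
3-step fructose skeleton admits 10). Duplicate identical rows are
permitted — two occurrences of the same step are a legitimate ordered
mechanism — and matrices differing only by row permutation are distinct
outputs (no canonicalization; observationally equivalent permutations tie
in the selection phase and are broken deterministically).

## Enumeration

Backtracking fills the matrix row by row from the lexicographically
ordered list of admissible rows. Pruning is sound (never discards a
feasible completion): a partial matrix is abandoned when some column's
remaining deficit exceeds `remaining_rows × max(|entry_min|, entry_max)`,
when a product column has overshot its target (products are terminal, so
sums in those columns are monotone), or when an intermediate's running sum
is already negative. The search tree is partitioned by first row across
workers (joblib); results are merged and sorted lexicographically, so the
output is identical for any worker count. A wall-clock `time_budget` is
checked between node expansions; on expiry the partial set is returned
with `complete=False` and a warning, not an exception.

## Simulation and estimation

* **Integrator.** LSODA (via `scipy.integrate.odeint`), stiff-capable,
  with `rtol=1e-6`, `atol=1e-8`, `mxstep=10000` by default, all
  overridable. Solver failure or a non-finite state yields a structured
  failure result; during fitting a failed simulation contributes a finite
  `failure_penalty` (default `1e10`) to the SSE so the optimizer can
  retreat from blow-up regions rather than crash.
* **Initial conditions.** Model species are matched to the experiment's
  initial-condition vector by name; species the experiment does not
  mention — in particular hypothesized intermediates — start at zero.
* **Optimizer.** L-BFGS-B with box bounds (default `[0, 10]`, chosen to
  bracket physically plausible rate constants for the bundled benchmarks)
  and finite-difference gradients, scipy default stopping criteria.
  `n_starts` (default 5) start points are drawn uniformly in the bounds
  box from a generator seeded by `FitConfig.seed`; the lowest final SSE
  wins. Start points are drawn as one block, so the first start of an
  `n_starts=1` run equals that of an `n_starts=5` run with the same seed
  and adding starts can only improve the result. Five starts are enough
  to escape the flat large-`k` plateau of decay-type objectives that traps
  single-start runs.
* **Scores.** `NLL = (N/2)·ln(SSE/N)` — the Gaussian log-likelihood
  concentrated over the MLE noise variance `σ̂² = SSE/N`, additive
  constants dropped; SSE is floored at `eps·N` before the log. AIC is
  exactly `2·NLL + 2·d` with `d` the number of steps. Because constants
  are dropped, AIC values are meaningful only as within-dataset
  differences, which is the only way the ladder uses them.

## The discovery ladder

Rung *i* uses `min_steps + i − 1` steps and `min_species + i − 1` species
(the extra species are intermediates). `min_steps`/`min_species` are user
inputs; a helper computes the smallest admissible start from the overall
molecule counts and the molecularity limits for users who omit them. All
candidates of a rung share `d`, so AIC ties are SSE ties; ties are broken
by the lexicographically smallest matrix, making the selection
deterministic. The ladder terminates when a rung's best AIC fails to
*strictly* improve the incumbent (equal counts as worsening — no
informational gain), at `max_iterations` (default 6), or at a global
wall-clock budget; the incumbent is returned in every case. The selection
metric is pluggable (`metric=` callable) for users preferring a different
criterion.

## Experiment design

The Hunter–Reiner objective is the unweighted squared Euclidean divergence
`Σ_t Σ_obs (X_ν − X_µ)²` between the two rival models' predicted
trajectories on the evaluation grid, maximized over a box of designable
initial conditions (observed species; intermediates fixed at zero) by
seeded multistart L-BFGS-B on the negated objective (default 10 starts).
A zero-volume box returns its single point; indistinguishable models
return zero divergence with a warning. The closed-loop "design → run →
merge → rediscover" workflow is deliberately left to the modeler as a
two-command sequence rather than automated.

## Synthetic benchmarks

The three bundled generators emulate in-silico kinetic studies: five
experiments per system at fixed initial-condition sets, 30 uniform
sampling times, additive zero-mean Gaussian noise on observed species
only, intermediates hidden.

* **hypothetical** (`4A → B + C`, [0, 10] h, noise sd 0.15 on A, B, C):
  ground truth `2A→D, A→E, D→B, A+E→C` with
  `k = (0.1 M⁻¹h⁻¹, 0.2 h⁻¹, 0.13 h⁻¹, 0.25 M⁻¹h⁻¹)`. The structure is a
  reconstruction: the printed constraints (overall stoichiometry, five
  species, four steps, the units of the four rate constants, and
  recoverability of all four constants at the stated noise) single out
  this two-channel arrangement; the serial-chain alternative
  `2A→D, D→E, E→B, 2A→C` was rejected because its middle constants sit on
  a `k₂↔k₃` identifiability ridge and cannot be recovered from the
  observed species at this noise level.
* **aldol** (`A + B → C + D`, [0, 10] h, sd 0.15 on A–D): enolization
  `A→E`, carbon–carbon coupling `E+B→F` (rate-determining), dehydration
  `F→C+D`, `k = (0.759 h⁻¹, 0.293 M⁻¹h⁻¹, 0.681 h⁻¹)`.
* **fructose** (`A → 3B + C`, [0, 90] min, sd 0.2 on A, B, C): the
  experimentally validated lumped rate law `r = k·C_A·C_acid` with
  constant `C_acid = 3.3×10⁻² M` and `k = k_ref = 0.9 M⁻¹min⁻¹` at
  `T = T_ref = 410.15 K` (the Arrhenius correction factor is exactly 1 at
  the reference temperature; `E_a = 124 J mol⁻¹` is carried for
  completeness). Implemented as the pseudo-first-order step `A → 3B + C`
  with `k_eff = k·C_acid`; fitted `k_eff` values are converted back to the
  second-order constant by dividing by `C_acid`.

Noise is drawn from one seeded generator per dataset, one block per
experiment in column-major (species-by-species) order, so fixtures are
bitwise stable across releases. Negative noisy concentrations are
retained, not clipped: clipping would bias the zero-mean error model the
SSE objective assumes.

What the generators do **not** emulate: heteroscedastic or multiplicative
measurement error, sampling jitter, missing data, side reactions and yield
losses, temperature drift, or real analytical calibration error. Passing
tests on these benchmarks therefore demonstrate correctness of the
machinery and recoverability under idealized noise, not robustness to the
full messiness of laboratory data.

## Problem sizes used in the test suite

The suite verifies enumeration exactly (counts 2/31/10 and set-equality
against exhaustive filtering on every instance with at most 5⁸
unconstrained matrices) and parameter recovery on all three benchmarks
(noiseless to 1% relative, noisy to 10%). The complexity-ladder checks run
the rungs that finish at desk scale — the aldol ladder through its second
rung (1 + 14 candidates), the fructose first rung (10 candidates) — and
verify the AIC-worsening termination end-to-end on a self-consistent
dataset generated from a one-step mechanism. The deeper case-study rungs
enumerate and fit thousands of candidates (e.g. 835 three-step aldol
candidates at rung 3, 2175 four-step fructose candidates at rung 2, each
candidate a full multistart ODE fit) and are run the same way, just
longer, by calling `run_discovery` with larger `max_iterations`.

## Known limitations

* Net representation cannot express autocatalytic steps (`A + B → 2B`).
* No canonicalization: row permutations and symmetric intermediate
  relabelings are enumerated and fitted separately, so candidate counts
  (and fitting time) grow faster than the number of observationally
  distinct models.
* Intermediates are structural placeholders; the method does not identify
  their chemical identity.
* Finite-difference gradients through an adaptive-step integrator can be
  noisy near solver-tolerance scales; the multistart scheme mitigates but
  does not eliminate convergence to local minima.
* No uncertainty quantification on the estimated rate constants or on
  model selection; AIC differences near zero should be read as "the data
  cannot distinguish these candidates".
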