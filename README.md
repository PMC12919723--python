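# parsimech

Automated discovery of the most parsimonious mass-action reaction mechanism
consistent with concentration–time data.

Chemists and reaction engineers routinely need a microkinetic model — the
set of elementary steps and rate constants behind an overall reaction —
but building one by hand means guessing intermediates and testing rate
laws one at a time. `parsimech` automates the search from a data-first
perspective: given only the overall stoichiometry (e.g. `4A -> B + C`) and
one or more concentration–time experiments, it finds the simplest set of
elementary steps that the data support.

## The method

The pipeline has four phases, iterated on a complexity ladder:

1. **Mechanism generation.** Candidate mechanisms are ordered integer
   matrices `ν` (rows = elementary steps, columns = species; negative
   entries consume, positive produce). A backtracking search with pruning
   emits every matrix satisfying the feasibility rules: each step has at
   least one reactant and one product and at most two molecules of each
   (raiseable limits), each column sums to the species' coefficient in the
   overall reaction (zero for intermediates), intermediates are produced
   before — and in no smaller amount than — they are consumed, every
   declared intermediate takes part, and overall products are terminal.
2. **Translation.** Row *j* becomes the irreversible mass-action step with
   rate `r_j = k_j · Π_i C_i^{m_ij}` over its reactants, giving the ODE
   system `dC/dt = νᵀ r`.
3. **Estimation.** Rate constants minimize the sum of squared errors
   between simulated and observed concentrations over all experiments,
   `SSE(θ) = Σ_exp Σ_t Σ_obs (ŷ − y)²`, by multistart L-BFGS-B within
   bounds (default `[0, 10]`, 5 seeded uniform starts).
4. **Selection.** Candidates are scored by `AIC = 2·NLL + 2·d` with the
   concentrated Gaussian `NLL = (N/2)·ln(SSE/N)` and `d` the number of
   steps. Each ladder rung adds one elementary step and one intermediate;
   the ladder stops as soon as the best AIC fails to strictly improve and
   returns the incumbent mechanism.

A model-based design-of-experiments module (Hunter–Reiner criterion) picks
the initial conditions that maximize the squared divergence between the
two best rival models' predicted trajectories, so the next experiment is
the most informative one for discriminating them.

Three seeded in-silico benchmarks are bundled (`generate_hypothetical`,
`generate_aldol`, `generate_fructose`): five experiments each, 30 sampling
times, additive zero-mean Gaussian noise, intermediates hidden.

## Worked example

Refitting the aldol-condensation benchmark (acetophenone A + benzaldehyde
B → chalcone C + water D via an enolate E and a β-hydroxy adduct F):

```python
import numpy as np
import parsimech as pm

case = pm.get_case_study("aldol")
data = pm.generate_aldol(seed=42)                 # 5 experiments, sd 0.15
result = pm.fit(case.true_model, data, pm.FitConfig(seed=1, n_starts=5))
print(np.round(result.k_hat, 4).tolist())         # [0.7534, 0.291, 0.6835]
print(round(result.sse, 3), round(result.aic, 2)) # 12.741 -2305.26
```

The estimates sit within a few percent of the true constants
(0.759 h⁻¹, 0.293 M⁻¹h⁻¹, 0.681 h⁻¹), and the SSE of 12.7 over 600
observations is at the noise floor `N·σ² = 600·0.15² = 13.5` — the model
explains everything except the injected measurement noise.

Short narrative scripts for each capability live in `examples/`
(enumeration, fitting, the discovery ladder, experiment design), and a
thin CLI exposes the same operations from a shell:

```bash
parsimech enumerate --stoich "A:-4,B:1,C:1" --steps 3 --intermediates 1
parsimech simulate-case --name fructose --seed 42 --out data/
parsimech discover --data data/fructose.csv --stoich "A:-1,B:3,C:1" \
    --min-steps 3 --min-species 5 --seed 7 --out result.json
```

## Documentation

`docs/methods.md` describes the model assumptions, the feasibility rules
and their rationale, numerical choices (solver tolerances, failure
penalties, tie-breaks), what the synthetic benchmarks do and do not
emulate, and known limitations.
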