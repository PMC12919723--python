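"""Run the full discovery ladder on a small self-generated dataset.

Data come from the single bimolecular step A + B -> C + D.  The ladder
fits the one-step rung, then tries a two-step rung with one intermediate;
because the extra step buys no informational gain on data the simple
mechanism already explains, the AIC worsens and the ladder returns the
one-step incumbent.  (The bundled case studies run the same way, just
longer: pass the output of `generate_aldol` etc. to `run_discovery`.)
"""

import numpy as np

import parsimech as pm

truth = pm.matrix_to_steps([[-1, -1, 1, 1]], ("A", "B", "C", "D"))
data = pm.generate_generic(
    truth, [0.4],
    [(5, 10, 0, 0), (5, 5, 2, 0), (10, 10, 0, 0)],
    t_span=(0, 10), n_t=30, noise_sd=0.05,
    observed_names=("A", "B", "C", "D"), seed=7,
)

stoich = pm.StoichiometrySpec(("A", "B", "C", "D"), (-1, -1, 1, 1))
result = pm.run_discovery(
    stoich, data, min_steps=1, min_species=4,
    fit_config=pm.FitConfig(seed=0), max_iterations=4,
)

for rec in result.records:
    print(
        f"iteration {rec.iteration_index}: {rec.n_steps}x{rec.n_species} matrix, "
        f"{rec.n_candidates} candidates, best AIC {rec.aic:.2f}"
    )
print("termination:", result.termination_reason)
print("winner: iteration", result.winner.iteration_index)
for line in result.winner.reaction_strings():
    print("  " + line)
print("k_hat:", np.round(result.winner.best_fit.k_hat, 4).tolist(), "(true 0.4)")

# The winning mechanism is the data-generating step and its rate constant
# is recovered to within the noise; the second rung's higher AIC is what
# stopped the ladder.
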