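"""Enumerate every feasible elementary-step mechanism for a fixed size.

For the overall reaction 4A -> B + C with one hidden intermediate and
three elementary steps, the unconstrained search space holds 5**12
(about 2.4e8) integer matrices; the feasibility rules cut this to a
few dozen chemically sensible candidates.
"""

import parsimech as pm

stoich = pm.StoichiometrySpec(("A", "B", "C"), (-4, 1, 1), n_intermediates=1)
config = pm.EnumerationConfig(n_steps=3)

print("search space:", pm.search_space_size(3, stoich.n_species, config))
result = pm.enumerate_feasible(stoich, config)
print("feasible mechanisms:", len(result))

names = stoich.all_species_names
for matrix in list(result)[:5]:
    model = pm.matrix_to_steps(matrix, names)
    print("  " + ";  ".join(pm.steps_to_strings(model)))
print("  ...")

# Each line above is one candidate mechanism: three elementary steps over
# A, B, C and the intermediate D, with every step consuming at most two and
# producing at most two molecules, columns balancing the overall reaction,
# and D produced before it is consumed.
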