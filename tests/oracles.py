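"""Independent brute-force oracle for the mechanism feasibility rules.

Deliberately written from scratch against the rule statements (plain
tuples, exhaustive Cartesian product) so it shares no code with the
backtracking enumeration it cross-checks.
"""

import itertools


def row_admissible(row, entry_min=-2, entry_max=2, max_react=2, max_prod=2):
    if any(x < entry_min or x > entry_max for x in row):
        return False
    neg = sum(-x for x in row if x < 0)
    pos = sum(x for x in row if x > 0)
    return 1 <= neg <= max_react and 1 <= pos <= max_prod


def matrix_feasible(mat, targets, n_observed):
    n = len(targets)
    for j in range(n):
        col = [row[j] for row in mat]
        if sum(col) != targets[j]:
            return False
        if j < n_observed and targets[j] > 0 and any(x < 0 for x in col):
            return False  # overall products are terminal
        if j >= n_observed:
            running = 0
            for x in col:
                running += x
                if running < 0:
                    return False  # consumed before produced
            if all(x == 0 for x in col):
                return False  # declared intermediate never used
    return True


def brute_force_enumerate(targets, n_observed, n_steps, entry_min=-2, entry_max=2):
    """All feasible matrices by filtering the full Cartesian product."""
    n = len(targets)
    rows = [
        r
        for r in itertools.product(range(entry_min, entry_max + 1), repeat=n)
        if row_admissible(r, entry_min, entry_max)
    ]
    return {
        mat
        for mat in itertools.product(rows, repeat=n_steps)
        if matrix_feasible(mat, targets, n_observed)
    }
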