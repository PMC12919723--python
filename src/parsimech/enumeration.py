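"""Constrained enumeration of candidate reaction mechanisms.

A mechanism is an ordered integer matrix: each row is one elementary step,
each column one chemical species (observed species first, then declared
intermediates).  Negative entries are net consumption, positive entries net
production.  Enumeration walks the matrix row by row with backtracking,
pruning partial mechanisms that can no longer satisfy the feasibility rules:

* per-row molecularity limits (at least one reactant and one product, at
  most ``max_reactant_molecules`` / ``max_product_molecules`` of each,
  counting stoichiometric multiplicity);
* stoichiometric consistency (every column sums to the species' coefficient
  in the overall reaction; zero for intermediates);
* intermediate availability (the running sum of an intermediate column must
  never go negative: an intermediate cannot be consumed before — or in
  larger amount than — it has been produced);
* intermediate usage (a declared intermediate must take part in at least
  one step);
* overall products are terminal (a species with a positive overall
  coefficient is never consumed by a later step).
"""

from __future__ import annotations

import itertools
import json
import string
import time
from dataclasses import dataclass, field

from joblib import Parallel, delayed

__all__ = [
    "StoichiometrySpec",
    "EnumerationConfig",
    "MechanismMatrix",
    "EnumerationResult",
    "candidate_rows",
    "search_space_size",
    "is_feasible",
    "enumerate_feasible",
]


@dataclass(frozen=True)
class StoichiometrySpec:
    """Overall reaction stoichiometry plus a count of hidden intermediates.

    Parameters
    ----------
    species_names
        Labels of the observed species, in column order.
    overall_coeffs
        Signed integer coefficient of each observed species in the overall
        reaction: negative for reactants, positive for products.  Zeros are
        not allowed here — species absent from the overall reaction are
        declared through ``n_intermediates`` instead.
    n_intermediates
        Number of intermediate columns appended after the observed species.
        Each intermediate column must sum to zero.
    """

    species_names: tuple[str, ...]
    overall_coeffs: tuple[int, ...]
    n_intermediates: int = 0

    def __init__(self, species_names, overall_coeffs, n_intermediates=0):
        object.__setattr__(self, "species_names", tuple(species_names))
        object.__setattr__(self, "overall_coeffs", tuple(int(c) for c in overall_coeffs))
        object.__setattr__(self, "n_intermediates", int(n_intermediates))
        self._validate()

    def _validate(self) -> None:
        if len(self.species_names) != len(self.overall_coeffs):
            raise ValueError("species_names and overall_coeffs must have equal length")
        if len(set(self.species_names)) != len(self.species_names):
            raise ValueError("species names must be unique")
        if any(c == 0 for c in self.overall_coeffs):
            raise ValueError(
                "zero coefficients are not allowed among observed species; "
                "declare intermediates via n_intermediates"
            )
        if not any(c < 0 for c in self.overall_coeffs):
            raise ValueError("overall reaction needs at least one reactant")
        if not any(c > 0 for c in self.overall_coeffs):
            raise ValueError("overall reaction needs at least one product")
        if self.n_intermediates < 0:
            raise ValueError("n_intermediates must be non-negative")

    @property
    def n_observed(self) -> int:
        return len(self.species_names)

    @property
    def n_species(self) -> int:
        return self.n_observed + self.n_intermediates

    @property
    def column_targets(self) -> tuple[int, ...]:
        """Per-column sum targets: overall coefficients, then zeros."""
        return self.overall_coeffs + (0,) * self.n_intermediates

    @property
    def all_species_names(self) -> tuple[str, ...]:
        """Observed names followed by generated intermediate labels.

        Intermediates are labelled with the next unused uppercase letters
        (D, E, F, ...), falling back to I1, I2, ... once the alphabet is
        exhausted or collides.
        """
        used = set(self.species_names)
        labels = []
        pool = iter(string.ascii_uppercase)
        for i in range(self.n_intermediates):
            for cand in pool:
                if cand not in used:
                    used.add(cand)
                    labels.append(cand)
                    break
            else:
                cand = f"I{i + 1}"
                while cand in used:
                    cand += "x"
                used.add(cand)
                labels.append(cand)
        return self.species_names + tuple(labels)

    def with_intermediates(self, n: int) -> "StoichiometrySpec":
        return StoichiometrySpec(self.species_names, self.overall_coeffs, n)


@dataclass(frozen=True)
class EnumerationConfig:
    """Limits and resources for mechanism enumeration.

    Defaults encode the four elementary-reaction archetypes A→B, A+B→C,
    A→B+C and A+B→C+D: entries in [-2, 2], at most two reactant and two
    product molecules per step.  Raise the limits for higher-order steps.
    """

    n_steps: int = 1
    entry_min: int = -2
    entry_max: int = 2
    max_reactant_molecules: int = 2
    max_product_molecules: int = 2
    time_budget: float | None = None  # seconds; None = unlimited
    n_workers: int = 1

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be positive")
        if not (self.entry_min < 0 < self.entry_max):
            raise ValueError("entry bounds must satisfy entry_min < 0 < entry_max")
        if self.max_reactant_molecules < 1 or self.max_product_molecules < 1:
            raise ValueError("molecularity limits must be positive")
        if self.n_workers < 1:
            raise ValueError("n_workers must be positive")


@dataclass(frozen=True)
class MechanismMatrix:
    """Ordered net-stoichiometry matrix: rows are steps, columns species."""

    entries: tuple[tuple[int, ...], ...]

    def __init__(self, entries):
        object.__setattr__(
            self, "entries", tuple(tuple(int(x) for x in row) for row in entries)
        )
        if not self.entries:
            raise ValueError("mechanism matrix needs at least one row")
        widths = {len(r) for r in self.entries}
        if len(widths) != 1:
            raise ValueError("all rows must have the same length")

    @property
    def n_steps(self) -> int:
        return len(self.entries)

    @property
    def n_species(self) -> int:
        return len(self.entries[0])

    def to_dict(self, species_names: tuple[str, ...] | None = None) -> dict:
        d = {"entries": [list(r) for r in self.entries]}
        if species_names is not None:
            d["species_names"] = list(species_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MechanismMatrix":
        return cls(d["entries"])

    def to_json(self, species_names=None) -> str:
        return json.dumps(self.to_dict(species_names))


@dataclass
class EnumerationResult:
    """Feasible mechanisms plus a flag telling whether the search finished."""

    matrices: list[MechanismMatrix]
    complete: bool = True
    elapsed: float = 0.0

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)


# ---------------------------------------------------------------------------
# row-level predicates


def _row_ok(row, config: EnumerationConfig) -> str | None:
    """Return None if the row satisfies the per-row rules, else a rule tag."""
    neg = sum(-x for x in row if x < 0)
    pos = sum(x for x in row if x > 0)
    if any(x < config.entry_min or x > config.entry_max for x in row):
        return "entry-bounds"
    if neg == 0:
        return "row-needs-reactant"
    if pos == 0:
        return "row-needs-product"
    if neg > config.max_reactant_molecules:
        return "reactant-molecularity"
    if pos > config.max_product_molecules:
        return "product-molecularity"
    return None


def candidate_rows(n_species: int, config: EnumerationConfig) -> list[tuple[int, ...]]:
    """All admissible step rows for ``n_species`` columns, lexicographically.

    A row is admissible when it has at least one negative and one positive
    entry, within the configured entry bounds and molecularity limits.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rows = []
    for row in itertools.product(
        range(config.entry_min, config.entry_max + 1), repeat=n_species
    ):
        if _row_ok(row, config) is None:
            rows.append(row)
    return rows


def search_space_size(n_steps: int, n_species: int, config: EnumerationConfig) -> int:
    """Total number of unconstrained matrices, d**(n_steps*n_species)."""
    if n_steps < 1 or n_species < 1:
        raise ValueError("n_steps and n_species must be >= 1")
    d = config.entry_max - config.entry_min + 1
    return d ** (n_steps * n_species)


def is_feasible(
    matrix: MechanismMatrix,
    stoich: StoichiometrySpec,
    config: EnumerationConfig,
) -> tuple[bool, str | None]:
    """Check all feasibility rules; on failure report the first violated rule.

    Rule tags: ``entry-bounds``, ``row-needs-reactant``, ``row-needs-product``,
    ``reactant-molecularity``, ``product-molecularity``, ``column-sum``,
    ``product-consumed``, ``intermediate-availability``,
    ``intermediate-unused``.
    """
    if matrix.n_steps != config.n_steps or matrix.n_species != stoich.n_species:
        raise ValueError(
            f"matrix is {matrix.n_steps}x{matrix.n_species}, expected "
            f"{config.n_steps}x{stoich.n_species}"
        )
    for row in matrix.entries:
        tag = _row_ok(row, config)
        if tag is not None:
            return False, tag
    targets = stoich.column_targets
    n_obs = stoich.n_observed
    for j, target in enumerate(targets):
        col = [row[j] for row in matrix.entries]
        if sum(col) != target:
            return False, "column-sum"
        if j < n_obs and target > 0 and any(x < 0 for x in col):
            return False, "product-consumed"
        if j >= n_obs:
            running = 0
            for x in col:
                running += x
                if running < 0:
                    return False, "intermediate-availability"
            if all(x == 0 for x in col):
                return False, "intermediate-unused"
    return True, None


# ---------------------------------------------------------------------------
# backtracking search


def _search_subtree(first_rows, rows, stoich, config, deadline):
    """Depth-first completion of matrices whose first row is in first_rows.

    Returns (list of entry tuples, completed flag).
    """
    targets = stoich.column_targets
    n_obs = stoich.n_observed
    n_steps = config.n_steps
    n_species = stoich.n_species
    reach = max(-config.entry_min, config.entry_max)
    # products are terminal: rows consuming an overall product can never
    # take part in a feasible mechanism, so drop them up front
    prod_cols = [j for j in range(n_obs) if targets[j] > 0]
    rows = [r for r in rows if all(r[j] >= 0 for j in prod_cols)]
    first_rows = [r for r in first_rows if all(r[j] >= 0 for j in prod_cols)]
    out: list[tuple[tuple[int, ...], ...]] = []
    complete = True

    def prune(partial_sums, running_inter, depth) -> bool:
        remaining = n_steps - depth
        for j in range(n_species):
            deficit = targets[j] - partial_sums[j]
            if abs(deficit) > remaining * reach:
                return True
            # products are terminal: a product column overshooting its
            # target can never come back down
            if j < n_obs and targets[j] > 0 and deficit < 0:
                return True
        for s in running_inter:
            if s < 0:  # availability violation already committed
                return True
        return False

    def extend(prefix, partial_sums, running_inter, depth):
        nonlocal complete
        if deadline is not None and time.monotonic() > deadline:
            complete = False
            return
        if depth == n_steps:
            if all(partial_sums[j] == targets[j] for j in range(n_species)):
                # availability held at every prefix; check usage only
                for j in range(n_obs, n_species):
                    if all(row[j] == 0 for row in prefix):
                        return
                out.append(tuple(prefix))
            return
        for row in rows:
            new_sums = tuple(partial_sums[j] + row[j] for j in range(n_species))
            new_inter = tuple(
                running_inter[j - n_obs] + row[j] for j in range(n_obs, n_species)
            )
            if any(s < 0 for s in new_inter):
                continue
            if prune(new_sums, new_inter, depth + 1):
                continue
            prefix.append(row)
            extend(prefix, new_sums, new_inter, depth + 1)
            prefix.pop()
            if not complete:
                return

    zero = (0,) * n_species
    for first in first_rows:
        sums = tuple(first)
        inter = tuple(first[j] for j in range(n_obs, n_species))
        if any(s < 0 for s in inter):
            continue
        if prune(sums, inter, 1):
            continue
        extend([first], sums, inter, 1)
        if not complete:
            break
    del zero
    return out, complete


def enumerate_feasible(
    stoich: StoichiometrySpec, config: EnumerationConfig
) -> EnumerationResult:
    """Enumerate every feasible ordered mechanism matrix by backtracking.

    The search tree is partitioned by first-row candidate so workers can
    explore subtrees independently; results are merged and sorted
    lexicographically, so the output is identical for any ``n_workers``.
    On time-budget expiry the partial set is returned with
    ``complete=False``.
    """
    t0 = time.monotonic()
    rows = candidate_rows(stoich.n_species, config)
    deadline = None if config.time_budget is None else t0 + config.time_budget

    if config.n_workers == 1 or len(rows) < 2:
        found, complete = _search_subtree(rows, rows, stoich, config, deadline)
    else:
        chunks = [rows[i :: config.n_workers] for i in range(config.n_workers)]
        results = Parallel(n_jobs=config.n_workers)(
            delayed(_search_subtree)(chunk, rows, stoich, config, deadline)
            for chunk in chunks
        )
        found = [m for part, _ in results for m in part]
        complete = all(flag for _, flag in results)

    found.sort()
    return EnumerationResult(
        matrices=[MechanismMatrix(m) for m in found],
        complete=complete,
        elapsed=time.monotonic() - t0,
    )
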