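"""Iterative mechanism discovery: enumerate, fit, select, grow, stop.

Starting from the smallest admissible matrix size, each iteration adds one
elementary step and one intermediate species, enumerates every feasible
mechanism of that size, fits each candidate's rate constants, and keeps the
candidate with the lowest AIC.  The ladder stops as soon as an iteration
fails to strictly improve the incumbent AIC (equal counts as worsening),
returning the incumbent; a maximum iteration count and an optional global
wall-clock budget guard against unbounded growth.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from typing import Callable

from joblib import Parallel, delayed

from .enumeration import (
    EnumerationConfig,
    MechanismMatrix,
    StoichiometrySpec,
    enumerate_feasible,
)
from .estimation import ExperimentSet, FitConfig, FitResult, fit
from .kinetics import matrix_to_steps, steps_to_strings

__all__ = [
    "IterationRecord",
    "DiscoveryResult",
    "iteration_dimensions",
    "minimal_ladder_start",
    "run_iteration",
    "run_discovery",
]

logger = logging.getLogger(__name__)


@dataclass
class IterationRecord:
    iteration_index: int  # 1-based
    n_steps: int
    n_species: int
    n_candidates: int
    best_matrix: MechanismMatrix | None
    best_fit: FitResult | None
    enumeration_complete: bool = True
    species_names: tuple[str, ...] = ()

    @property
    def empty(self) -> bool:
        return self.best_fit is None

    @property
    def aic(self) -> float:
        return math.inf if self.best_fit is None else self.best_fit.aic

    def reaction_strings(self) -> list[str]:
        if self.best_matrix is None:
            return []
        return steps_to_strings(matrix_to_steps(self.best_matrix, self.species_names))


@dataclass
class DiscoveryResult:
    records: list[IterationRecord] = field(default_factory=list)
    winner: IterationRecord | None = None
    termination_reason: str = ""  # aic_worsened | max_iterations | budget | empty

    @property
    def winner_index(self) -> int | None:
        return None if self.winner is None else self.winner.iteration_index


def iteration_dimensions(
    min_steps: int, min_species: int, iteration_index: int
) -> tuple[int, int]:
    """Matrix size at a ladder rung: one extra step and species per rung.

    Returns ``(n_steps, n_intermediates_added)`` where the added
    intermediates come on top of the iteration-1 species set.
    """
    if iteration_index < 1:
        raise ValueError("iteration_index is 1-based")
    return min_steps + iteration_index - 1, iteration_index - 1


def minimal_ladder_start(
    stoich: StoichiometrySpec, config: EnumerationConfig | None = None
) -> tuple[int, int]:
    """Smallest (min_steps, min_species) the molecularity limits allow.

    With at most r reactant and p product molecules per step, s steps can
    consume at most s*r and produce at most s*p molecules, so the overall
    molecule counts bound the step count from below.  Users with prior
    knowledge should override this starting point.
    """
    if config is None:
        config = EnumerationConfig()
    consumed = sum(-c for c in stoich.overall_coeffs if c < 0)
    produced = sum(c for c in stoich.overall_coeffs if c > 0)
    min_steps = max(
        1,
        math.ceil(consumed / config.max_reactant_molecules),
        math.ceil(produced / config.max_product_molecules),
    )
    return min_steps, stoich.n_observed


def _fit_candidate(matrix, species_names, data, fit_config):
    model = matrix_to_steps(matrix, species_names)
    return fit(model, data, fit_config)


def run_iteration(
    stoich: StoichiometrySpec,
    data: ExperimentSet,
    iteration_index: int,
    min_steps: int,
    min_species: int,
    enum_config: EnumerationConfig | None = None,
    fit_config: FitConfig | None = None,
    n_workers: int = 1,
    metric: Callable[[FitResult], float] | None = None,
) -> IterationRecord:
    """Enumerate and fit all candidates of one ladder rung; pick the best.

    ``metric`` maps a FitResult to the selection score (lower is better);
    the default is the AIC.  Ties are broken by the lexicographically
    smallest matrix, which is the enumeration order.
    """
    if metric is None:
        metric = lambda fr: fr.aic  # noqa: E731
    n_steps, added = iteration_dimensions(min_steps, min_species, iteration_index)
    n_intermediates = (min_species - stoich.n_observed) + added
    rung_stoich = stoich.with_intermediates(n_intermediates)
    enum_config = enum_config or EnumerationConfig()
    enum_config = EnumerationConfig(
        n_steps=n_steps,
        entry_min=enum_config.entry_min,
        entry_max=enum_config.entry_max,
        max_reactant_molecules=enum_config.max_reactant_molecules,
        max_product_molecules=enum_config.max_product_molecules,
        time_budget=enum_config.time_budget,
        n_workers=enum_config.n_workers,
    )
    enum_result = enumerate_feasible(rung_stoich, enum_config)
    if not enum_result.complete:
        logger.warning(
            "iteration %d: enumeration time budget expired after %d matrices",
            iteration_index,
            len(enum_result),
        )
    names = rung_stoich.all_species_names
    record = IterationRecord(
        iteration_index=iteration_index,
        n_steps=n_steps,
        n_species=rung_stoich.n_species,
        n_candidates=len(enum_result),
        best_matrix=None,
        best_fit=None,
        enumeration_complete=enum_result.complete,
        species_names=names,
    )
    if len(enum_result) == 0:
        return record

    if n_workers > 1:
        fits = Parallel(n_jobs=n_workers)(
            delayed(_fit_candidate)(m, names, data, fit_config)
            for m in enum_result.matrices
        )
    else:
        fits = [
            _fit_candidate(m, names, data, fit_config) for m in enum_result.matrices
        ]

    best_i = None
    for i, fr in enumerate(fits):
        logger.debug(
            "iteration %d candidate %d: SSE=%.6g AIC=%.6g",
            iteration_index,
            i,
            fr.sse,
            fr.aic,
        )
        if not fr.success:
            continue
        if best_i is None or metric(fr) < metric(fits[best_i]):
            best_i = i
    if best_i is None:
        logger.warning("iteration %d: all candidate fits failed", iteration_index)
        return record
    record.best_matrix = enum_result.matrices[best_i]
    record.best_fit = fits[best_i]
    logger.info(
        "iteration %d: %d candidates, best AIC %.4f",
        iteration_index,
        len(enum_result),
        record.best_fit.aic,
    )
    return record


def run_discovery(
    stoich: StoichiometrySpec,
    data: ExperimentSet,
    min_steps: int | None = None,
    min_species: int | None = None,
    enum_config: EnumerationConfig | None = None,
    fit_config: FitConfig | None = None,
    max_iterations: int = 6,
    time_budget: float | None = None,
    n_workers: int = 1,
    metric: Callable[[FitResult], float] | None = None,
) -> DiscoveryResult:
    """Run the complexity ladder until the AIC stops improving.

    The winner is the best model of the last strictly improving iteration.
    Termination reasons: ``aic_worsened`` (next rung failed to improve),
    ``max_iterations``, ``budget`` (global wall clock), or ``empty`` (a rung
    produced no fittable candidate before any incumbent existed).
    """
    if min_steps is None or min_species is None:
        auto_steps, auto_species = minimal_ladder_start(stoich, enum_config)
        min_steps = min_steps if min_steps is not None else auto_steps
        min_species = min_species if min_species is not None else auto_species
    if min_species < stoich.n_observed:
        raise ValueError("min_species cannot be below the observed species count")

    result = DiscoveryResult()
    deadline = None if time_budget is None else time.monotonic() + time_budget
    incumbent: IterationRecord | None = None
    for i in range(1, max_iterations + 1):
        record = run_iteration(
            stoich,
            data,
            i,
            min_steps,
            min_species,
            enum_config,
            fit_config,
            n_workers,
            metric,
        )
        result.records.append(record)
        if record.empty:
            if incumbent is None:
                result.termination_reason = "empty"
                return result
            result.termination_reason = "aic_worsened"
            result.winner = incumbent
            return result
        if incumbent is not None and record.aic >= incumbent.aic:
            # equal AIC counts as worsening: no informational gain
            result.termination_reason = "aic_worsened"
            result.winner = incumbent
            return result
        incumbent = record
        if deadline is not None and time.monotonic() > deadline:
            result.termination_reason = "budget"
            result.winner = incumbent
            return result
    result.termination_reason = "max_iterations"
    result.winner = incumbent
    return result
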