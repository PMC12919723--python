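"""Rate-constant estimation by multistart bounded quasi-Newton SSE fitting.

The objective is the plain sum of squared errors between simulated and
observed concentrations over all experiments, sampling times and observed
species.  Models are scored with the Akaike information criterion computed
from the concentrated Gaussian negative log-likelihood
``NLL = (N/2) ln(SSE/N)`` (maximum-likelihood noise variance, additive
constants dropped), so AIC differences within one dataset are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .kinetics import MassActionModel, simulate

__all__ = [
    "Experiment",
    "ExperimentSet",
    "FitConfig",
    "FitResult",
    "sse",
    "nll",
    "aic",
    "fit",
]

DEFAULT_FAILURE_PENALTY = 1e10


@dataclass(frozen=True)
class Experiment:
    """One concentration-time experiment.

    ``C0_full`` is the full initial-condition vector aligned with
    ``species_names_full`` (the data-generating species list, observed
    species first).  Model species are matched to initial conditions by
    name; species the experiment does not mention start at zero.
    """

    t: np.ndarray
    y: np.ndarray  # n_t x n_observed
    observed_names: tuple[str, ...]
    C0_full: np.ndarray
    species_names_full: tuple[str, ...]

    def __init__(self, t, y, observed_names, C0_full, species_names_full=None):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        observed_names = tuple(observed_names)
        if species_names_full is None:
            species_names_full = observed_names
        species_names_full = tuple(species_names_full)
        C0_full = np.asarray(C0_full, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing with n_t >= 2")
        if y.shape != (len(t), len(observed_names)):
            raise ValueError("y must be n_t x n_observed")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        if C0_full.shape != (len(species_names_full),):
            raise ValueError("C0_full must align with species_names_full")
        if not set(observed_names) <= set(species_names_full):
            raise ValueError("observed species must be in species_names_full")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "observed_names", observed_names)
        object.__setattr__(self, "C0_full", C0_full)
        object.__setattr__(self, "species_names_full", species_names_full)

    @property
    def n_t(self) -> int:
        return len(self.t)

    def c0_for(self, model: MassActionModel) -> np.ndarray:
        """Initial conditions in the model's species order; unknowns -> 0."""
        lookup = dict(zip(self.species_names_full, self.C0_full))
        return np.array([lookup.get(name, 0.0) for name in model.species_names])


@dataclass(frozen=True)
class ExperimentSet:
    """A collection of experiments sharing species naming and observables."""

    experiments: tuple[Experiment, ...]

    def __init__(self, experiments):
        experiments = tuple(experiments)
        if not experiments:
            raise ValueError("need at least one experiment")
        obs = experiments[0].observed_names
        if any(e.observed_names != obs for e in experiments):
            raise ValueError("all experiments must share the observed species set")
        object.__setattr__(self, "experiments", experiments)

    @property
    def observed_names(self) -> tuple[str, ...]:
        return self.experiments[0].observed_names

    @property
    def total_points(self) -> int:
        return sum(e.n_t * len(e.observed_names) for e in self.experiments)

    def __len__(self) -> int:
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)


@dataclass(frozen=True)
class FitConfig:
    lower: float = 0.0
    upper: float = 10.0
    n_starts: int = 5
    seed: int | None = None
    solver_opts: dict | None = None
    failure_penalty: float = DEFAULT_FAILURE_PENALTY

    def __post_init__(self):
        if self.lower < 0:
            raise ValueError("lower bound must be non-negative")
        if self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FitResult:
    k_hat: np.ndarray
    sse: float
    nll: float
    aic: float
    d: int
    per_start: list[tuple[np.ndarray, float, bool]] = field(default_factory=list)
    success: bool = True

    def to_dict(self) -> dict:
        return {
            "k_hat": list(map(float, self.k_hat)),
            "sse": float(self.sse),
            "nll": float(self.nll),
            "aic": float(self.aic),
            "d": int(self.d),
            "success": bool(self.success),
        }


def sse(
    model: MassActionModel,
    k,
    data: ExperimentSet,
    solver_opts: dict | None = None,
    failure_penalty: float = DEFAULT_FAILURE_PENALTY,
) -> float:
    """Sum of squared errors over experiments, times and observed species.

    A failed simulation contributes ``failure_penalty`` instead of raising.
    """
    k = np.asarray(k, dtype=float)
    if k.shape != (model.n_params,):
        raise ValueError(f"k must have length {model.n_params}")
    name_to_idx = {n: i for i, n in enumerate(model.species_names)}
    total = 0.0
    for exp in data:
        try:
            cols = [name_to_idx[n] for n in exp.observed_names]
        except KeyError as missing:
            raise ValueError(f"model lacks observed species {missing}") from None
        res = simulate(model, k, exp.c0_for(model), exp.t, solver_opts)
        if not res.success:
            total += failure_penalty
            continue
        resid = res.y[:, cols] - exp.y
        total += float(np.sum(resid * resid))
    return total


def nll(sse_value: float, n_points: int) -> float:
    """Concentrated Gaussian negative log-likelihood, constants dropped.

    ``NLL = (N/2) ln(SSE/N)`` with the MLE variance ``SSE/N``; SSE is
    floored at machine epsilon times N to keep the log finite.
    """
    if sse_value < 0:
        raise ValueError("SSE must be non-negative")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    floor = np.finfo(float).eps * n_points
    return 0.5 * n_points * float(np.log(max(sse_value, floor) / n_points))


def aic(nll_value: float, d: int) -> float:
    """Akaike information criterion, ``2 NLL + 2 d``."""
    if d < 0:
        raise ValueError("parameter count must be non-negative")
    return 2.0 * nll_value + 2.0 * d


def fit(
    model: MassActionModel,
    data: ExperimentSet,
    config: FitConfig | None = None,
) -> FitResult:
    """Multistart bounded L-BFGS-B minimization of the SSE.

    Start points are drawn uniformly in the bounds box from a generator
    seeded by ``config.seed``; the start reaching the lowest SSE wins, so
    the result is deterministic given (seed, data, model).
    """
    if config is None:
        config = FitConfig()
    d = model.n_params
    if d < 1:
        raise ValueError("model must have at least one parameter")
    rng = np.random.default_rng(config.seed)
    starts = rng.uniform(config.lower, config.upper, size=(config.n_starts, d))
    bounds = [(config.lower, config.upper)] * d

    def objective(k):
        return sse(model, k, data, config.solver_opts, config.failure_penalty)

    per_start = []
    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        final = float(res.fun)
        per_start.append((x0.copy(), final, bool(res.success)))
        if best is None or final < best[1]:
            best = (np.clip(res.x, config.lower, config.upper), final)

    k_hat, best_sse = best
    n = data.total_points
    success = best_sse < config.failure_penalty
    nll_val = nll(best_sse, n)
    return FitResult(
        k_hat=k_hat,
        sse=best_sse,
        nll=nll_val,
        aic=aic(nll_val, d),
        d=d,
        per_start=per_start,
        success=success,
    )
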