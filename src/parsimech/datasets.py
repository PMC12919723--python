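"""Seeded in-silico case-study datasets for mechanism-discovery benchmarks.

Three ground-truth systems are bundled:

* ``hypothetical`` — overall 4A → B + C through two hidden intermediates:
  2A → D, A → E, D → B, A + E → C with k = (0.1 M⁻¹h⁻¹, 0.2 h⁻¹, 0.13 h⁻¹,
  0.25 M⁻¹h⁻¹); A, B, C observed over [0, 10] h.
* ``aldol`` — aldol condensation of acetophenone (A) and benzaldehyde (B)
  to chalcone (C) and water (D) via enolization (A → E), carbon–carbon
  coupling (E + B → F) and dehydration (F → C + D) with k = (0.759 h⁻¹,
  0.293 M⁻¹h⁻¹, 0.681 h⁻¹); A–D observed over [0, 10] h.
* ``fructose`` — acid-catalysed dehydration of fructose (A) to HMF (C)
  releasing three waters (B): overall A → 3B + C with the experimentally
  validated rate r = k·C_A·C_acid at constant C_acid = 3.3e-2 M,
  k = 0.9 M⁻¹min⁻¹ at 410.15 K; A, B, C observed over [0, 90] min.

Each generator simulates five experiments at fixed initial-condition sets,
samples 30 time points, and adds zero-mean Gaussian noise to the observed
species only (sd 0.15 for the first two cases, 0.2 for fructose);
intermediates are hidden.  Noise is drawn from a single seeded generator,
one block per experiment in column-major (species-by-species) order, so
datasets are bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .enumeration import StoichiometrySpec
from .estimation import Experiment, ExperimentSet
from .kinetics import MassActionModel, matrix_to_steps, simulate

__all__ = [
    "CaseStudy",
    "ArrheniusRate",
    "GAS_CONSTANT",
    "generate_generic",
    "generate_hypothetical",
    "generate_aldol",
    "generate_fructose",
    "get_case_study",
    "CASE_STUDY_NAMES",
]

GAS_CONSTANT = 8.314  # J K^-1 mol^-1


@dataclass(frozen=True)
class ArrheniusRate:
    """Second-order rate constant with Arrhenius temperature correction."""

    k_ref: float  # M^-1 min^-1 at T_ref
    E_a: float  # J mol^-1
    T: float  # K
    T_ref: float  # K
    C_acid: float  # M, constant catalyst concentration

    def __post_init__(self):
        if self.T <= 0 or self.T_ref <= 0:
            raise ValueError("temperatures must be positive")

    @property
    def k(self) -> float:
        """k(T) = k_ref * exp(-E_a/R * (1/T - 1/T_ref)); k_ref at T = T_ref."""
        val = self.k_ref * math.exp(
            -self.E_a / GAS_CONSTANT * (1.0 / self.T - 1.0 / self.T_ref)
        )
        if val <= 0:
            raise ValueError("evaluated rate constant must be positive")
        return val

    @property
    def k_effective(self) -> float:
        """Pseudo-first-order constant k * C_acid (min^-1)."""
        return self.k * self.C_acid


@dataclass(frozen=True)
class CaseStudy:
    """Ground truth and experimental design of one in-silico benchmark."""

    name: str
    stoich: StoichiometrySpec
    true_model: MassActionModel
    true_k: tuple[float, ...]
    k_units: tuple[str, ...]
    initial_condition_sets: tuple[tuple[float, ...], ...]
    t_span: tuple[float, float]
    n_t: int
    noise_sd: float
    observed_names: tuple[str, ...]
    time_unit: str
    min_steps: int
    min_species: int


def generate_generic(
    model: MassActionModel,
    k,
    initial_condition_sets,
    t_span,
    n_t,
    noise_sd,
    observed_names,
    seed=None,
    noiseless: bool = False,
    solver_opts: dict | None = None,
) -> ExperimentSet:
    """Simulate-then-perturb pipeline shared by the named generators.

    Each initial-condition vector (aligned with ``model.species_names``)
    yields one experiment on a uniform grid of ``n_t`` points spanning
    ``t_span``; Gaussian noise with standard deviation ``noise_sd`` is
    added to the observed columns unless ``noiseless``.
    """
    k = np.asarray(k, dtype=float)
    t_grid = np.linspace(t_span[0], t_span[1], n_t)
    observed_names = tuple(observed_names)
    cols = [model.species_names.index(n) for n in observed_names]
    rng = np.random.default_rng(seed)
    experiments = []
    for c0 in initial_condition_sets:
        c0 = np.asarray(c0, dtype=float)
        res = simulate(model, k, c0, t_grid, solver_opts)
        if not res.success:
            raise RuntimeError(f"ground-truth simulation failed: {res.message}")
        y = res.y[:, cols].copy()
        if not noiseless and noise_sd > 0:
            # column-major draw: one species' whole series at a time
            noise = rng.normal(0.0, noise_sd, size=(len(cols), n_t)).T
            y = y + noise
        experiments.append(
            Experiment(
                t=t_grid,
                y=y,
                observed_names=observed_names,
                C0_full=c0,
                species_names_full=model.species_names,
            )
        )
    return ExperimentSet(experiments)


def _hypothetical_case() -> CaseStudy:
    stoich = StoichiometrySpec(("A", "B", "C"), (-4, 1, 1), n_intermediates=2)
    # 2A -> D, A -> E, D -> B, A + E -> C  (species A, B, C, D, E)
    matrix = [
        [-2, 0, 0, 1, 0],
        [-1, 0, 0, 0, 1],
        [0, 1, 0, -1, 0],
        [-1, 0, 1, 0, -1],
    ]
    model = matrix_to_steps(matrix, ("A", "B", "C", "D", "E"))
    return CaseStudy(
        name="hypothetical",
        stoich=stoich,
        true_model=model,
        true_k=(0.1, 0.2, 0.13, 0.25),
        k_units=("M^-1 h^-1", "h^-1", "h^-1", "M^-1 h^-1"),
        initial_condition_sets=(
            (10, 0, 2, 0, 0),
            (10, 2, 0, 0, 0),
            (10, 2, 2, 0, 0),
            (5, 0, 0, 0, 0),
            (10, 0, 0, 0, 0),
        ),
        t_span=(0.0, 10.0),
        n_t=30,
        noise_sd=0.15,
        observed_names=("A", "B", "C"),
        time_unit="h",
        min_steps=2,
        min_species=3,
    )


def _aldol_case() -> CaseStudy:
    stoich = StoichiometrySpec(("A", "B", "C", "D"), (-1, -1, 1, 1), n_intermediates=2)
    # A -> E, E + B -> F, F -> C + D  (species A..F)
    matrix = [
        [-1, 0, 0, 0, 1, 0],
        [0, -1, 0, 0, -1, 1],
        [0, 0, 1, 1, 0, -1],
    ]
    model = matrix_to_steps(matrix, ("A", "B", "C", "D", "E", "F"))
    return CaseStudy(
        name="aldol",
        stoich=stoich,
        true_model=model,
        true_k=(0.759, 0.293, 0.681),
        k_units=("h^-1", "M^-1 h^-1", "h^-1"),
        initial_condition_sets=(
            (5, 10, 0, 0, 0, 0),
            (5, 5, 2, 0, 0, 0),
            (5, 10, 0, 2, 0, 0),
            (10, 10, 0, 2, 0, 0),
            (10, 10, 2, 2, 0, 0),
        ),
        t_span=(0.0, 10.0),
        n_t=30,
        noise_sd=0.15,
        observed_names=("A", "B", "C", "D"),
        time_unit="h",
        min_steps=1,
        min_species=4,
    )


FRUCTOSE_RATE = ArrheniusRate(
    k_ref=0.9, E_a=124.0, T=410.15, T_ref=410.15, C_acid=3.3e-2
)


def _fructose_case() -> CaseStudy:
    stoich = StoichiometrySpec(("A", "B", "C"), (-1, 3, 1), n_intermediates=2)
    # pseudo-first-order lumped rate model: A -> 3B + C at k_eff = k * C_acid
    model = matrix_to_steps([[-1, 3, 1]], ("A", "B", "C"))
    return CaseStudy(
        name="fructose",
        stoich=stoich,
        true_model=model,
        true_k=(FRUCTOSE_RATE.k_effective,),
        k_units=("min^-1 (k_eff = k * C_acid)",),
        initial_condition_sets=(
            (4, 0, 0),
            (6, 2, 1),
            (4, 2, 0),
            (4, 0, 1),
            (6, 2, 0),
        ),
        t_span=(0.0, 90.0),
        n_t=30,
        noise_sd=0.2,
        observed_names=("A", "B", "C"),
        time_unit="min",
        min_steps=3,
        min_species=5,
    )


_CASES = {
    "hypothetical": _hypothetical_case,
    "aldol": _aldol_case,
    "fructose": _fructose_case,
}
CASE_STUDY_NAMES = tuple(_CASES)


def get_case_study(name: str) -> CaseStudy:
    try:
        return _CASES[name]()
    except KeyError:
        raise ValueError(
            f"unknown case study {name!r}; choose from {CASE_STUDY_NAMES}"
        ) from None


def _generate_case(name, seed, noiseless):
    case = get_case_study(name)
    return generate_generic(
        case.true_model,
        case.true_k,
        case.initial_condition_sets,
        case.t_span,
        case.n_t,
        0.0 if noiseless else case.noise_sd,
        case.observed_names,
        seed=seed,
        noiseless=noiseless,
    )


def generate_hypothetical(seed=None, noiseless: bool = False) -> ExperimentSet:
    """Five seeded experiments of the 4A → B + C benchmark (A, B, C observed)."""
    return _generate_case("hypothetical", seed, noiseless)


def generate_aldol(seed=None, noiseless: bool = False) -> ExperimentSet:
    """Five seeded experiments of the aldol condensation (A–D observed)."""
    return _generate_case("aldol", seed, noiseless)


def generate_fructose(seed=None, noiseless: bool = False) -> ExperimentSet:
    """Five seeded experiments of fructose dehydration (A, B, C observed)."""
    return _generate_case("fructose", seed, noiseless)
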