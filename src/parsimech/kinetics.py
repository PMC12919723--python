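"""Mass-action kinetics: matrix -> reaction steps -> ODEs -> trajectories.

Each mechanism row becomes one irreversible elementary step whose rate is
``k_j * prod_i C_i**m_ij`` over its reactants (mass-action).  The species
balance is ``dC/dt = nu^T r`` with ``nu`` the net stoichiometry matrix.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

from .enumeration import MechanismMatrix

__all__ = [
    "ReactionStep",
    "MassActionModel",
    "SimulationResult",
    "matrix_to_steps",
    "steps_to_strings",
    "parse_reaction_strings",
    "rhs",
    "simulate",
]

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-8


@dataclass(frozen=True)
class ReactionStep:
    """One irreversible elementary step in net representation."""

    reactants: tuple[tuple[int, int], ...]  # (species_index, multiplicity>=1)
    products: tuple[tuple[int, int], ...]
    rate_index: int

    def __post_init__(self):
        if not self.reactants or not self.products:
            raise ValueError("a step needs at least one reactant and one product")
        r_idx = {i for i, _ in self.reactants}
        p_idx = {i for i, _ in self.products}
        if r_idx & p_idx:
            raise ValueError("net representation forbids a species on both sides")
        if any(m < 1 for _, m in self.reactants + self.products):
            raise ValueError("multiplicities must be >= 1")


@dataclass(frozen=True)
class MassActionModel:
    """An ordered set of mass-action steps defining an ODE right-hand side."""

    steps: tuple[ReactionStep, ...]
    species_names: tuple[str, ...]
    # cached arrays for fast rate evaluation
    _nu: np.ndarray = field(repr=False, compare=False, default=None)
    _exponents: np.ndarray = field(repr=False, compare=False, default=None)

    def __init__(self, steps, species_names):
        object.__setattr__(self, "steps", tuple(steps))
        object.__setattr__(self, "species_names", tuple(species_names))
        rate_idx = sorted(s.rate_index for s in self.steps)
        if rate_idx != list(range(len(self.steps))):
            raise ValueError("rate_index values must be 0..n_steps-1, each once")
        nu = np.zeros((len(self.steps), len(self.species_names)))
        ex = np.zeros_like(nu)
        for s in self.steps:
            for i, m in s.reactants:
                nu[s.rate_index, i] -= m
                ex[s.rate_index, i] = m
            for i, m in s.products:
                nu[s.rate_index, i] += m
        object.__setattr__(self, "_nu", nu)
        object.__setattr__(self, "_exponents", ex)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_params(self) -> int:
        return len(self.steps)

    @property
    def nu(self) -> np.ndarray:
        """Net stoichiometry matrix, steps x species."""
        return self._nu.copy()

    def to_matrix(self) -> MechanismMatrix:
        return MechanismMatrix(self._nu.astype(int))


def matrix_to_steps(
    matrix: MechanismMatrix | "np.ndarray | list",
    species_names,
) -> MassActionModel:
    """Translate a net-stoichiometry matrix into a mass-action model.

    Row ``j`` becomes step ``j``: negative entries are reactants with
    multiplicity ``|entry|``, positive entries products; ``rate_index = j``.
    """
    if not isinstance(matrix, MechanismMatrix):
        matrix = MechanismMatrix(matrix)
    species_names = tuple(species_names)
    if len(species_names) != matrix.n_species:
        raise ValueError("species_names length must match matrix columns")
    steps = []
    for j, row in enumerate(matrix.entries):
        reactants = tuple((i, -x) for i, x in enumerate(row) if x < 0)
        products = tuple((i, x) for i, x in enumerate(row) if x > 0)
        if not reactants and not products:
            raise ValueError(f"row {j} is all zeros (redundant step)")
        if not reactants or not products:
            raise ValueError(f"row {j} lacks a reactant or a product")
        steps.append(ReactionStep(reactants, products, rate_index=j))
    return MassActionModel(steps, species_names)


# ---------------------------------------------------------------------------
# reaction strings

_TERM_RE = re.compile(r"^\s*(\d*)\s*([A-Za-z][A-Za-z0-9_]*)\s*$")
_ARROW_RE = re.compile(r"->|→")


def steps_to_strings(model: MassActionModel) -> list[str]:
    """Render each step as e.g. ``2A -> B`` or ``A + B -> C + D``."""

    def side(pairs):
        terms = []
        for i, m in pairs:
            prefix = "" if m == 1 else str(m)
            terms.append(f"{prefix}{model.species_names[i]}")
        return " + ".join(terms)

    return [f"{side(s.reactants)} -> {side(s.products)}" for s in model.steps]


def parse_reaction_strings(lines, species_names=None) -> MassActionModel:
    """Parse reaction strings back into a model (inverse of steps_to_strings).

    Accepts both ``->`` and the unicode arrow.  If ``species_names`` is
    omitted, species are indexed in order of first appearance.
    """
    parsed = []
    seen: list[str] = list(species_names) if species_names is not None else []
    fixed = species_names is not None

    def side_terms(text, lineno):
        out = []
        for term in text.split("+"):
            m = _TERM_RE.match(term)
            if not m:
                raise ValueError(f"line {lineno}: cannot parse term {term!r}")
            mult = int(m.group(1)) if m.group(1) else 1
            name = m.group(2)
            if name not in seen:
                if fixed:
                    raise ValueError(f"line {lineno}: unknown species {name!r}")
                seen.append(name)
            out.append((seen.index(name), mult))
        return tuple(out)

    for lineno, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = _ARROW_RE.split(line)
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected exactly one reaction arrow")
        parsed.append((side_terms(parts[0], lineno), side_terms(parts[1], lineno)))

    steps = [
        ReactionStep(reactants, products, rate_index=j)
        for j, (reactants, products) in enumerate(parsed)
    ]
    return MassActionModel(steps, tuple(seen))


# ---------------------------------------------------------------------------
# ODE right-hand side and simulation


def rhs(model: MassActionModel, k, C) -> np.ndarray:
    """Time derivative of the concentration vector under mass action."""
    k = np.asarray(k, dtype=float)
    C = np.asarray(C, dtype=float)
    if k.shape != (model.n_params,):
        raise ValueError(f"k must have length {model.n_params}")
    if C.shape != (model.n_species,):
        raise ValueError(f"C must have length {model.n_species}")
    if np.any(k < 0):
        raise ValueError("rate constants must be non-negative")
    rates = k * np.prod(C[None, :] ** model._exponents, axis=1)
    return model._nu.T @ rates


@dataclass
class SimulationResult:
    """Trajectory on the requested grid, or a structured failure."""

    success: bool
    t: np.ndarray
    y: np.ndarray | None  # len(t) x n_species
    message: str = ""


def simulate(
    model: MassActionModel,
    k,
    C0,
    t_grid,
    solver_opts: dict | None = None,
) -> SimulationResult:
    """Integrate the mass-action ODEs on ``t_grid`` (LSODA, stiff-capable).

    Solver failure or a non-finite state yields ``success=False`` rather
    than an exception, so parameter estimation can penalize it.
    """
    k = np.asarray(k, dtype=float)
    C0 = np.asarray(C0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if C0.shape != (model.n_species,):
        raise ValueError(f"C0 must have length {model.n_species}")
    if k.shape != (model.n_params,):
        raise ValueError(f"k must have length {model.n_params}")
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    opts = {"rtol": DEFAULT_RTOL, "atol": DEFAULT_ATOL, "mxstep": 10000}
    if solver_opts:
        opts.update(solver_opts)

    nu_T = model._nu.T
    ex = model._exponents

    def f(C, _t):
        return nu_T @ (k * np.prod(C[None, :] ** ex, axis=1))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            y, info = odeint(f, C0, t_grid, full_output=True, **opts)
        except Exception as exc:  # pragma: no cover - defensive
            return SimulationResult(False, t_grid, None, f"solver raised: {exc}")
    if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
        return SimulationResult(False, t_grid, None, info["message"])
    y[0] = C0
    return SimulationResult(True, t_grid, y)
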