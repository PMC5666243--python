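"""Flux balance analysis: the steady-state linear program and utilities.

The LP solved here is

    max  c·v
    s.t. S·v = ẋ,   Vmin ≤ v ≤ Vmax,
         ẋᵢ = 0 for internal metabolites,
         ẋᵢ ∈ ℝ for boundary (exchange) metabolites,

where ``S`` has one row per non-boundary metabolite.  Solving uses SciPy's
HiGHS interface, which is deterministic for a fixed variable ordering (the
model's reaction order is used throughout).

FBA optima are generically degenerate: many flux vectors attain the same
objective, so non-objective fluxes (lactate export, PDH at the ATP optimum)
depend on the vertex the solver returns.  ``resolve_degeneracy=True`` adds a
secondary LP that minimizes the sum of absolute fluxes subject to the
objective fixed at its optimum, yielding a reproducible, parsimonious flux
distribution.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from os import PathLike

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .core import LARGE_BOUND, MetabolicModel, ModelStructureError

#: |S·v| must not exceed this for a solution to count as mass balanced.
FEASIBILITY_TOL = 1e-6
#: LP optimality tolerance handed to HiGHS.
OPTIMALITY_TOL = 1e-9

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_UNBOUNDED = "unbounded"

_LINPROG_STATUS = {0: STATUS_OPTIMAL, 2: STATUS_INFEASIBLE, 3: STATUS_UNBOUNDED}


@dataclass
class StoichiometricSystem:
    """Sparse stoichiometric system S, Vmin, Vmax, c ready for the LP.

    Rows cover only non-boundary metabolites; species flagged as boundary
    have unconstrained accumulation and therefore no mass-balance row.
    """

    matrix: sp.csr_matrix
    row_index: list[str]
    col_index: list[str]
    lower: np.ndarray
    upper: np.ndarray
    objective_vector: np.ndarray
    #: full matrix including boundary-species rows, used for accumulation rates
    boundary_matrix: sp.csr_matrix = field(repr=False, default=None)
    boundary_index: list[str] = field(default_factory=list)


@dataclass
class FluxSolution:
    """An LP outcome: flux vector, objective value and solver status.

    ``accumulation`` reports the net production rate ẋ of each boundary
    metabolite (zero for internal metabolites by construction); for models
    following the single-sided exchange convention the flux of an exchange
    reaction itself is the accumulation rate of the exchanged species.
    """

    fluxes: dict[str, float]
    objective_value: float
    status: str
    accumulation: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == STATUS_OPTIMAL

    def flux_series(self) -> pd.Series:
        return pd.Series(self.fluxes, name="flux")

    def to_csv(self, path: str | PathLike) -> None:
        frame = self.flux_series().rename_axis("reaction").reset_index()
        frame.to_csv(path, index=False)

    def to_escher_json(self, path: str | PathLike) -> None:
        """Write the reaction→flux map consumed by Escher flux overlays."""
        with open(path, "w") as fh:
            json.dump(self.fluxes, fh, indent=1, sort_keys=True)


def build_system(model: MetabolicModel) -> StoichiometricSystem:
    """Assemble the sparse stoichiometric system from a model.

    Raises :class:`~oxflux.core.ModelStructureError` naming the reaction if a
    stoichiometry references an unknown metabolite.
    """
    internal = [m.id for m in model.metabolites if not m.is_boundary]
    boundary = [m.id for m in model.metabolites if m.is_boundary]
    row_of = {m: i for i, m in enumerate(internal)}
    brow_of = {m: i for i, m in enumerate(boundary)}
    cols = model.reaction_ids

    data, rows, col_ids = [], [], []
    bdata, brows, bcols = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            if met_id in row_of:
                rows.append(row_of[met_id])
                col_ids.append(j)
                data.append(coef)
            elif met_id in brow_of:
                brows.append(brow_of[met_id])
                bcols.append(j)
                bdata.append(coef)
            else:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )

    matrix = sp.csr_matrix(
        (data, (rows, col_ids)), shape=(len(internal), len(cols))
    )
    boundary_matrix = sp.csr_matrix(
        (bdata, (brows, bcols)), shape=(len(boundary), len(cols))
    )
    lower = np.array([r.lower_bound for r in model.reactions], dtype=float)
    upper = np.array([r.upper_bound for r in model.reactions], dtype=float)
    objective = np.zeros(len(cols))
    for rxn_id, coef in model.objective.items():
        objective[cols.index(rxn_id)] = coef
    return StoichiometricSystem(
        matrix=matrix,
        row_index=internal,
        col_index=cols,
        lower=lower,
        upper=upper,
        objective_vector=objective,
        boundary_matrix=boundary_matrix,
        boundary_index=boundary,
    )


def _solve_lp(c, A_eq, b_eq, bounds):
    return linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": OPTIMALITY_TOL,
                 "dual_feasibility_tolerance": OPTIMALITY_TOL},
    )


def solve_fba(
    system: StoichiometricSystem,
    direction: str = "maximize",
    resolve_degeneracy: bool = False,
) -> FluxSolution:
    """Solve the flux balance LP for an assembled system.

    With ``resolve_degeneracy`` a secondary LP minimizes Σ|v| at the fixed
    optimum (parsimonious flux distribution); the objective value is
    unchanged, only the reported vertex is.
    """
    if not np.any(system.objective_vector):
        raise ValueError("objective vector is all zero; nothing to optimize")
    sign = -1.0 if direction == "maximize" else 1.0
    n = len(system.col_index)
    bounds = list(zip(system.lower, system.upper))
    res = _solve_lp(
        sign * system.objective_vector,
        system.matrix,
        np.zeros(system.matrix.shape[0]),
        bounds,
    )
    status = _LINPROG_STATUS.get(res.status, STATUS_INFEASIBLE)
    if status != STATUS_OPTIMAL:
        return FluxSolution(fluxes={}, objective_value=np.nan, status=status)

    v = res.x
    opt = float(system.objective_vector @ v)
    if resolve_degeneracy:
        v = _l1_minimal_vertex(system, opt, direction)
        opt = float(system.objective_vector @ v)

    fluxes = dict(zip(system.col_index, map(float, v)))
    accumulation = {}
    if system.boundary_index:
        rates = system.boundary_matrix @ v
        accumulation = dict(zip(system.boundary_index, map(float, rates)))
    return FluxSolution(
        fluxes=fluxes,
        objective_value=opt,
        status=STATUS_OPTIMAL,
        accumulation=accumulation,
    )


def _l1_minimal_vertex(
    system: StoichiometricSystem, optimum: float, direction: str
) -> np.ndarray:
    """Minimize Σ|v| subject to S·v = 0, bounds, and c·v at the optimum.

    Standard split formulation: v = p − q with p, q ≥ 0 and Σ(p + q)
    minimized.  The optimum is held by an equality row on c·v.
    """
    n = len(system.col_index)
    m = system.matrix.shape[0]
    # variables [p; q], v = p - q
    A_parts = sp.hstack([system.matrix, -system.matrix])
    c_row = sp.csr_matrix(
        np.concatenate([system.objective_vector, -system.objective_vector])
    )
    A_eq = sp.vstack([A_parts, c_row]).tocsr()
    b_eq = np.concatenate([np.zeros(m), [optimum]])
    big = max(LARGE_BOUND, np.abs(system.lower).max(), np.abs(system.upper).max())
    var_bounds = [(0.0, big)] * (2 * n)
    # v bounds become inequalities p - q in [lower, upper]
    eye = sp.identity(n, format="csr")
    A_ub = sp.vstack([sp.hstack([eye, -eye]), sp.hstack([-eye, eye])]).tocsr()
    b_ub = np.concatenate([system.upper, -system.lower])
    res = linprog(
        np.ones(2 * n),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=var_bounds,
        method="highs",
    )
    if res.status != 0:
        warnings.warn(
            "degeneracy-resolving LP did not converge; returning plain vertex"
        )
        sign = -1.0 if direction == "maximize" else 1.0
        return _solve_lp(
            sign * system.objective_vector,
            system.matrix,
            np.zeros(m),
            list(zip(system.lower, system.upper)),
        ).x
    return res.x[:n] - res.x[n:]


def solve_model(
    model: MetabolicModel,
    direction: str = "maximize",
    resolve_degeneracy: bool = False,
) -> FluxSolution:
    """Convenience wrapper: build the system from a model and solve it."""
    return solve_fba(
        build_system(model), direction=direction, resolve_degeneracy=resolve_degeneracy
    )


def set_bounds(
    model: MetabolicModel, reaction_id: str, lower: float, upper: float
) -> MetabolicModel:
    """Return a copy of the model with one reaction's bounds replaced."""
    return model.with_reaction_bounds(reaction_id, lower, upper)


def max_flux(
    model: MetabolicModel, reaction_id: str, large_bound: float = LARGE_BOUND
) -> float:
    """Maximum attainable flux through one reaction (its flux capacity).

    Solves the LP with that single reaction as the objective.  An unbounded
    LP returns the configured large bound with a warning.
    """
    model.reaction(reaction_id)  # raise KeyError early
    system = build_system(model)
    j = system.col_index.index(reaction_id)
    obj = np.zeros(len(system.col_index))
    obj[j] = 1.0
    probe = StoichiometricSystem(
        matrix=system.matrix,
        row_index=system.row_index,
        col_index=system.col_index,
        lower=system.lower,
        upper=system.upper,
        objective_vector=obj,
        boundary_matrix=system.boundary_matrix,
        boundary_index=system.boundary_index,
    )
    sol = solve_fba(probe)
    if sol.status == STATUS_UNBOUNDED:
        warnings.warn(
            f"max flux of {reaction_id!r} is unbounded; returning {large_bound}"
        )
        return large_bound
    if not sol.optimal:
        raise RuntimeError(f"capacity LP for {reaction_id!r}: {sol.status}")
    return sol.objective_value
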