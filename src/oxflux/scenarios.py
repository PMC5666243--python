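"""Simulation protocols: condition presets, titrations, amino-acid relaxation.

Conditions encode environmental oxygen availability as the uptake bound of
the oxygen exchange reaction.  The normoxic uptake level is
19.8 µmol min⁻¹ gDW⁻¹; hypoxia is 10% of that, exposed as the explicit
preset value 1.9 µmol min⁻¹ gDW⁻¹ to match the level typically used in
experimental hypoxia studies; anoxia is 0.  Because exchanges carry uptake
as negative flux, a cap of ``U`` is imposed as lower bound ``−U``.

Two titration protocols are provided:

* ``oxygen_titration`` lowers the oxygen uptake cap from 100% to 0% of its
  normoxic level in 10% intervals, re-solving the ATP-maximization LP at
  each level and recording tracked fluxes (PDH, lactate and succinate
  exports by default when configured);
* ``pdh_titration`` first measures PDH's maximum flux capacity under a
  condition, then caps PDH from that capacity down to zero in 10% steps,
  recording the attainable ATP optimum.

Both emit a tidy :class:`ScanTable`.  Reported non-objective fluxes at an
ATP optimum are vertex-dependent (alternate optima); with
``resolve_degeneracy`` the scan records parsimonious (L1-minimal) fluxes in
additional ``*_l1`` columns so the caveat stays explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CATEGORY_BOUNDARY, LARGE_BOUND, MetabolicModel
from .fba import max_flux, solve_model

logger = logging.getLogger(__name__)

#: Oxygen uptake under normal conditions, µmol min⁻¹ gDW⁻¹.
NORMOXIC_OXYGEN_UPTAKE = 19.8
#: Hypoxic (10%) oxygen uptake as reported for the simulations.
HYPOXIC_OXYGEN_UPTAKE = 1.9

POLICY_AS_MODEL = "as_model"
POLICY_UNCONSTRAINED = "unconstrained"

#: Lower-cased names of the 20 proteinogenic amino acids, for the fallback
#: heuristic that identifies amino-acid exchange reactions by name.
PROTEINOGENIC_AMINO_ACIDS = (
    "alanine", "arginine", "asparagine", "aspartate", "cysteine",
    "glutamine", "glutamate", "glycine", "histidine", "isoleucine",
    "leucine", "lysine", "methionine", "phenylalanine", "proline",
    "serine", "threonine", "tryptophan", "tyrosine", "valine",
)


class ConfigurationError(ValueError):
    """A configured reaction id is missing from the model."""


@dataclass(frozen=True)
class ConditionSpec:
    """A named set of bound overrides defining a simulation condition."""

    name: str
    oxygen_uptake_cap: float
    amino_acid_policy: str = POLICY_AS_MODEL
    extra_overrides: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.oxygen_uptake_cap < 0:
            raise ValueError("oxygen uptake cap must be non-negative")
        if self.amino_acid_policy not in (POLICY_AS_MODEL, POLICY_UNCONSTRAINED):
            raise ValueError(f"unknown amino-acid policy {self.amino_acid_policy!r}")
        object.__setattr__(self, "extra_overrides", dict(self.extra_overrides))


NORMOXIA = ConditionSpec("Normoxia", NORMOXIC_OXYGEN_UPTAKE)
HYPOXIA = ConditionSpec("Hypoxia", HYPOXIC_OXYGEN_UPTAKE)
ANOXIA = ConditionSpec("Anoxia", 0.0)
NORMOXIA_AA = ConditionSpec(
    "NormoxiaAA", NORMOXIC_OXYGEN_UPTAKE, POLICY_UNCONSTRAINED
)
HYPOXIA_AA = ConditionSpec("HypoxiaAA", HYPOXIC_OXYGEN_UPTAKE, POLICY_UNCONSTRAINED)


@dataclass
class ScanTable:
    """Tidy record of a titration: one row per control-parameter level.

    ``frame`` columns: ``fraction`` (of the base cap, strictly decreasing
    from 1.0 to 0.0), ``cap`` (absolute flux bound), ``objective``,
    ``status`` and one column per tracked reaction (plus ``*_l1`` columns
    when degeneracy resolution is on).
    """

    control: str
    frame: pd.DataFrame

    def to_csv(self, path: str | PathLike) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def objectives(self) -> np.ndarray:
        return self.frame["objective"].to_numpy()

    @property
    def fractions(self) -> np.ndarray:
        return self.frame["fraction"].to_numpy()


def unconstrain_amino_acids(
    model: MetabolicModel,
    ids: Sequence[str],
    large_bound: float = LARGE_BOUND,
) -> MetabolicModel:
    """Raise the uptake capacity of the listed exchange reactions.

    In the uptake-negative sign convention, "increasing the upper uptake
    bound" means lowering each exchange's lower bound to ``−large_bound``.
    Non-boundary or unknown ids raise a validation error listing them.
    """
    bad = [
        rid for rid in ids
        if not model.has_reaction(rid)
        or model.reaction_category(rid) != CATEGORY_BOUNDARY
    ]
    if bad:
        raise ValueError(
            f"not boundary (exchange) reactions of this model: {bad}"
        )
    out = model
    for rid in ids:
        out = out.with_reaction_bounds(
            rid, -large_bound, out.reaction(rid).upper_bound
        )
    return out


def find_amino_acid_exchanges(model: MetabolicModel) -> list[str]:
    """Heuristic: boundary reactions whose name mentions an amino acid.

    A fallback for models that do not come with a configured amino-acid
    exchange list; every use is logged because name matching can both miss
    and over-match.
    """
    hits = []
    for rid in model.boundary_reactions():
        rxn = model.reaction(rid)
        text = " ".join(
            [rxn.name.lower(), rxn.id.lower()]
            + [model.metabolite(m).name.lower() for m in rxn.stoichiometry]
        )
        if any(aa in text for aa in PROTEINOGENIC_AMINO_ACIDS):
            hits.append(rid)
    logger.warning(
        "amino-acid exchange heuristic matched %d boundary reactions: %s",
        len(hits), hits,
    )
    return hits


def apply_condition(
    model: MetabolicModel,
    spec: ConditionSpec,
    oxygen_id: str,
    amino_acid_ids: Sequence[str] | None = None,
    large_bound: float = LARGE_BOUND,
) -> MetabolicModel:
    """Return a copy of the model with a condition's bounds imposed.

    The oxygen exchange's uptake is capped at ``spec.oxygen_uptake_cap``;
    under the unconstrained amino-acid policy every configured amino-acid
    uptake is raised to the large bound (falling back to the name heuristic
    when no list is given); ``extra_overrides`` are applied last.  The
    operation is idempotent and side-effect free.
    """
    if not model.has_reaction(oxygen_id):
        raise ConfigurationError(
            f"configured oxygen exchange {oxygen_id!r} not in model"
        )
    out = model.with_reaction_bounds(
        oxygen_id, -spec.oxygen_uptake_cap, model.reaction(oxygen_id).upper_bound
    )
    if spec.amino_acid_policy == POLICY_UNCONSTRAINED:
        ids = (
            list(amino_acid_ids)
            if amino_acid_ids is not None
            else find_amino_acid_exchanges(out)
        )
        out = unconstrain_amino_acids(out, ids, large_bound=large_bound)
    for rid, (lo, hi) in spec.extra_overrides.items():
        out = out.with_reaction_bounds(rid, lo, hi)
    return out


def _fraction_grid(steps: int) -> np.ndarray:
    # both endpoints included: 1.0, 0.9, ..., 0.0 for steps=10
    return np.linspace(1.0, 0.0, steps + 1)


def _scan_rows(
    models: Iterable[tuple[float, float, MetabolicModel]],
    track: Sequence[str],
    resolve_degeneracy: bool,
) -> pd.DataFrame:
    rows = []
    for fraction, cap, cond in models:
        row: dict[str, object] = {"fraction": fraction, "cap": cap}
        sol = solve_model(cond)
        row["objective"] = sol.objective_value
        row["status"] = sol.status
        for rid in track:
            row[rid] = sol.fluxes.get(rid, np.nan)
        if resolve_degeneracy and sol.optimal:
            l1 = solve_model(cond, resolve_degeneracy=True)
            for rid in track:
                row[f"{rid}_l1"] = l1.fluxes.get(rid, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def oxygen_titration(
    model: MetabolicModel,
    oxygen_id: str,
    base_cap: float = NORMOXIC_OXYGEN_UPTAKE,
    steps: int = 10,
    track: Sequence[str] = (),
    resolve_degeneracy: bool = False,
) -> ScanTable:
    """Scan the oxygen uptake cap from ``base_cap`` down to zero.

    Eleven levels at fractions 1.0, 0.9, …, 0.0 by default; each row records
    the ATP-maximal objective and the tracked reaction fluxes.  Infeasible
    levels are recorded with their status and the scan continues.
    """
    if base_cap <= 0:
        raise ValueError("base_cap must be positive")
    for rid in track:
        model.reaction(rid)  # raise KeyError early
    if not model.has_reaction(oxygen_id):
        raise ConfigurationError(
            f"configured oxygen exchange {oxygen_id!r} not in model"
        )
    upper = model.reaction(oxygen_id).upper_bound

    def conditions():
        for fraction in _fraction_grid(steps):
            cap = base_cap * fraction
            yield fraction, cap, model.with_reaction_bounds(oxygen_id, -cap, upper)

    frame = _scan_rows(conditions(), track, resolve_degeneracy)
    return ScanTable(control="oxygen_fraction", frame=frame)


def pdh_titration(
    model: MetabolicModel,
    spec: ConditionSpec,
    pdh_id: str,
    oxygen_id: str,
    amino_acid_ids: Sequence[str] | None = None,
    steps: int = 10,
    track: Sequence[str] = (),
    resolve_degeneracy: bool = False,
    capacity_tol: float = 1e-9,
) -> ScanTable:
    """Scan PDH activity from its maximum flux capacity down to zero.

    The condition is applied first, PDH's capacity is measured with a
    dedicated LP, then PDH's upper bound is capped at 100%, 90%, …, 0% of
    that capacity while the ATP objective is re-optimized.  A condition
    under which PDH can carry no flux yields a degenerate single-row table
    with a warning.
    """
    cond = apply_condition(model, spec, oxygen_id, amino_acid_ids)
    if not cond.has_reaction(pdh_id):
        raise ConfigurationError(f"configured PDH reaction {pdh_id!r} not in model")
    capacity = max_flux(cond, pdh_id)
    if capacity <= capacity_tol:
        logger.warning(
            "PDH capacity is zero under condition %s; titration degenerate",
            spec.name,
        )
        sol = solve_model(cond)
        frame = pd.DataFrame(
            [{
                "fraction": 1.0,
                "cap": 0.0,
                "objective": sol.objective_value,
                "status": sol.status,
                **{rid: sol.fluxes.get(rid, np.nan) for rid in track},
            }]
        )
        return ScanTable(control="pdh_fraction", frame=frame)

    lb = cond.reaction(pdh_id).lower_bound

    def conditions():
        for fraction in _fraction_grid(steps):
            cap = capacity * fraction
            yield fraction, cap, cond.with_reaction_bounds(pdh_id, min(lb, cap), cap)

    frame = _scan_rows(conditions(), track, resolve_degeneracy)
    return ScanTable(control="pdh_fraction", frame=frame)
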