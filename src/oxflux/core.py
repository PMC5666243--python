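"""Core domain types for compartmentalized constraint-based metabolic models.

A :class:`MetabolicModel` is the in-memory container shared by every stage of
the pipeline: it holds the stoichiometry (columns of the matrix ``S``), the
flux bounds ``Vmin``/``Vmax`` and the linear objective vector ``c``.  All flux
bounds are in µmol min⁻¹ gDW⁻¹ and are never rescaled on I/O.

Reactions are classified into three mutually exclusive categories:

``boundary``
    the reaction exchanges matter with the environment — it either touches a
    species flagged ``is_boundary`` (exempt from the steady-state constraint)
    or has species on only one side (pure source/sink, e.g. ``atp_c →``);
``transport``
    it moves at least one chemical entity between two distinct compartments
    and is not boundary;
``internal``
    everything else.

The exchange sign convention is fixed throughout the package: a boundary
reaction is written ``metabolite →`` so that positive flux means export or
accumulation and negative flux means uptake; an uptake cap of ``U`` is imposed
as lower bound ``−U``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

#: Default "large bound" for unconstrained flux directions, µmol min⁻¹ gDW⁻¹.
LARGE_BOUND = 1000.0

CATEGORY_BOUNDARY = "boundary"
CATEGORY_TRANSPORT = "transport"
CATEGORY_INTERNAL = "internal"


class ModelStructureError(ValueError):
    """A model violates a structural invariant (bad reference, bad bounds)."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species located in one compartment.

    ``is_boundary`` species are exempt from the steady-state constraint
    (their net accumulation rate is unconstrained), mirroring the SBML
    ``boundaryCondition`` attribute.
    """

    id: str
    name: str = ""
    compartment: str = ""
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelStructureError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed, positive = produced).  Zero coefficients are rejected rather
    than silently stored.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = LARGE_BOUND
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelStructureError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelStructureError(f"reaction {self.id!r}: empty stoichiometry")
        if any(coef == 0 for coef in self.stoichiometry.values()):
            raise ModelStructureError(
                f"reaction {self.id!r}: zero stoichiometric coefficient stored"
            )
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def reactants(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicModel:
    """A compartmentalized reaction network with bounds and objective.

    ``objective`` maps reaction ids to coefficients of the vector ``c``;
    reactions not listed carry coefficient zero.
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def compartments(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.metabolites:
            if m.compartment and m.compartment not in seen:
                seen[m.compartment] = None
        return list(seen)

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite id {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction id {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        met_index: dict[str, Metabolite] = {}
        for m in self.metabolites:
            if m.id in met_index:
                raise ModelStructureError(f"duplicate metabolite id {m.id!r}")
            met_index[m.id] = m
        rxn_index: dict[str, Reaction] = {}
        for r in self.reactions:
            if r.id in rxn_index:
                raise ModelStructureError(f"duplicate reaction id {r.id!r}")
            rxn_index[r.id] = r
            for met_id in r.stoichiometry:
                if met_id not in met_index:
                    raise ModelStructureError(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
        for rxn_id in self.objective:
            if rxn_id not in rxn_index:
                raise ModelStructureError(
                    f"objective references unknown reaction {rxn_id!r}"
                )
        self._met_index = met_index
        self._rxn_index = rxn_index

    # -- classification ----------------------------------------------------

    def reaction_category(self, rxn_id: str) -> str:
        """Classify one reaction as boundary, transport or internal.

        Boundary detection precedence: a reaction touching a species flagged
        ``is_boundary`` is boundary, then single-sided stoichiometry; a
        non-boundary reaction spanning two or more compartments is transport.
        """
        rxn = self.reaction(rxn_id)
        touches_boundary = any(
            self.metabolite(m).is_boundary for m in rxn.stoichiometry
        )
        single_sided = not rxn.reactants or not rxn.products
        if touches_boundary or single_sided:
            return CATEGORY_BOUNDARY
        compartments = {self.metabolite(m).compartment for m in rxn.stoichiometry}
        if len(compartments) > 1:
            return CATEGORY_TRANSPORT
        return CATEGORY_INTERNAL

    def reactions_by_category(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {
            CATEGORY_BOUNDARY: [],
            CATEGORY_TRANSPORT: [],
            CATEGORY_INTERNAL: [],
        }
        for r in self.reactions:
            out[self.reaction_category(r.id)].append(r.id)
        return out

    def boundary_reactions(self) -> list[str]:
        return self.reactions_by_category()[CATEGORY_BOUNDARY]

    # -- functional updates ------------------------------------------------

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def with_reaction_bounds(
        self, rxn_id: str, lower: float, upper: float
    ) -> "MetabolicModel":
        """Return a copy with one reaction's bounds replaced.

        Scenario construction is side-effect free: the receiver is never
        mutated.
        """
        if lower > upper:
            raise ModelStructureError(
                f"reaction {rxn_id!r}: lower bound {lower} exceeds upper {upper}"
            )
        self.reaction(rxn_id)  # raise KeyError early
        new = self.copy()
        new.reactions = [
            replace(r, lower_bound=lower, upper_bound=upper) if r.id == rxn_id else r
            for r in new.reactions
        ]
        new.validate()
        return new


def model_summary(model: MetabolicModel) -> dict:
    """Composition summary: reaction/metabolite counts and the category split.

    The three category counts always partition the reaction set, so
    ``n_boundary + n_transport + n_internal == n_reactions``.
    """
    cats = model.reactions_by_category()
    return {
        "n_reactions": len(model.reactions),
        "n_metabolites": len(model.metabolites),
        "n_boundary": len(cats[CATEGORY_BOUNDARY]),
        "n_transport": len(cats[CATEGORY_TRANSPORT]),
        "n_internal": len(cats[CATEGORY_INTERNAL]),
        "compartments": model.compartments,
    }


def _as_id_list(ids: Iterable[str]) -> list[str]:
    return list(ids)
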