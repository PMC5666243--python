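"""Synthetic core-carbon network with a closed-form ATP optimum.

The generator builds a three-compartment (extracellular, cytosol,
mitochondrial matrix) caricature of central energy metabolism: lumped
glycolysis, lactate fermentation, pyruvate dehydrogenase (PDH), a lumped TCA
cycle, the malate–aspartate shuttle and a two-entry electron transport chain
with P/O ratios 2.5 (NADH) and 1.5 (FADH2).  Adenine nucleotides are not
tracked and mitochondrial ATP is pooled with cytosolic ATP (the adenine
translocase is assumed non-limiting), so the ATP demand is a single-sided
sink and the classifier counts it among the boundary reactions.

With glucose uptake cap ``g`` and oxygen uptake cap ``q`` the maximal ATP
production of the minimal variant has the closed form

    ATP(g, q) = 2·g + 15·min(2·g, q/3),

because each pyruvate routed through PDH yields 5 mitochondrial NADH
(1 shuttle + 1 PDH + 3 TCA), 1 FADH2 and 1 substrate-level ATP — 15 ATP at
P/O (2.5, 1.5) — and consumes 3 O2 (six half-O2 reductions), while pyruvate
supply is 2 per glucose.  Pyruvate not oxidized leaves as lactate:
lactate export = 2·g − min(2·g, q/3).

The ``succinate`` variant splits the TCA lump in two so that partial
oxidation to exportable succinate becomes possible; succinate yields more
ATP per O2 (11 ATP / 2 O2) but less per pyruvate (11 vs 15), so the LP
exports succinate exactly when oxygen, not carbon, is limiting — the toy
analogue of hypoxic succinate accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LARGE_BOUND, MetabolicModel, Metabolite, Reaction
from .fba import solve_model

#: Reaction ids of the toy network the scenario protocols need to know.
GLUCOSE_EXCHANGE = "EX_glc"
OXYGEN_EXCHANGE = "EX_o2"
LACTATE_EXCHANGE = "EX_lac"
SUCCINATE_EXCHANGE = "EX_succ"
PDH_REACTION = "PDH"
ATP_DEMAND = "ATPASE"


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of the generated network.

    ``glucose_uptake_cap`` and ``oxygen_uptake_cap`` are the environmental
    bounds (µmol min⁻¹ gDW⁻¹); the P/O ratios are ATP per reducing
    equivalent oxidized by the respiratory chain (modern consensus 2.5 for
    NADH, 1.5 for FADH2, making the aerobic yield exactly 32 ATP/glucose).
    """

    variant: str = "minimal"
    glucose_uptake_cap: float = 1.0
    oxygen_uptake_cap: float = 6.0
    p_o_nadh: float = 2.5
    p_o_fadh2: float = 1.5

    def __post_init__(self) -> None:
        if self.variant not in ("minimal", "succinate"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.glucose_uptake_cap < 0 or self.oxygen_uptake_cap < 0:
            raise ValueError("uptake caps must be non-negative")
        if self.p_o_nadh <= 0 or self.p_o_fadh2 <= 0:
            raise ValueError("P/O ratios must be positive")


def build_toy_model(spec: ToyModelSpec = ToyModelSpec()) -> MetabolicModel:
    """Construct the toy network as a :class:`MetabolicModel`.

    Exchanges follow the package-wide sign convention (single-sided,
    positive flux = export, uptake cap as negative lower bound); the
    objective is the cytosolic ATP demand.
    """
    B = LARGE_BOUND
    mets = [
        Metabolite("glc_e", "glucose", "e"),
        Metabolite("glc_c", "glucose", "c"),
        Metabolite("pyr_c", "pyruvate", "c"),
        Metabolite("lac_c", "lactate", "c"),
        Metabolite("lac_e", "lactate", "e", is_boundary=True),
        Metabolite("pyr_m", "pyruvate", "m"),
        Metabolite("accoa_m", "acetyl-CoA", "m"),
        Metabolite("o2_c", "oxygen", "c"),
        Metabolite("co2_c", "carbon dioxide", "c"),
        Metabolite("nad_c", "NAD+", "c"),
        Metabolite("nadh_c", "NADH", "c"),
        Metabolite("nad_m", "NAD+", "m"),
        Metabolite("nadh_m", "NADH", "m"),
        Metabolite("fad_m", "FAD", "m"),
        Metabolite("fadh2_m", "FADH2", "m"),
        Metabolite("atp_c", "ATP", "c"),
    ]
    g, q = spec.glucose_uptake_cap, spec.oxygen_uptake_cap
    pn, pf = spec.p_o_nadh, spec.p_o_fadh2
    rxns = [
        Reaction(GLUCOSE_EXCHANGE, {"glc_e": -1.0}, -g, 0.0, name="glucose exchange"),
        Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, 0, B, name="glucose transport"),
        Reaction(
            "GLYC",
            {"glc_c": -1, "nad_c": -2, "pyr_c": 2, "nadh_c": 2, "atp_c": 2},
            0, B, name="glycolysis (lumped)",
        ),
        Reaction(
            "LDH",
            {"pyr_c": -1, "nadh_c": -1, "nad_c": 1, "lac_c": 1},
            0, B, name="lactate dehydrogenase",
        ),
        # lac_e is a boundary species, so this export is a boundary reaction
        # and its flux is the lactate accumulation rate
        Reaction(LACTATE_EXCHANGE, {"lac_c": -1, "lac_e": 1}, 0, B,
                 name="lactate exchange"),
        Reaction("PYRt", {"pyr_c": -1, "pyr_m": 1}, 0, B, name="pyruvate transport"),
        Reaction(
            PDH_REACTION,
            {"pyr_m": -1, "nad_m": -1, "accoa_m": 1, "nadh_m": 1, "co2_c": 1},
            0, B, name="pyruvate dehydrogenase",
        ),
        Reaction(
            "SHUTTLE",
            {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1},
            0, B, name="malate-aspartate shuttle (lumped)",
        ),
        Reaction(
            "ETC1",
            {"nadh_m": -1, "o2_c": -0.5, "nad_m": 1, "atp_c": pn},
            0, B, name="electron transport, NADH entry",
        ),
        Reaction(
            "ETC2",
            {"fadh2_m": -1, "o2_c": -0.5, "fad_m": 1, "atp_c": pf},
            0, B, name="electron transport, FADH2 entry",
        ),
        Reaction(ATP_DEMAND, {"atp_c": -1.0}, 0, B, name="ATP demand"),
        Reaction(OXYGEN_EXCHANGE, {"o2_c": -1.0}, -q, 0.0, name="oxygen exchange"),
        Reaction("EX_co2", {"co2_c": -1.0}, 0, B, name="CO2 exchange"),
    ]
    if spec.variant == "minimal":
        rxns.insert(
            7,
            Reaction(
                "TCA",
                {"accoa_m": -1, "nad_m": -3, "fad_m": -1,
                 "nadh_m": 3, "fadh2_m": 1, "atp_c": 1, "co2_c": 2},
                0, B, name="TCA cycle (lumped)",
            ),
        )
    else:
        mets.extend([
            Metabolite("succ_m", "succinate", "m"),
            Metabolite("succ_e", "succinate", "e", is_boundary=True),
        ])
        rxns.insert(
            7,
            Reaction(
                "TCA1",
                {"accoa_m": -1, "nad_m": -2,
                 "succ_m": 1, "nadh_m": 2, "atp_c": 1, "co2_c": 2},
                0, B, name="TCA cycle, acetyl-CoA to succinate",
            ),
        )
        rxns.insert(
            8,
            Reaction(
                "TCA2",
                {"succ_m": -1, "fad_m": -1, "nad_m": -1,
                 "fadh2_m": 1, "nadh_m": 1},
                0, B, name="TCA cycle, succinate oxidation (lumped)",
            ),
        )
        rxns.append(
            Reaction(SUCCINATE_EXCHANGE, {"succ_m": -1, "succ_e": 1}, 0, B,
                     name="succinate exchange")
        )
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        objective={ATP_DEMAND: 1.0},
        notes=f"toy core-carbon model ({spec.variant} variant)",
    )


def analytic_atp_yield(g: float, q: float) -> float:
    """Closed-form ATP optimum of the minimal variant at default P/O ratios.

    ``2g + 15·min(2g, q/3)``: glycolytic substrate-level ATP plus 15 ATP per
    pyruvate fully oxidized, oxygen allowing one pyruvate per 3 O2.
    """
    if g < 0 or q < 0:
        raise ValueError("uptake caps must be non-negative")
    return 2.0 * g + 15.0 * min(2.0 * g, q / 3.0)


def analytic_lactate_export(g: float, q: float) -> float:
    """Lactate export at the ATP optimum of the minimal variant."""
    if g < 0 or q < 0:
        raise ValueError("uptake caps must be non-negative")
    return 2.0 * g - min(2.0 * g, q / 3.0)


def analytic_atp_yield_succinate(g: float, q: float) -> float:
    """Closed-form ATP optimum of the succinate variant.

    Full oxidation gives 15 ATP / 3 O2 per pyruvate, partial oxidation to
    exported succinate 11 ATP / 2 O2; the LP mixes the two along the carbon
    and oxygen constraints, giving the piecewise form
    ``2g + 11q/2`` (q ≤ 4g), ``8g + 4q`` (4g ≤ q ≤ 6g), ``32g`` (q ≥ 6g).
    """
    if g < 0 or q < 0:
        raise ValueError("uptake caps must be non-negative")
    if q <= 4 * g:
        return 2 * g + 5.5 * q
    if q <= 6 * g:
        return 8 * g + 4 * q
    return 32 * g


def sample_condition_fluxes(
    spec: ToyModelSpec = ToyModelSpec(),
    oxygen_fractions: tuple[float, ...] = (1.0, 0.1, 0.0),
    seed: int = 0,
    noise_sd: float = 0.0,
    condition_names: list[str] | None = None,
) -> pd.DataFrame:
    """Flux table (reactions × conditions) across oxygen availabilities.

    Each condition solves the toy model with the oxygen cap scaled to a
    fraction of ``spec.oxygen_uptake_cap``, using the degeneracy-resolving
    (parsimonious) solve so columns are reproducible.  ``noise_sd`` applies
    multiplicative Gaussian noise to nonzero fluxes, emulating measurement
    scatter; with ``noise_sd=0`` the table is exactly deterministic.
    """
    if any(f < 0 or f > 1 for f in oxygen_fractions):
        raise ValueError("oxygen fractions must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    columns = {}
    names = condition_names or [f"O2_{f:g}" for f in oxygen_fractions]
    if len(names) != len(oxygen_fractions):
        raise ValueError("one condition name per oxygen fraction required")
    base = build_toy_model(spec)
    for name, frac in zip(names, oxygen_fractions):
        cond = base.with_reaction_bounds(
            OXYGEN_EXCHANGE, -spec.oxygen_uptake_cap * frac, 0.0
        )
        sol = solve_model(cond, resolve_degeneracy=True)
        if not sol.optimal:
            raise RuntimeError(f"toy model infeasible at oxygen fraction {frac}")
        col = sol.flux_series()
        if noise_sd > 0:
            factors = rng.normal(1.0, noise_sd, size=len(col))
            col = col * np.where(col.to_numpy() != 0, factors, 1.0)
        columns[name] = col
    return pd.DataFrame(columns)
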