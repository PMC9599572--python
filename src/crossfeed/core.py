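"""Stoichiometric models and flux balance analysis (FBA).

A metabolic model is a set of metabolites (cytosolic or extracellular) and
reactions with flux bounds in mmol·gDW⁻¹·h⁻¹.  FBA maximises the flux through
the biomass pseudo-reaction subject to steady state (S·v = 0) and bounds,
solved as a linear program.  Growth media are expressed as uptake ceilings on
exchange reactions: an exchange carries a single extracellular metabolite out
of the system (stoichiometry {met: -1}), so uptake is a *negative* flux and a
medium opens uptake by lowering the exchange's lower bound.

Biomass yields are reported in gDW produced per mmol of the focal carbon
source consumed, the quantity used throughout the niche analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: Flux bound used for "open" reactions (mmol·gDW⁻¹·h⁻¹).
DEFAULT_BOUND = 1000.0

#: Default uptake ceiling for the focal carbon source (mmol·gDW⁻¹·h⁻¹).
#: One uniform bound for every substrate mirrors panels standardised by
#: substrate molarity rather than by carbon mass.
DEFAULT_CARBON_UPTAKE = 10.0

#: Biomass flux above which a model is called "growing".  Separates LP
#: solutions from numerical noise; yields on realistic bounds are orders of
#: magnitude above it.
GROWTH_THRESHOLD = 1e-6

#: Steady-state / solver tolerance.
LP_TOLERANCE = 1e-9

COMPARTMENTS = ("cytosol", "extracellular")
REACTION_KINDS = ("internal", "transport", "exchange", "biomass")


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class YieldInvariantError(RuntimeError):
    """Positive biomass with zero carbon uptake: carbon from nowhere."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    carbon_atoms: int | None = None

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )
        if self.carbon_atoms is not None and self.carbon_atoms < 0:
            raise ModelValidationError(
                f"metabolite {self.id!r}: negative carbon_atoms"
            )


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction; negative coefficients are consumed."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    genes: frozenset[str] = field(default_factory=frozenset)
    kind: str = "internal"

    def __post_init__(self):
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(
                f"reaction {self.id!r}: kind {self.kind!r} not in {REACTION_KINDS}"
            )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound > upper_bound"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class StoichiometricModel:
    """One species' (or one community's) metabolic network.

    ``biomass_id`` names the primary biomass reaction.  Single-species models
    carry exactly one biomass-kind reaction; mixed-bag community models retain
    every member's biomass reaction and the FBA objective is their sum.
    """

    species_id: str
    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    biomass_id: str

    def validate(self) -> None:
        for mid, met in self.metabolites.items():
            if mid != met.id:
                raise ModelValidationError(f"metabolite key {mid!r} != id {met.id!r}")
        biomass_ids = []
        for rid, rxn in self.reactions.items():
            if rid != rxn.id:
                raise ModelValidationError(f"reaction key {rid!r} != id {rxn.id!r}")
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelValidationError(
                        f"reaction {rid!r} references unknown metabolite {mid!r}"
                    )
            if rxn.kind == "exchange":
                if len(rxn.stoichiometry) != 1:
                    raise ModelValidationError(
                        f"exchange {rid!r} must touch exactly one metabolite"
                    )
                (mid,) = rxn.stoichiometry
                if self.metabolites[mid].compartment != "extracellular":
                    raise ModelValidationError(
                        f"exchange {rid!r} metabolite {mid!r} is not extracellular"
                    )
            if rxn.kind == "biomass":
                biomass_ids.append(rid)
        if not biomass_ids:
            raise ModelValidationError(
                f"model {self.species_id!r} has no biomass reaction"
            )
        if self.biomass_id not in self.reactions:
            raise ModelValidationError(
                f"biomass_id {self.biomass_id!r} not among reactions"
            )
        if self.reactions[self.biomass_id].kind != "biomass":
            raise ModelValidationError(
                f"biomass_id {self.biomass_id!r} is not a biomass-kind reaction"
            )

    @property
    def biomass_reaction_ids(self) -> list[str]:
        return sorted(r.id for r in self.reactions.values() if r.kind == "biomass")

    def exchange_for(self, metabolite_id: str) -> str | None:
        """Id of the exchange reaction carrying ``metabolite_id``.

        Accepts either the full extracellular metabolite id or the bare
        compound name (``glucose`` resolves to ``glucose_e``).
        """
        accepted = {metabolite_id, f"{metabolite_id}_e"}
        for rid in sorted(self.reactions):
            rxn = self.reactions[rid]
            if rxn.kind == "exchange" and accepted & set(rxn.stoichiometry):
                return rxn.id
        return None

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            species_id=self.species_id,
            metabolites=dict(self.metabolites),
            reactions=dict(self.reactions),
            biomass_id=self.biomass_id,
        )


@dataclass(frozen=True)
class MediumSpec:
    """A minimal medium: base nutrients plus one focal carbon source.

    ``base_nutrients`` maps exchange-reaction ids to maximum uptake rates for
    carbon-free nutrients (ammonium, phosphate, sulfate, water, trace).  The
    focal carbon source is named by metabolite id and capped separately.
    """

    carbon_source: str
    carbon_uptake_max: float = DEFAULT_CARBON_UPTAKE
    base_nutrients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.carbon_uptake_max <= 0:
            raise ValueError("carbon_uptake_max must be > 0")
        for ex_id, up in self.base_nutrients.items():
            if up < 0:
                raise ValueError(f"negative uptake for base nutrient {ex_id!r}")


@dataclass
class FBAResult:
    status: str  # optimal | infeasible | unbounded
    objective: float
    fluxes: dict[str, float]


def apply_medium(model: StoichiometricModel, medium: MediumSpec) -> StoichiometricModel:
    """Return a copy of ``model`` with exchange bounds set by ``medium``.

    Every exchange not named by the medium is closed for uptake (lower bound
    0); secretion stays open.  The focal carbon source's exchange, if present,
    is opened down to ``-carbon_uptake_max``.
    """
    carbon_ex = model.exchange_for(medium.carbon_source)
    out = model.copy()
    for rid, rxn in model.reactions.items():
        if rxn.kind != "exchange":
            continue
        if rid == carbon_ex:
            lb = -medium.carbon_uptake_max
        elif rid in medium.base_nutrients:
            lb = -medium.base_nutrients[rid]
        else:
            lb = 0.0
        out.reactions[rid] = replace(rxn, lower_bound=lb,
                                     upper_bound=max(rxn.upper_bound, 0.0))
    return out


def _lp_arrays(model: StoichiometricModel):
    rxn_ids = sorted(model.reactions)
    met_ids = sorted(model.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.empty(len(rxn_ids))
    ub = np.empty(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        lb[j] = rxn.lower_bound
        ub[j] = rxn.upper_bound
        for mid, coef in rxn.stoichiometry.items():
            S[met_index[mid], j] = coef
    return rxn_ids, S, lb, ub


def run_fba(model: StoichiometricModel, medium: MediumSpec) -> FBAResult:
    """Maximise total biomass flux at steady state under ``medium``.

    Returns objective 0 (flagged via ``status``) when the LP is infeasible.
    """
    model.validate()
    constrained = apply_medium(model, medium)
    rxn_ids, S, lb, ub = _lp_arrays(constrained)
    c = np.zeros(len(rxn_ids))
    for bid in constrained.biomass_reaction_ids:
        c[rxn_ids.index(bid)] = -1.0  # linprog minimises
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOLERANCE,
                 "dual_feasibility_tolerance": LP_TOLERANCE},
    )
    if res.status == 2:
        logger.warning("FBA infeasible for %s on %s",
                       model.species_id, medium.carbon_source)
        return FBAResult("infeasible", 0.0, {})
    if res.status == 3:
        return FBAResult("unbounded", math.inf, {})
    if not res.success:  # pragma: no cover - solver edge cases
        raise RuntimeError(f"LP solver failure: {res.message}")
    fluxes = dict(zip(rxn_ids, res.x))
    objective = max(0.0, -res.fun)
    return FBAResult("optimal", objective, fluxes)


def biomass_yield(model: StoichiometricModel, medium: MediumSpec,
                  tol: float = 1e-9) -> float:
    """Biomass produced per mmol of the focal carbon source consumed.

    Zero when the model takes up no carbon.  Raises ``YieldInvariantError``
    if biomass is produced while carbon uptake is zero, which would mean the
    model creates carbon from nothing.
    """
    result = run_fba(model, medium)
    if result.status != "optimal":
        return 0.0
    carbon_ex = model.exchange_for(medium.carbon_source)
    uptake = -result.fluxes.get(carbon_ex, 0.0) if carbon_ex else 0.0
    if uptake <= tol:
        if result.objective > GROWTH_THRESHOLD:
            raise YieldInvariantError(
                f"{model.species_id}: biomass {result.objective:g} with zero "
                f"uptake of {medium.carbon_source}"
            )
        return 0.0
    return result.objective / uptake


def predicts_growth(model: StoichiometricModel, medium: MediumSpec,
                    threshold: float = GROWTH_THRESHOLD) -> bool:
    """True iff optimal biomass flux strictly exceeds ``threshold``."""
    if threshold <= 0:
        raise ValueError("growth threshold must be > 0")
    result = run_fba(model, medium)
    if result.status == "infeasible":
        logger.info("infeasible FBA counted as no growth (%s on %s)",
                    model.species_id, medium.carbon_source)
        return False
    return result.objective > threshold
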