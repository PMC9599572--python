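"""Phenotype-guided gapfilling and mixed-bag community models.

Draft metabolic models often miss reactions and therefore fail to grow on
substrates the organism demonstrably uses.  Gapfilling repairs each such
false negative by adding a cardinality-minimal set of reactions drawn from a
universal reaction database, solved here as a mixed-integer program (one
binary indicator per candidate reaction, minimise the count subject to a
positive biomass flux).  Gapfilling only ever adds reactions: observed
*no-growth* phenotypes are never enforced, and any residual false growth is
recorded in the report rather than repaired away.

A mixed-bag community model pools every member's metabolites and reactions
into one shared compartment pair with no species boundaries; its objective is
the summed biomass flux of all members, so the community "grows" on a carbon
source as soon as any combination of pooled reactions can produce biomass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .core import (
    GROWTH_THRESHOLD,
    MediumSpec,
    Reaction,
    StoichiometricModel,
    apply_medium,
    predicts_growth,
)

logger = logging.getLogger(__name__)

GROWTH, NO_GROWTH, UNTESTED = "growth", "no_growth", "untested"

#: Minimum biomass flux a gapfilled model must reach on a positive medium.
#: Well above GROWTH_THRESHOLD so repaired growth is unambiguous.
GAPFILL_MIN_BIOMASS = 1e-3


class ReactionCollisionError(ValueError):
    """Same reaction id with conflicting stoichiometry."""


@dataclass
class UniversalReactionSet:
    """Donor database of candidate reactions for gapfilling."""

    reactions: dict[str, Reaction]
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, rxn: Reaction, provenance: str = "") -> None:
        existing = self.reactions.get(rxn.id)
        if existing is not None:
            if existing.stoichiometry != rxn.stoichiometry:
                raise ReactionCollisionError(
                    f"universal set id collision on {rxn.id!r}"
                )
            # identical chemistry from another donor: keep the widest bounds
            self.reactions[rxn.id] = Reaction(
                id=rxn.id,
                stoichiometry=existing.stoichiometry,
                lower_bound=min(existing.lower_bound, rxn.lower_bound),
                upper_bound=max(existing.upper_bound, rxn.upper_bound),
                genes=existing.genes | rxn.genes,
                kind=existing.kind,
            )
        else:
            self.reactions[rxn.id] = rxn
            if provenance:
                self.provenance[rxn.id] = provenance


@dataclass
class GrowthPhenotypeMatrix:
    """Observed growth calls per (species, carbon source) pair."""

    entries: dict[tuple[str, str], str]

    def __post_init__(self):
        for key, value in self.entries.items():
            if value not in (GROWTH, NO_GROWTH, UNTESTED):
                raise ValueError(f"bad phenotype {value!r} for {key}")

    def phenotype(self, species_id: str, carbon_source: str) -> str:
        return self.entries.get((species_id, carbon_source), UNTESTED)

    def positives_for(self, species_id: str) -> list[str]:
        return sorted(c for (s, c), v in self.entries.items()
                      if s == species_id and v == GROWTH)


@dataclass
class GapfillReport:
    species_id: str
    added_reaction_ids: list[str] = field(default_factory=list)
    #: carbon source -> "growing" | "gapfilled" | "unresolvable"
    resolution: dict[str, str] = field(default_factory=dict)
    #: negative phenotypes on which the (gapfilled) model still grows
    false_growth: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "added_reaction_ids": list(self.added_reaction_ids),
            "resolution": dict(self.resolution),
            "false_growth": list(self.false_growth),
        }


def _with_reactions(model: StoichiometricModel,
                    extra: list[Reaction],
                    universe_mets) -> StoichiometricModel:
    out = model.copy()
    for rxn in extra:
        out.reactions[rxn.id] = rxn
        for mid in rxn.stoichiometry:
            if mid not in out.metabolites:
                out.metabolites[mid] = universe_mets[mid]
    return out


def minimal_additions(draft: StoichiometricModel,
                      universal: UniversalReactionSet,
                      universal_metabolites: dict,
                      medium: MediumSpec) -> list[str] | None:
    """Cardinality-minimal candidate set giving growth on ``medium``.

    Returns ``None`` when even the full universal set cannot produce biomass
    (the phenotype is unresolvable).  Solved as a MILP: continuous fluxes for
    the draft plus all candidates, a binary per candidate gating its bounds,
    biomass constrained above :data:`GAPFILL_MIN_BIOMASS`.
    """
    candidates = sorted(r for r in universal.reactions
                        if r not in draft.reactions)
    extended = _with_reactions(
        draft, [universal.reactions[r] for r in candidates], universal_metabolites
    )
    constrained = apply_medium(extended, medium)
    rxn_ids = sorted(constrained.reactions)
    n = len(rxn_ids)
    idx = {r: j for j, r in enumerate(rxn_ids)}
    cand_idx = [idx[r] for r in candidates]
    met_ids = sorted(constrained.metabolites)
    met_pos = {m: i for i, m in enumerate(met_ids)}

    rows, cols, vals = [], [], []
    for j, rid in enumerate(rxn_ids):
        for mid, coef in constrained.reactions[rid].stoichiometry.items():
            rows.append(met_pos[mid]); cols.append(j); vals.append(coef)
    S = sp.csr_matrix((vals, (rows, cols)), shape=(len(met_ids), n + len(cand_idx)))

    lb = np.array([constrained.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([constrained.reactions[r].upper_bound for r in rxn_ids])

    constraints = [LinearConstraint(S, 0.0, 0.0)]

    # gate candidate fluxes: lb_j*y_j <= v_j <= ub_j*y_j
    gate_rows, gate_cols, gate_vals, g_lo, g_hi = [], [], [], [], []
    k = 0
    for j in cand_idx:
        # v_j - ub_j * y_j <= 0
        gate_rows += [k, k]; gate_cols += [j, n + cand_idx.index(j)]
        gate_vals += [1.0, -ub[j]]
        g_lo.append(-np.inf); g_hi.append(0.0)
        k += 1
        # v_j - lb_j * y_j >= 0
        gate_rows += [k, k]; gate_cols += [j, n + cand_idx.index(j)]
        gate_vals += [1.0, -lb[j]]
        g_lo.append(0.0); g_hi.append(np.inf)
        k += 1
    if cand_idx:
        G = sp.csr_matrix((gate_vals, (gate_rows, gate_cols)),
                          shape=(k, n + len(cand_idx)))
        constraints.append(LinearConstraint(G, g_lo, g_hi))

    # summed biomass flux must clear the growth floor
    bio = np.zeros(n + len(cand_idx))
    for bid in constrained.biomass_reaction_ids:
        bio[idx[bid]] = 1.0
    constraints.append(LinearConstraint(bio, GAPFILL_MIN_BIOMASS, np.inf))

    c = np.concatenate([np.zeros(n), np.ones(len(cand_idx))])
    integrality = np.concatenate([np.zeros(n), np.ones(len(cand_idx))])
    var_lb = np.concatenate([lb, np.zeros(len(cand_idx))])
    var_ub = np.concatenate([ub, np.ones(len(cand_idx))])

    res = milp(c, constraints=constraints, integrality=integrality,
               bounds=Bounds(var_lb, var_ub))
    if not res.success:
        return None
    y = res.x[n:]
    return [candidates[i] for i in range(len(candidates)) if y[i] > 0.5]


def gapfill_model(draft: StoichiometricModel,
                  universal: UniversalReactionSet,
                  phenotypes: GrowthPhenotypeMatrix,
                  media: list[MediumSpec],
                  universal_metabolites: dict | None = None,
                  ) -> tuple[StoichiometricModel, GapfillReport]:
    """Repair ``draft`` to grow on every observed-growth medium.

    Media are visited in ascending carbon-source order; additions accumulate,
    so a reaction added for one substrate is available for the next.  Each
    medium's addition set is cardinality-minimal given the model state at
    that point.  Unresolvable positives and residual false growth on
    negatives are recorded, never fatal.
    """
    if universal_metabolites is None:
        universal_metabolites = _infer_universal_metabolites(universal, draft)
    media_by_source = {m.carbon_source: m for m in media}
    positives = phenotypes.positives_for(draft.species_id)
    missing = [c for c in positives if c not in media_by_source]
    if missing:
        raise ValueError(
            f"no medium provided for positive phenotypes {missing} "
            f"of {draft.species_id!r}"
        )

    model = draft.copy()
    report = GapfillReport(species_id=draft.species_id)
    for source in positives:
        medium = media_by_source[source]
        if predicts_growth(model, medium):
            report.resolution[source] = "growing"
            continue
        additions = minimal_additions(model, universal,
                                      universal_metabolites, medium)
        if additions is None:
            logger.warning("unresolvable positive phenotype: %s on %s",
                           draft.species_id, source)
            report.resolution[source] = "unresolvable"
            continue
        model = _with_reactions(model, [universal.reactions[r] for r in additions],
                                universal_metabolites)
        report.added_reaction_ids.extend(additions)
        report.resolution[source] = "gapfilled"

    for (species, source), value in sorted(phenotypes.entries.items()):
        if species != draft.species_id or value != NO_GROWTH:
            continue
        medium = media_by_source.get(source)
        if medium is not None and predicts_growth(model, medium):
            report.false_growth.append(source)
    return model, report


def _infer_universal_metabolites(universal: UniversalReactionSet,
                                 draft: StoichiometricModel) -> dict:
    """Metabolite objects for universal reactions: draft's where known,
    otherwise inferred extracellular for ``*_e`` ids, cytosolic else."""
    from .core import Metabolite

    mets = dict(draft.metabolites)
    for rxn in universal.reactions.values():
        for mid in rxn.stoichiometry:
            if mid not in mets:
                comp = "extracellular" if mid.endswith("_e") else "cytosol"
                mets[mid] = Metabolite(id=mid, compartment=comp)
    return mets


def phenotype_concordance(models: list[StoichiometricModel],
                          phenotypes: GrowthPhenotypeMatrix,
                          media: list[MediumSpec],
                          threshold: float = GROWTH_THRESHOLD) -> float:
    """Fraction of non-untested phenotype entries the models predict correctly."""
    by_species = {m.species_id: m for m in models}
    media_by_source = {m.carbon_source: m for m in media}
    total = correct = 0
    for (species, source), value in phenotypes.entries.items():
        if value == UNTESTED:
            continue
        model = by_species.get(species)
        medium = media_by_source.get(source)
        if model is None or medium is None:
            raise ValueError(f"no model/medium for tested pair ({species}, {source})")
        total += 1
        predicted = predicts_growth(model, medium, threshold=threshold)
        if predicted == (value == GROWTH):
            correct += 1
    if total == 0:
        raise ValueError("phenotype matrix has no tested entries")
    return correct / total


def merge_mixed_bag(models: list[StoichiometricModel]) -> StoichiometricModel:
    """Pool members into one boundary-free community model.

    Metabolites and reactions are unioned on id.  Duplicate reaction ids with
    identical stoichiometry collapse to one reaction with the widest bounds;
    conflicting stoichiometry under one id is a hard error.  Every member's
    biomass reaction is retained and FBA maximises their sum.
    """
    if not models:
        raise ValueError("merge_mixed_bag needs at least one model")
    if len(models) == 1:
        return models[0].copy()

    metabolites: dict = {}
    reactions: dict[str, Reaction] = {}
    for model in models:
        model.validate()
        for mid, met in model.metabolites.items():
            existing = metabolites.get(mid)
            if existing is not None and existing.compartment != met.compartment:
                raise ReactionCollisionError(
                    f"metabolite {mid!r}: conflicting compartments across members"
                )
            metabolites.setdefault(mid, met)
        for rid, rxn in model.reactions.items():
            existing = reactions.get(rid)
            if existing is None:
                reactions[rid] = rxn
                continue
            if existing.stoichiometry != rxn.stoichiometry:
                raise ReactionCollisionError(
                    f"reaction id {rid!r} has conflicting stoichiometry "
                    f"across members"
                )
            reactions[rid] = Reaction(
                id=rid,
                stoichiometry=existing.stoichiometry,
                lower_bound=min(existing.lower_bound, rxn.lower_bound),
                upper_bound=max(existing.upper_bound, rxn.upper_bound),
                genes=existing.genes | rxn.genes,
                kind=existing.kind,
            )

    community = StoichiometricModel(
        species_id="community[" + "+".join(m.species_id for m in models) + "]",
        metabolites=metabolites,
        reactions=reactions,
        biomass_id=sorted(r.id for r in reactions.values()
                          if r.kind == "biomass")[0],
    )
    community.validate()
    return community
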