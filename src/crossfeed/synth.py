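"""Ground-truth-known synthetic inputs for every pipeline stage.

The consortium generator builds toy stoichiometric models from designed
substrate sets: each species gets a complete uptake chain (exchange,
transport, catabolism) for exactly the carbon sources in its designed
fundamental niche, plus a species-specific biomass reaction consuming a
shared carbon precursor (one precursor per carbon atom, so yields scale with
substrate carbon content and a disaccharide yields exactly twice its
hexose).  Chitin, the polymer, is handled through extracellular hydrolysis
roles: a *chitinase* role cleaves chitin to chitobiose and a *chitobiase*
role cleaves chitobiose to NAG.  Splitting the two roles across species
makes chitin growth an emergent community property: no isolate completes the
chain, the mixed-bag model does.

The default eight-species design mirrors a chitin-degrading soil consortium:
nested designed niches of strictly decreasing size (so the niche ranking is
unambiguous), designed abundances that decrease with niche size, hydrolysis
roles split between early-stage and mid-stage species, twelve panel carbon
sources, three transcriptome replicates and five metabolome replicates over
two time points.

Count matrices are negative-binomial (Gamma–Poisson) with planted
differentially expressed genes and optional per-species abundance shifts;
metabolite tables are log-normal with planted group differences.  All
generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_BOUND, Metabolite, Reaction, StoichiometricModel
from .gapfill import GrowthPhenotypeMatrix, UniversalReactionSet
from .niche import DEFAULT_PANEL, NicheProfile

#: Carbon atoms per panel metabolite; the chitin unit is modelled as a
#: 4-mer of NAG and chitobiose as the NAG dimer.
CARBON_ATOMS = {
    "glucose": 6, "fructose": 6, "nag": 8, "xylose": 5, "arabinose": 5,
    "maltose": 12, "sucrose": 12, "serine": 3, "glycine": 2, "alanine": 3,
    "glutamate": 5, "chitobiose": 16, "chitin": 32, "precursor": 1,
}

#: Disaccharide hydrolysis products (cytosolic split reactions).
DISACCHARIDES = {"maltose": ("glucose", "glucose"),
                 "sucrose": ("glucose", "fructose")}

POLYMERS = ("chitin",)

#: Substrate preference order used to build nested designed niches; the
#: universally used sources come first and glycine (rarest) last.
NESTING_ORDER = (
    "glucose", "nag", "glutamate", "arabinose", "fructose", "xylose",
    "alanine", "maltose", "sucrose", "serine", "glycine",
)

#: Default designed niche sizes, descending; analogues of a real consortium's
#: ordering with the broadest generalist first and narrow specialists last.
DEFAULT_NICHE_SIZES = {
    "ensifer": 11, "streptomyces": 10, "variovorax": 9, "rhodococcus": 8,
    "sinorhizobium": 7, "sphingopyxis": 6, "neorhizobium": 5, "dyadobacter": 4,
}

#: Designed community abundances, strictly decreasing with niche size.
DEFAULT_ABUNDANCES = {
    "ensifer": 0.30, "streptomyces": 0.20, "variovorax": 0.15,
    "rhodococcus": 0.12, "sinorhizobium": 0.09, "sphingopyxis": 0.07,
    "neorhizobium": 0.04, "dyadobacter": 0.03,
}

#: Hydrolysis role assignments: early-stage species cleave the polymer,
#: mid-stage species cleave the dimer; no species holds both roles.
DEFAULT_ROLES = {
    "streptomyces": {"chitinase"}, "neorhizobium": {"chitinase"},
    "sinorhizobium": {"chitobiase"}, "ensifer": {"chitobiase"},
}


class InfeasibleDesignError(ValueError):
    """A designed niche depends on a metabolite no species can supply."""


@dataclass
class ConsortiumDesign:
    """Blueprint for a synthetic consortium with known niches."""

    substrate_sets: dict[str, set[str]]          # species -> designed niche
    carbon_panel: tuple[str, ...] = DEFAULT_PANEL
    roles: dict[str, set[str]] = field(default_factory=dict)
    abundances: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        panel = set(self.carbon_panel)
        for species, subs in self.substrate_sets.items():
            extra = subs - panel
            if extra:
                raise ValueError(f"{species!r}: designed niche outside panel: "
                                 f"{sorted(extra)}")
            poly = subs & set(POLYMERS)
            if poly:
                raise InfeasibleDesignError(
                    f"{species!r} lists polymer {sorted(poly)} as a designed "
                    f"substrate; polymer growth requires hydrolysis roles "
                    f"(chitinase + chitobiase) plus NAG uptake"
                )
        for species, role_set in self.roles.items():
            if species not in self.substrate_sets:
                raise ValueError(f"role assigned to unknown species {species!r}")
            bad = role_set - {"chitinase", "chitobiase"}
            if bad:
                raise ValueError(f"unknown roles {sorted(bad)}")
        if any(p in panel for p in POLYMERS):
            if not any("chitinase" in r for r in self.roles.values()):
                raise InfeasibleDesignError(
                    "panel contains chitin but no species carries the "
                    "chitinase (polymer degrader) role"
                )


def default_design(seed: int = 42) -> ConsortiumDesign:
    """The eight-species, twelve-source default consortium design."""
    substrate_sets = {
        species: set(NESTING_ORDER[:size])
        for species, size in DEFAULT_NICHE_SIZES.items()
    }
    return ConsortiumDesign(
        substrate_sets=substrate_sets,
        roles={s: set(r) for s, r in DEFAULT_ROLES.items()},
        abundances=dict(DEFAULT_ABUNDANCES),
        seed=seed,
    )


def _met(mid: str, compartment: str) -> Metabolite:
    base = mid[:-2] if mid.endswith(("_e", "_c")) else mid
    return Metabolite(id=mid, name=base, compartment=compartment,
                      carbon_atoms=CARBON_ATOMS.get(base))


def _substrate_reactions(source: str, species_id: str
                         ) -> tuple[list[Reaction], list[Metabolite]]:
    """Complete uptake chain for one designed (non-polymer) substrate."""
    rxns = [
        Reaction(id=f"EX_{source}", stoichiometry={f"{source}_e": -1.0},
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="exchange"),
        Reaction(id=f"TR_{source}",
                 stoichiometry={f"{source}_e": -1.0, f"{source}_c": 1.0},
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="transport",
                 genes=frozenset({f"{species_id}_tr_{source}"})),
    ]
    mets = [_met(f"{source}_e", "extracellular"), _met(f"{source}_c", "cytosol")]
    if source in DISACCHARIDES:
        left, right = DISACCHARIDES[source]
        products: dict[str, float] = {}
        for hexose in (left, right):
            products[f"{hexose}_c"] = products.get(f"{hexose}_c", 0.0) + 1.0
        rxns.append(Reaction(
            id=f"SPLIT_{source}",
            stoichiometry={f"{source}_c": -1.0, **products},
            kind="internal",
            genes=frozenset({f"{species_id}_split_{source}"}),
        ))
        for hexose in {left, right}:
            mets.append(_met(f"{hexose}_c", "cytosol"))
            rxns.append(_catabolism(hexose, species_id))
    else:
        rxns.append(_catabolism(source, species_id))
    return rxns, mets


def _catabolism(source: str, species_id: str) -> Reaction:
    return Reaction(
        id=f"CAT_{source}",
        stoichiometry={f"{source}_c": -1.0,
                       "precursor_c": float(CARBON_ATOMS[source])},
        kind="internal",
        genes=frozenset({f"{species_id}_cat_{source}"}),
    )


_CHITINASE = Reaction(id="CHITINASE",
                      stoichiometry={"chitin_e": -1.0, "chitobiose_e": 2.0},
                      kind="internal")
_CHITOBIASE = Reaction(id="CHITOBIASE",
                       stoichiometry={"chitobiose_e": -1.0, "nag_e": 2.0},
                       kind="internal")


def _build_species_model(species_id: str,
                         design: ConsortiumDesign) -> StoichiometricModel:
    metabolites: dict[str, Metabolite] = {
        "precursor_c": _met("precursor_c", "cytosol")
    }
    reactions: dict[str, Reaction] = {}

    for source in sorted(design.substrate_sets[species_id]):
        rxns, mets = _substrate_reactions(source, species_id)
        for met in mets:
            metabolites.setdefault(met.id, met)
        for rxn in rxns:
            reactions.setdefault(rxn.id, rxn)

    roles = design.roles.get(species_id, set())
    if "chitinase" in roles:
        for met in (_met("chitin_e", "extracellular"),
                    _met("chitobiose_e", "extracellular")):
            metabolites.setdefault(met.id, met)
        reactions.setdefault("EX_chitin", Reaction(
            id="EX_chitin", stoichiometry={"chitin_e": -1.0},
            lower_bound=0.0, kind="exchange"))
        reactions.setdefault("EX_chitobiose", Reaction(
            id="EX_chitobiose", stoichiometry={"chitobiose_e": -1.0},
            lower_bound=0.0, kind="exchange"))
        reactions["CHITINASE"] = Reaction(
            id="CHITINASE", stoichiometry=dict(_CHITINASE.stoichiometry),
            kind="internal", genes=frozenset({f"{species_id}_chitinase"}))
    if "chitobiase" in roles:
        for met in (_met("chitobiose_e", "extracellular"),
                    _met("nag_e", "extracellular")):
            metabolites.setdefault(met.id, met)
        reactions.setdefault("EX_chitobiose", Reaction(
            id="EX_chitobiose", stoichiometry={"chitobiose_e": -1.0},
            lower_bound=0.0, kind="exchange"))
        reactions.setdefault("EX_nag", Reaction(
            id="EX_nag", stoichiometry={"nag_e": -1.0},
            lower_bound=0.0, kind="exchange"))
        reactions["CHITOBIASE"] = Reaction(
            id="CHITOBIASE", stoichiometry=dict(_CHITOBIASE.stoichiometry),
            kind="internal", genes=frozenset({f"{species_id}_chitobiase"}))

    biomass_id = f"BIOMASS_{species_id}"
    reactions[biomass_id] = Reaction(
        id=biomass_id, stoichiometry={"precursor_c": -1.0}, kind="biomass")

    model = StoichiometricModel(species_id=species_id, metabolites=metabolites,
                                reactions=reactions, biomass_id=biomass_id)
    model.validate()
    return model


def _designed_fundamental(species_id: str, design: ConsortiumDesign) -> set[str]:
    niche = set(design.substrate_sets[species_id])
    roles = design.roles.get(species_id, set())
    if {"chitinase", "chitobiase"} <= roles and "nag" in niche \
            and "chitin" in design.carbon_panel:
        niche.add("chitin")
    return niche


def _designed_realized(design: ConsortiumDesign) -> set[str]:
    realized = set()
    for species in design.substrate_sets:
        realized |= _designed_fundamental(species, design)
    has_chitinase = any("chitinase" in r for r in design.roles.values())
    has_chitobiase = any("chitobiase" in r for r in design.roles.values())
    has_nag_uptake = any("nag" in s for s in design.substrate_sets.values())
    if ("chitin" in design.carbon_panel and has_chitinase and has_chitobiase
            and has_nag_uptake):
        realized.add("chitin")
    return realized


def gen_consortium(design: ConsortiumDesign
                   ) -> tuple[list[StoichiometricModel], NicheProfile]:
    """Build the designed species models and their ground-truth niches.

    Each model grows (by FBA) exactly on its designed substrate set; the
    mixed-bag merge grows exactly on the designed community set.
    """
    design.validate()
    models = [_build_species_model(s, design)
              for s in sorted(design.substrate_sets)]
    truth = NicheProfile(
        fundamental={s: _designed_fundamental(s, design)
                     for s in design.substrate_sets},
        realized=_designed_realized(design),
    )
    return models, truth


def gen_draft_and_universal(
    models: list[StoichiometricModel],
    deletions_per_model: tuple[int, int] = (1, 3),
    n_decoys: int = 20,
    seed: int = 0,
) -> tuple[list[StoichiometricModel], UniversalReactionSet, dict[str, list[str]]]:
    """Derive broken drafts plus a universal reaction set for gapfilling.

    Per model, between ``deletions_per_model[0]`` and ``[1]`` transport /
    catabolism / split reactions are removed (each breaks at least one
    designed growth phenotype).  The universal set is the union of every
    ground-truth reaction across models plus mass-balanced decoy reactions
    disconnected from biomass.  Returns (drafts, universal, deletion truth).
    """
    rng = np.random.default_rng(seed)
    lo, hi = deletions_per_model
    universal = UniversalReactionSet(reactions={})
    for model in models:
        for rxn in model.reactions.values():
            if rxn.kind != "biomass":
                universal.add(rxn, provenance=model.species_id)

    # decoy loop: mass-balanced conversions among dead-end metabolites
    decoy_mets = {}
    for i in range(n_decoys):
        a, b = f"decoy{i}a_c", f"decoy{i}b_c"
        decoy_mets[a] = Metabolite(id=a, compartment="cytosol", carbon_atoms=3)
        decoy_mets[b] = Metabolite(id=b, compartment="cytosol", carbon_atoms=3)
        universal.add(Reaction(id=f"DECOY_{i}",
                               stoichiometry={a: -1.0, b: 1.0},
                               lower_bound=-DEFAULT_BOUND, kind="internal"),
                      provenance="decoy")

    drafts = []
    truth: dict[str, list[str]] = {}
    for model in models:
        removable = sorted(
            r.id for r in model.reactions.values()
            if r.id.startswith(("TR_", "CAT_", "SPLIT_"))
        )
        k = int(rng.integers(lo, hi + 1))
        if k > len(removable):
            raise ValueError(
                f"{model.species_id!r}: requested {k} deletions but only "
                f"{len(removable)} removable reactions"
            )
        deleted = sorted(rng.choice(removable, size=k, replace=False).tolist())
        draft = model.copy()
        for rid in deleted:
            del draft.reactions[rid]
        drafts.append(draft)
        truth[model.species_id] = deleted
    return drafts, universal, truth


def gen_phenotypes(truth: NicheProfile, panel: tuple[str, ...] = DEFAULT_PANEL,
                   flip_rate: float = 0.0, seed: int = 0
                   ) -> GrowthPhenotypeMatrix:
    """Phenotype matrix from ground-truth niches, optionally noised by
    flipping each call with probability ``flip_rate``."""
    rng = np.random.default_rng(seed)
    entries = {}
    for species, niche in truth.fundamental.items():
        for source in panel:
            value = "growth" if source in niche else "no_growth"
            if flip_rate > 0 and rng.random() < flip_rate:
                value = "no_growth" if value == "growth" else "growth"
            entries[(species, source)] = value
    return GrowthPhenotypeMatrix(entries=entries)


def gen_counts(
    n_genes_per_species: int = 200,
    n_planted_degs: int = 20,
    effect_fold: float = 4.0,
    dispersion: float = 0.1,
    n_reps: int = 3,
    abundance_shifts: dict[str, float] | None = None,
    species_abundances: dict[str, float] | None = None,
    total_reads: int = 1_000_000,
    seed: int = 0,
):
    """Two-time-point negative-binomial count matrix with planted DEGs.

    Gene means are species-abundance-scaled log-normal weights; planted genes
    are multiplied by ``effect_fold`` in the second group; species listed in
    ``abundance_shifts`` change their community share by that fold between
    groups.  Returns (ExpressionMatrix, truth dict with planted gene ids and
    designed per-group abundance fractions).
    """
    from .omics import ExpressionMatrix

    if effect_fold <= 1:
        raise ValueError("effect_fold must be > 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    if species_abundances is None:
        species_abundances = dict(DEFAULT_ABUNDANCES)
    abundance_shifts = abundance_shifts or {}
    species = sorted(species_abundances)

    a70 = np.array([species_abundances[s] for s in species], dtype=float)
    a70 = a70 / a70.sum()
    a118 = a70 * np.array([abundance_shifts.get(s, 1.0) for s in species])
    a118 = a118 / a118.sum()

    sample_ids, time_points, replicates = [], [], []
    for tp in ("70h", "118h"):
        for r in range(1, n_reps + 1):
            sample_ids.append(f"{tp}_r{r}")
            time_points.append(tp)
            replicates.append(r)

    gene_ids, gene_species, planted = [], [], []
    blocks = []
    for si, sp in enumerate(species):
        genes = [f"{sp}_g{j:04d}" for j in range(n_genes_per_species)]
        gene_ids.extend(genes)
        gene_species.extend([sp] * n_genes_per_species)
        weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes_per_species)
        weights /= weights.sum()
        deg_idx = rng.choice(n_genes_per_species,
                             size=min(n_planted_degs, n_genes_per_species),
                             replace=False)
        planted.extend(genes[j] for j in sorted(deg_idx))
        mu70 = total_reads * a70[si] * weights
        mu118 = total_reads * a118[si] * weights
        mu118 = mu118.copy()
        mu118[deg_idx] *= effect_fold
        block = np.empty((n_genes_per_species, 2 * n_reps))
        for col, tp in enumerate(time_points):
            mu = mu70 if tp == "70h" else mu118
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            block[:, col] = rng.poisson(lam)
        blocks.append(block)

    counts = pd.DataFrame(np.vstack(blocks).astype(int), index=gene_ids,
                          columns=sample_ids)
    samples = pd.DataFrame({"time_point": time_points,
                            "replicate": replicates}, index=sample_ids)
    gene_map = pd.Series(gene_species, index=gene_ids, name="species_id")
    matrix = ExpressionMatrix(counts=counts, samples=samples, gene_map=gene_map)
    truth = {
        "planted_degs": sorted(planted),
        "effect_fold": effect_fold,
        "abundance_70h": dict(zip(species, a70)),
        "abundance_118h": dict(zip(species, a118)),
        "seed": seed,
    }
    return matrix, truth


def gen_metabolites(
    n_metabolites: int = 100,
    n_diff: int = 5,
    fold: float = 6.55,
    sigma: float = 0.1,
    n_reps: int = 5,
    seed: int = 0,
):
    """Log-normal metabolite × sample table with ``n_diff`` metabolites
    shifted by ``fold`` in the second group.  Returns (table, groups, truth)."""
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    metabolites = [f"met{j:03d}" for j in range(n_metabolites)]
    shifted = metabolites[:n_diff]
    base = rng.lognormal(mean=8.0, sigma=1.0, size=n_metabolites)

    sample_ids, labels = [], []
    for tp in ("70h", "118h"):
        for r in range(1, n_reps + 1):
            sample_ids.append(f"{tp}_r{r}")
            labels.append(tp)
    data = np.empty((n_metabolites, 2 * n_reps))
    for col, tp in enumerate(labels):
        scale = np.ones(n_metabolites)
        if tp == "118h":
            scale[:n_diff] = fold
        data[:, col] = base * scale * rng.lognormal(0.0, sigma, n_metabolites)
    table = pd.DataFrame(data, index=metabolites, columns=sample_ids)
    groups = pd.Series(labels, index=sample_ids, name="group")
    truth = {"shifted": shifted, "fold": fold, "seed": seed}
    return table, groups, truth
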