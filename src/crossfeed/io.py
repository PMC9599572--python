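"""File formats, fixture directories and the end-to-end pipeline.

Model schema: one JSON document per species (metabolites[], reactions[] with
stoichiometry maps, bounds, genes, kind, biomass_id), with an equivalent
two-file TSV dialect (``<stem>.metabolites.tsv`` + ``<stem>.reactions.tsv``).
Read and write round-trip without loss.  A flat SBML subset (species,
reactions, fbc flux bounds) can be ingested; any construct outside the
subset — rules, events, extra compartments — is rejected loudly rather than
silently dropped.

``run_pipeline`` ties the stages together in analysis order: load or
generate models → gapfill against phenotypes → mixed-bag merge → niche
tables, then the omics summaries, writing TSV outputs plus a run manifest
recording the seed and every threshold used.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .core import (
    GROWTH_THRESHOLD,
    DEFAULT_CARBON_UPTAKE,
    MediumSpec,
    Metabolite,
    Reaction,
    StoichiometricModel,
)
from .gapfill import (
    GrowthPhenotypeMatrix,
    UniversalReactionSet,
    gapfill_model,
    merge_mixed_bag,
    phenotype_concordance,
)
from .niche import niche_table, rank_agreement
from .omics import (
    ExpressionMatrix,
    abundance_profile,
    call_degs,
    degs_to_frame,
    metabolite_diff,
)
from .pathway import AnnotationTable, default_chitin_pathway, score_coverage

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A file does not conform to the supported schema."""


# ---------------------------------------------------------------- model JSON

def model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "species_id": model.species_id,
        "biomass_id": model.biomass_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "carbon_atoms": m.carbon_atoms}
            for m in sorted(model.metabolites.values(), key=lambda m: m.id)
        ],
        "reactions": [
            {"id": r.id, "stoichiometry": dict(sorted(r.stoichiometry.items())),
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "genes": sorted(r.genes), "kind": r.kind}
            for r in sorted(model.reactions.values(), key=lambda r: r.id)
        ],
    }


def model_from_dict(doc: dict) -> StoichiometricModel:
    try:
        metabolites = {
            m["id"]: Metabolite(id=m["id"], name=m.get("name", ""),
                                compartment=m["compartment"],
                                carbon_atoms=m.get("carbon_atoms"))
            for m in doc["metabolites"]
        }
        reactions = {
            r["id"]: Reaction(id=r["id"],
                              stoichiometry={k: float(v) for k, v
                                             in r["stoichiometry"].items()},
                              lower_bound=float(r["lower_bound"]),
                              upper_bound=float(r["upper_bound"]),
                              genes=frozenset(r.get("genes", [])),
                              kind=r["kind"])
            for r in doc["reactions"]
        }
        model = StoichiometricModel(
            species_id=doc["species_id"], metabolites=metabolites,
            reactions=reactions, biomass_id=doc["biomass_id"])
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed model document: {exc}") from exc
    model.validate()
    return model


def write_model(model: StoichiometricModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1,
                                     sort_keys=True) + "\n")


def read_model(path) -> StoichiometricModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON at offset {exc.pos}: "
                          f"{exc.msg}") from exc
    return model_from_dict(doc)


# ----------------------------------------------------------------- model TSV

def write_model_tsv(model: StoichiometricModel, stem) -> None:
    """Two-file TSV dialect: ``<stem>.metabolites.tsv`` and
    ``<stem>.reactions.tsv`` (stoichiometry as ``met:coef;met:coef``)."""
    stem = Path(stem)
    mets = pd.DataFrame([
        {"id": m.id, "name": m.name, "compartment": m.compartment,
         "carbon_atoms": "" if m.carbon_atoms is None else m.carbon_atoms}
        for m in sorted(model.metabolites.values(), key=lambda m: m.id)
    ])
    rxns = pd.DataFrame([
        {"id": r.id,
         "stoichiometry": ";".join(f"{k}:{v:g}" for k, v
                                   in sorted(r.stoichiometry.items())),
         "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
         "genes": ";".join(sorted(r.genes)), "kind": r.kind,
         "species_id": model.species_id,
         "is_biomass_objective": r.id == model.biomass_id}
        for r in sorted(model.reactions.values(), key=lambda r: r.id)
    ])
    mets.to_csv(stem.with_suffix(".metabolites.tsv"), sep="\t", index=False)
    rxns.to_csv(stem.with_suffix(".reactions.tsv"), sep="\t", index=False)


def read_model_tsv(stem) -> StoichiometricModel:
    stem = Path(stem)
    mets = pd.read_csv(stem.with_suffix(".metabolites.tsv"), sep="\t",
                       keep_default_na=False)
    rxns = pd.read_csv(stem.with_suffix(".reactions.tsv"), sep="\t",
                       keep_default_na=False)
    metabolites = {}
    for _, row in mets.iterrows():
        carbon = row["carbon_atoms"]
        metabolites[row["id"]] = Metabolite(
            id=row["id"], name=str(row["name"]),
            compartment=row["compartment"],
            carbon_atoms=None if carbon == "" else int(carbon))
    reactions = {}
    biomass_id = None
    species_id = None
    for _, row in rxns.iterrows():
        stoich = {}
        for pair in str(row["stoichiometry"]).split(";"):
            met, _, coef = pair.rpartition(":")
            if not met:
                raise SchemaError(f"{stem}: bad stoichiometry field {pair!r}")
            stoich[met] = float(coef)
        genes = frozenset(g for g in str(row["genes"]).split(";") if g)
        reactions[row["id"]] = Reaction(
            id=row["id"], stoichiometry=stoich,
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            genes=genes, kind=row["kind"])
        species_id = row["species_id"]
        if str(row["is_biomass_objective"]) in ("True", "true", "1"):
            biomass_id = row["id"]
    if biomass_id is None:
        raise SchemaError(f"{stem}: no reaction marked is_biomass_objective")
    model = StoichiometricModel(species_id=species_id, metabolites=metabolites,
                                reactions=reactions, biomass_id=biomass_id)
    model.validate()
    return model


# --------------------------------------------------------------- SBML subset

class SBMLUnsupportedError(SchemaError):
    """The SBML file uses constructs outside the supported flat subset."""


_SBML_COMPARTMENTS = {"c": "cytosol", "cytosol": "cytosol",
                      "e": "extracellular", "extracellular": "extracellular"}


def read_sbml_model(path) -> StoichiometricModel:
    """Read a flat SBML(+fbc) subset: two compartments, species, reactions
    with fbc or local-parameter bounds.  Anything else is rejected."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SchemaError(f"{path}: SBML parse error: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SchemaError(f"{path}: no model element")
    for construct, count in [("rules", sbml_model.getNumRules()),
                             ("events", sbml_model.getNumEvents()),
                             ("constraints", sbml_model.getNumConstraints())]:
        if count:
            raise SBMLUnsupportedError(
                f"{path}: SBML {construct} are not supported "
                f"({count} present); refusing to drop them silently")

    metabolites = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        comp = _SBML_COMPARTMENTS.get(sp.getCompartment())
        if comp is None:
            raise SBMLUnsupportedError(
                f"{path}: species {sp.getId()!r} in unsupported compartment "
                f"{sp.getCompartment()!r} (supported: c/e)")
        metabolites[sp.getId()] = Metabolite(
            id=sp.getId(), name=sp.getName() or "", compartment=comp)

    fbc = sbml_model.getPlugin("fbc")
    reactions = {}
    biomass_id = None
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) \
                + ref.getStoichiometry()
        lb, ub = (-1000.0, 1000.0) if rxn.getReversible() else (0.0, 1000.0)
        rplug = rxn.getPlugin("fbc")
        if rplug is not None:
            for attr, setter in ((rplug.getLowerFluxBound(), "lb"),
                                 (rplug.getUpperFluxBound(), "ub")):
                if attr:
                    param = sbml_model.getParameter(attr)
                    if param is None:
                        raise SchemaError(
                            f"{path}: reaction {rxn.getId()!r} references "
                            f"missing flux-bound parameter {attr!r}")
                    if setter == "lb":
                        lb = param.getValue()
                    else:
                        ub = param.getValue()
        rid = rxn.getId()
        lowered = rid.lower()
        if "biomass" in lowered:
            kind = "biomass"
            biomass_id = rid
        elif rid.startswith("EX_"):
            kind = "exchange"
        else:
            kind = "internal"
        reactions[rid] = Reaction(id=rid, stoichiometry=stoich,
                                  lower_bound=lb, upper_bound=ub, kind=kind)
    if biomass_id is None:
        raise SchemaError(f"{path}: no biomass reaction found "
                          f"(expected an id containing 'biomass')")
    model = StoichiometricModel(
        species_id=sbml_model.getId() or Path(path).stem,
        metabolites=metabolites, reactions=reactions, biomass_id=biomass_id)
    model.validate()
    return model


# ------------------------------------------------------------- tabular files

def write_media(media: list[MediumSpec], path) -> None:
    rows = []
    for medium in media:
        rows.append({"carbon_source": medium.carbon_source,
                     "carbon_uptake_max": medium.carbon_uptake_max,
                     "base_nutrients": ";".join(
                         f"{k}:{v:g}" for k, v
                         in sorted(medium.base_nutrients.items()))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_media(path) -> list[MediumSpec]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    media = []
    for _, row in frame.iterrows():
        base = {}
        for pair in str(row.get("base_nutrients", "")).split(";"):
            if not pair:
                continue
            ex, _, up = pair.rpartition(":")
            base[ex] = float(up)
        media.append(MediumSpec(carbon_source=row["carbon_source"],
                                carbon_uptake_max=float(row["carbon_uptake_max"]),
                                base_nutrients=base))
    return media


def write_phenotypes(matrix: GrowthPhenotypeMatrix, path) -> None:
    rows = [{"species_id": s, "carbon_source": c, "phenotype": v}
            for (s, c), v in sorted(matrix.entries.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> GrowthPhenotypeMatrix:
    frame = pd.read_csv(path, sep="\t")
    entries = {(row["species_id"], row["carbon_source"]): row["phenotype"]
               for _, row in frame.iterrows()}
    return GrowthPhenotypeMatrix(entries=entries)


def read_expression(counts_path, samples_path, gene_map_path) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    gene_map = pd.read_csv(gene_map_path, sep="\t", index_col=0).iloc[:, 0]
    matrix = ExpressionMatrix(counts=counts, samples=samples, gene_map=gene_map)
    matrix.validate()
    return matrix


def read_annotations(path) -> dict[str, AnnotationTable]:
    """TSV of species_id, gene_id, term_type, term → per-species tables."""
    frame = pd.read_csv(path, sep="\t")
    tables = {}
    for species, group in frame.groupby("species_id"):
        tables[species] = AnnotationTable(
            species_id=species,
            annotations=[(r["gene_id"], r["term_type"], r["term"])
                         for _, r in group.iterrows()])
    return tables


# ------------------------------------------------------------ fixture writer

def write_fixture(out_dir, seed: int = 42) -> dict:
    """Write a complete synthetic fixture directory (models/, media.tsv,
    phenotypes.tsv, counts + metadata, metabolites.tsv, truth.json,
    manifest.json) and return the manifest."""
    from .synth import (default_design, gen_consortium, gen_counts,
                        gen_metabolites, gen_phenotypes)

    out = Path(out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    design = default_design(seed=seed)
    models, truth_niche = gen_consortium(design)
    for model in models:
        write_model(model, out / "models" / f"{model.species_id}.json")

    media = [MediumSpec(carbon_source=c, carbon_uptake_max=DEFAULT_CARBON_UPTAKE)
             for c in design.carbon_panel]
    write_media(media, out / "media.tsv")
    phenotypes = gen_phenotypes(truth_niche, panel=design.carbon_panel,
                                seed=seed)
    write_phenotypes(phenotypes, out / "phenotypes.tsv")

    counts, truth_counts = gen_counts(seed=seed)
    counts.counts.to_csv(out / "counts.tsv", sep="\t")
    counts.samples.to_csv(out / "samples.tsv", sep="\t")
    counts.gene_map.to_frame().to_csv(out / "gene_map.tsv", sep="\t")

    table, groups, truth_mets = gen_metabolites(seed=seed)
    table.to_csv(out / "metabolites.tsv", sep="\t")
    groups.to_frame().to_csv(out / "metabolite_groups.tsv", sep="\t")

    truth = {
        "niches": {
            "fundamental": {s: sorted(n)
                            for s, n in truth_niche.fundamental.items()},
            "realized": sorted(truth_niche.realized),
        },
        "abundances": design.abundances,
        "counts": truth_counts,
        "metabolites": truth_mets,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    manifest = {"seed": seed, "crossfeed_version": __version__,
                "files": sorted(p.relative_to(out).as_posix()
                                for p in out.rglob("*") if p.is_file())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# -------------------------------------------------------------- the pipeline

def run_pipeline(config: dict, out_dir) -> dict:
    """Run models → gapfill → mixed-bag → niches, then the omics summaries.

    ``config`` keys (paths): models_dir, media, phenotypes, counts, samples,
    gene_map, metabolites, metabolite_groups, annotations (optional);
    thresholds: growth_threshold, alpha, min_fold; seed.  Identical configs
    give byte-identical deterministic outputs.  Any stage failure aborts
    with the stage name; the manifest marks completed outputs.
    """
    path_keys = ("models_dir", "media", "phenotypes", "counts", "samples",
                 "gene_map", "metabolites", "metabolite_groups", "annotations")
    missing = [k for k in path_keys
               if k in config and not Path(config[k]).exists()]
    if missing:
        raise SchemaError(
            "config references nonexistent paths: "
            + ", ".join(f"{k}={config[k]}" for k in missing))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    threshold = float(config.get("growth_threshold", GROWTH_THRESHOLD))
    alpha = float(config.get("alpha", 0.05))
    min_fold = float(config.get("min_fold", 2.0))
    manifest: dict = {
        "crossfeed_version": __version__,
        "seed": config.get("seed"),
        "thresholds": {"growth_threshold": threshold, "alpha": alpha,
                       "min_fold": min_fold},
        "outputs": [],
        "complete": False,
    }
    logger.info("pipeline thresholds: growth=%g alpha=%g min_fold=%g seed=%s",
                threshold, alpha, min_fold, config.get("seed"))

    stage = "load models"
    try:
        models_dir = Path(config["models_dir"])
        models = [read_model(p) for p in sorted(models_dir.glob("*.json"))]
        if not models:
            raise SchemaError(f"no model JSON files in {models_dir}")
        media = read_media(config["media"])

        stage = "gapfill"
        reports = []
        if "phenotypes" in config:
            phenotypes = read_phenotypes(config["phenotypes"])
            universal = UniversalReactionSet(reactions={})
            for model in models:
                for rxn in model.reactions.values():
                    if rxn.kind != "biomass":
                        universal.add(rxn, provenance=model.species_id)
            gapfilled = []
            for model in models:
                filled, report = gapfill_model(model, universal, phenotypes,
                                               media)
                gapfilled.append(filled)
                reports.append(report.to_dict())
            models = gapfilled
            concordance = phenotype_concordance(models, phenotypes, media,
                                                threshold=threshold)
            (out / "gapfill_report.json").write_text(json.dumps(
                {"reports": reports, "phenotype_concordance": concordance},
                indent=1))
            manifest["outputs"].append("gapfill_report.json")

        stage = "mixed-bag merge and niches"
        community = merge_mixed_bag(models)
        profile = niche_table(models, community, media, threshold=threshold)
        pd.DataFrame(profile.to_records()).to_csv(
            out / "niche_table.tsv", sep="\t", index=False)
        manifest["outputs"].append("niche_table.tsv")

        stage = "differential expression"
        if "counts" in config:
            matrix = read_expression(config["counts"], config["samples"],
                                     config["gene_map"])
            degs = degs_to_frame(call_degs(matrix, alpha=alpha,
                                           min_fold=min_fold))
            degs.to_csv(out / "deg_results.tsv", sep="\t")
            manifest["outputs"].append("deg_results.tsv")

            profile_ab = abundance_profile(matrix)
            summary = profile_ab.group_stats.join(
                profile_ab.comparison, on="species_id")
            summary.to_csv(out / "abundance_profile.tsv", sep="\t")
            manifest["outputs"].append("abundance_profile.tsv")

            if "annotations" not in config:
                counts_by_species = degs.groupby("species_id").agg(
                    n_degs=("is_deg", "sum"), n_genes=("is_deg", "size"))
                from .omics import deg_percentage
                counts_by_species["pct_degs"] = [
                    deg_percentage(int(r.n_degs), int(r.n_genes))
                    for r in counts_by_species.itertuples()]
                counts_by_species.to_csv(out / "deg_summary.tsv", sep="\t")
                manifest["outputs"].append("deg_summary.tsv")

        stage = "metabolite differential abundance"
        if "metabolites" in config:
            table = pd.read_csv(config["metabolites"], sep="\t", index_col=0)
            groups = pd.read_csv(config["metabolite_groups"], sep="\t",
                                 index_col=0).iloc[:, 0]
            diff = metabolite_diff(table, groups, alpha=alpha)
            diff.to_csv(out / "metabolite_diff.tsv", sep="\t")
            manifest["outputs"].append("metabolite_diff.tsv")

        stage = "pathway coverage"
        if "annotations" in config:
            pathway = default_chitin_pathway()
            tables = read_annotations(config["annotations"])
            scores = [score_coverage(t, pathway) for t in tables.values()]
            pd.DataFrame([
                {"species_id": s.species_id, "covered": s.covered,
                 "n_steps": s.n_steps,
                 "covered_steps": ",".join(sorted(s.covered_steps)),
                 **{f"{k}_steps": v for k, v in s.per_stage.items()}}
                for s in scores
            ]).to_csv(out / "coverage.tsv", sep="\t", index=False)
            manifest["outputs"].append("coverage.tsv")
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["complete"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
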