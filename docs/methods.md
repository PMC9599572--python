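# Methods

This note documents the models, statistics and design choices behind
`crossfeed`, what the synthetic generators do and do not emulate, and the
numerical conventions the implementation relies on.

## Stoichiometric models and FBA

A model is a set of metabolites in two compartments (cytosol,
extracellular) and reactions with flux bounds in mmol·gDW⁻¹·h⁻¹.  Exchange
reactions carry exactly one extracellular metabolite out of the system
(stoichiometry `{met: -1}`), so uptake is a negative exchange flux.  A
medium is a base-nutrient map (carbon-free compounds) plus one focal carbon
source with an uptake ceiling; applying a medium closes every unlisted
exchange for uptake and leaves secretion open.

FBA maximises biomass flux subject to `S·v = 0` and the bounds, solved with
`scipy.optimize.linprog` (HiGHS, feasibility tolerances 1e-9).  Real
genome-scale platforms use more compartments and curated biomass
compositions; we deliberately restrict to two compartments because niche
calls depend only on exchange topology, and we treat absolute biomass
yields as model-convention-dependent: only yield *ratios* and growth/no-
growth calls are interpreted.

Key parameters:

- **Carbon uptake ceiling** — default 10 mmol·gDW⁻¹·h⁻¹, uniform across
  substrates.  This mirrors growth panels standardised by substrate
  molarity rather than carbon mass; with LP homogeneity the choice scales
  all yields equally and cancels in ratios.
- **Growth threshold** — biomass flux > 1e-6 (strict).  Separates numerical
  noise from growth; realistic optima under the default ceiling are ≥ O(1).
- **Yield** — optimal biomass flux divided by realized carbon uptake flux;
  defined as 0 when uptake is 0, and positive biomass with zero uptake
  raises an invariant error (carbon from nowhere).

Community models retain every member's biomass reaction and the objective
is their sum, so "community growth" means *some* combination of pooled
reactions produces biomass — exactly the realized-niche semantics.  A
single-species model still validates to exactly one biomass reaction; the
community model's `biomass_id` names the lexicographically first member
reaction purely as an anchor.

## Gapfilling

Per positive phenotype (medium), we solve a MILP over the draft plus all
universal candidate reactions: continuous fluxes, one binary per candidate
gating its bounds, biomass constrained ≥ 1e-3 (well above the growth
threshold), minimise the number of active candidates
(`scipy.optimize.milp`, HiGHS).  Media are visited in ascending
carbon-source order and additions accumulate, so the procedure is
deterministic and mirrors iterative per-condition gapfilling.  Each
medium's addition set is cardinality-minimal *given the model state at that
point*; the accumulated set across media need not be globally minimal,
which matches the iterative semantics.  Unresolvable positives are recorded
in the report and never fatal.  Negative phenotypes are never enforced —
the report lists residual false growth so concordance can be read either
including or excluding it.

## Niches and rank agreement

Fundamental niche: panel sources on which an isolate's FBA predicts growth.
Realized niche: same computation on the mixed-bag merge.  By LP
monotonicity under reaction addition the realized niche contains every
fundamental niche; the per-species delta (realized size − fundamental size)
measures the potential benefit of cross-feeding.  The niche table ranks
species by descending size with lexicographic tie-break.  Rank agreement
between niche sizes and abundances is Spearman's ρ with average-rank ties
(`scipy.stats.spearmanr`), requiring ≥ 3 species.

## Chitin-pathway coverage

The shipped pathway config (`crossfeed/data/chitin_pathway.json`) defines
eight steps over early (chitin binding K03933; GH18 chitinase EC 3.2.1.14;
GH19 chitinase K03791), mid (GH20/GH3 β-N-acetylhexosaminidase EC 3.2.1.52;
CE4 deacetylase EC 3.5.1.104; NAG PTS import EC 2.7.1.193) and late
(NAG-6-P deacetylase EC 3.5.1.25; glucosamine kinase EC 2.7.1.8) stages.
The file is versioned and editable: the exact gene-to-step assignment of
any given study is a curation decision, so users can swap their own
definition in.  A step is covered if any annotation matches any accepted
term; coverage counts **distinct steps, not genes** (a species with three
chitinase paralogues covers the chitinase step once).  EC matching honours
trailing `-`/`−` wildcards in the accepted term.  Malformed terms are
skipped with a warning.

## Omics statistics

**Per-species normalization.**  Median-of-ratios size factors are computed
within each species' gene set separately and genes are divided by their
species' per-sample factor.  This removes the species-abundance signal from
expression comparisons: multiplying one species' genes by a constant in one
sample changes no other species' factors (tested).  Factors are defined up
to the geometric-mean reference, as in the standard method; only ratios
between samples are meaningful.

**Differential expression.**  Per gene, a Wald test on the log ratio of
group means of normalized counts.  The variance follows the delta method
under a negative-binomial model (`Var(log mean) ≈ (1/mu + α)/n`), with a
per-gene method-of-moments dispersion floored at the genome-wide median
dispersion.  The floor shares information across genes: with 2–5
replicates, per-gene moment estimates frequently collapse to zero and
would otherwise produce arbitrarily small standard errors; flooring at the
central value keeps the null calibrated (≤ 2 false calls per 1,000 null
genes, seed-averaged, in the test suite) while retaining ~90% power for
4-fold effects at dispersion 0.1.  A half-count offset stabilises
zero-count groups.  P values are BH-adjusted; a gene is a DEG iff adjusted
P ≤ 0.05 **and** |fold change| > 2 (both flags configurable).  This is a
deliberately simple stand-alone test — it does not implement shrinkage of
fold changes or Cook's-distance outlier handling, and exact replication of
any specific DE package is out of scope; the DEG *filter* and downstream
count arithmetic are the load-bearing parts.

**%DEG of genome** is `100·n_degs/n_genes` rounded half-even to two
decimals (banker's rounding, matching conventional table formatting).

**Abundance profiles.**  Species fractions of total reads per sample; group
mean ± sd; fold change as the ratio of group means; Welch's t on
per-replicate fractions for significance.  Welch's t was chosen because the
shifted species' fraction variance grows with its mean.

**Metabolite differential abundance.**  Welch's t on log abundances
(multiplicative noise makes logs approximately normal), BH adjustment at
0.05, fold change reported as the ratio of raw group means.  Group order
follows first appearance in the metadata, so with 70 h samples listed
first the fold is 118 h over 70 h.  Nonpositive abundances exclude the
metabolite with a warning.

## Synthetic generators

The generators produce inputs with known ground truth so every analysis
stage can be tested as a parameter-recovery problem.

**Consortium models.**  Each species receives a complete uptake chain
(exchange → transport → catabolism) for exactly its designed substrates;
catabolism yields one biomass-precursor per substrate carbon atom, so
yields scale with carbon content and disaccharides (split into two hexoses
before catabolism) yield exactly twice glucose.  Chitin is an extracellular
4-mer of NAG hydrolysed in two extracellular steps, chitin → chitobiose
(chitinase role) and chitobiose → NAG (chitobiase role).  The default
eight-species design assigns nested substrate sets of sizes 11 down to 4
over the twelve-source panel (chitin, glucose, NAG, serine, glycine,
alanine, maltose, xylose, glutamate, sucrose, fructose, arabinose), with
designed abundances strictly decreasing with niche size and the two
hydrolysis roles split between different species, so no isolate grows on
chitin while the community does.  Because every designed chain is complete
within its species and the only extracellular intermediates are the chitin
series, the ground-truth realized niche is exactly the union of
fundamentals plus chitin.

**Drafts and universal set.**  1–3 transport/catabolism/split reactions are
deleted per species (each breaks at least one designed growth phenotype);
the universal set is the union of all ground-truth reactions — identical
chemistry under one id deduplicates with widest bounds — plus mass-balanced
decoy reactions disconnected from biomass.  Because every deleted reaction
is in the universal set and reaction ids are shared across species for
identical chemistry, minimal gapfilling restores the designed chain and
post-gapfill concordance is 100% by construction, for any seed.

**Counts.**  Gene means are species-abundance-scaled log-normal weights
(σ = 1) over a default library of 10⁶ reads; counts are Gamma–Poisson
(negative binomial) with dispersion 0.1 by default; planted DEGs are
multiplied by the effect fold (default 4) in the second group; per-species
abundance shifts renormalise the community composition, so the observable
fraction fold is slightly below the raw shift unless the species is rare.
Defaults mirror the emulated study's shape: 8 species, 3 replicates, 2
time points; 5 metabolome replicates in the metabolite generator.

**Metabolites.**  Log-normal abundances (base exp(N(8, 1)), multiplicative
noise σ = 0.1) with the first `n_diff` metabolites scaled by the planted
fold in the second group.

What the generators do **not** emulate: sequencing depth variation between
samples beyond abundance composition, gene-length effects, count outliers,
batch effects, correlated gene expression, metabolite identification
ambiguity, and any kinetics (the metabolic toys are purely
stoichiometric).  Passing recovery tests therefore demonstrates the
correctness of the implementations under the stated noise models, not
robustness to every artefact of real data.

## Numerical conventions and degenerate inputs

- LP/MILP: HiGHS, deterministic; alternate optimal flux distributions are
  irrelevant because only the objective and the focal uptake flux are
  consumed downstream.
- Growth threshold comparison is strict (`>`), so an objective exactly at
  threshold is no-growth.
- `merge_mixed_bag` rejects duplicate reaction ids with conflicting
  stoichiometry (hard error) and conflicting metabolite compartments;
  identical duplicates collapse with widest bounds.
- All-zero species submatrices get size factors of 1 with a warning;
  all-zero genes are excluded from DE testing and reported untested.
- Problem sizes used by the test suite and the benchmark script (8 toy
  models × 12 sources, ≤ 1,600 genes, 100 metabolites, ≤ 20 seeds per
  property) were chosen so that each ground-truth effect is comfortably
  identifiable under the stated noise models with seconds-scale runtimes.

## Known limitations

- No flux variability analysis, loopless FBA or thermodynamic constraints;
  alternate-optima structure is not explored.
- Gapfilling minimises reaction count only (no candidate weighting) and
  does not consider negative phenotypes as constraints.
- The DE test's normal reference is approximate at 2 replicates per group;
  the suite exercises 3+.
- The SBML reader supports a flat subset (two compartments, species,
  reactions, fbc bounds) and rejects anything else loudly; it is an ingest
  convenience, not a general SBML implementation.
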