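"""Metatranscriptomic and metabolomic summary statistics.

Count matrices from a consortium metatranscriptome mix two signals: changes
in a species' share of the community and changes in its gene expression.
Normalisation is therefore applied within each species' gene set separately
(median-of-ratios size factors computed per species), so abundance shifts are
not misread as expression changes.  Differential expression between the two
time-point groups is a Wald test on a negative-binomial mean model with
method-of-moments dispersion, Benjamini–Hochberg adjusted; a gene is a DEG
iff adjusted P ≤ alpha and absolute fold change > min_fold.

Species relative abundances are per-sample fractions of total aligned reads;
metabolite differential abundance is a Welch t test on log abundances with
BH adjustment, reporting the ratio of group means as the fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TIME_POINTS = ("70h", "118h")


@dataclass
class ExpressionMatrix:
    """Gene × sample raw counts with sample metadata and a gene→species map."""

    counts: pd.DataFrame                      # genes × samples, nonnegative ints
    samples: pd.DataFrame                     # index sample_id; time_point, replicate
    gene_map: pd.Series                       # index gene_id -> species_id

    def validate(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.counts.columns.equals(self.samples.index):
            if set(self.counts.columns) != set(self.samples.index):
                raise ValueError("counts columns and sample metadata disagree")
            self.samples = self.samples.loc[self.counts.columns]
        unmapped = self.counts.index.difference(self.gene_map.index)
        if len(unmapped):
            raise ValueError(f"{len(unmapped)} genes missing from gene_map")
        for tp, group in self.samples.groupby("time_point"):
            if len(group) < 2:
                raise ValueError(f"time point {tp!r} has < 2 replicates")

    def species_of(self, genes) -> pd.Series:
        return self.gene_map.loc[genes]

    def group_columns(self, time_point: str) -> list[str]:
        return list(self.samples.index[self.samples["time_point"] == time_point])


@dataclass
class DEGResult:
    gene_id: str
    species_id: str
    base_mean: float
    log2_fold_change: float       # 118h vs 70h
    p_value: float
    adjusted_p: float
    is_deg: bool
    tested: bool = True


@dataclass
class AbundanceProfile:
    #: per-sample species fractions (species × samples); columns sum to 1
    fractions: pd.DataFrame
    #: per-(species, time_point): mean and sd of fractions
    group_stats: pd.DataFrame
    #: per species: fold change of group means (118h / 70h) and Welch p
    comparison: pd.DataFrame


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors for one species' gene submatrix.

    Reference = per-gene geometric mean across samples over genes expressed
    everywhere; a sample's factor is the median ratio of its counts to the
    reference.  All-zero submatrices get factors of 1 with a warning.
    """
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    usable = np.isfinite(log_arr).all(axis=1)
    if not usable.any():
        logger.warning("no gene with all-positive counts; size factors set to 1")
        return pd.Series(1.0, index=counts.columns)
    log_ref = log_arr[usable].mean(axis=1)
    factors = np.exp(np.median(log_arr[usable] - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def normalize_counts(matrix: ExpressionMatrix
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalise counts with size factors computed per species independently.

    Returns (normalized counts, size-factor table species × samples).
    """
    matrix.validate()
    normalized = pd.DataFrame(index=matrix.counts.index,
                              columns=matrix.counts.columns, dtype=float)
    factor_rows = {}
    for species, genes in matrix.gene_map.groupby(matrix.gene_map):
        idx = matrix.counts.index.intersection(genes.index)
        factors = size_factors(matrix.counts.loc[idx])
        normalized.loc[idx] = matrix.counts.loc[idx].div(factors, axis=1)
        factor_rows[species] = factors
    return normalized, pd.DataFrame(factor_rows).T


def _mom_dispersion(group1: np.ndarray, group2: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion (var = mu + alpha·mu²)."""
    m1, m2 = group1.mean(), group2.mean()
    v1, v2 = group1.var(ddof=1), group2.var(ddof=1)
    mu = (m1 + m2) / 2.0
    if mu <= 0:
        return 0.0
    return max(0.0, ((v1 + v2) / 2.0 - mu) / mu ** 2)


def _nb_wald(group1: np.ndarray, group2: np.ndarray,
             alpha_disp: float) -> tuple[float, float]:
    """Wald test of equal negative-binomial means; returns (log2 FC, p).

    ``alpha_disp`` is the dispersion to use; the log-ratio standard error
    follows from the delta method and a half-count offset stabilises zero
    groups.
    """
    n1, n2 = len(group1), len(group2)
    m1o, m2o = group1.mean() + 0.5, group2.mean() + 0.5
    log_ratio = np.log(m2o / m1o)
    se = np.sqrt((1.0 / m1o + alpha_disp) / n1 + (1.0 / m2o + alpha_disp) / n2)
    z = log_ratio / se
    p = 2.0 * stats.norm.sf(abs(z))
    return log_ratio / np.log(2.0), float(p)


def call_degs(matrix: ExpressionMatrix, alpha: float = 0.05,
              min_fold: float = 2.0) -> list[DEGResult]:
    """Per-gene differential expression, 118h vs 70h, on per-species
    normalised counts; BH-adjusted, filtered at (alpha, min_fold).

    Per-gene method-of-moments dispersions are floored at the genome-wide
    median dispersion, sharing information across genes so that genes whose
    few replicates happen to agree closely do not get an unrealistically
    small standard error.  Genes with zero counts in every sample are
    excluded from testing and reported with ``tested=False``.
    """
    normalized, _ = normalize_counts(matrix)
    cols1 = matrix.group_columns("70h")
    cols2 = matrix.group_columns("118h")
    if not cols1 or not cols2:
        raise ValueError("both time-point groups must be present")

    tested_groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    dispersions: dict[str, float] = {}
    for gene in normalized.index:
        if matrix.counts.loc[gene].sum() == 0:
            continue
        row = normalized.loc[gene]
        g1 = row[cols1].to_numpy(dtype=float)
        g2 = row[cols2].to_numpy(dtype=float)
        tested_groups[gene] = (g1, g2)
        dispersions[gene] = _mom_dispersion(g1, g2)
    central_disp = float(np.median(list(dispersions.values()))) \
        if dispersions else 0.0

    results: list[DEGResult] = []
    tested_idx: list[int] = []
    p_values: list[float] = []
    for gene in normalized.index:
        species = matrix.gene_map[gene]
        if gene not in tested_groups:
            results.append(DEGResult(gene, species, 0.0, 0.0, np.nan, np.nan,
                                     False, tested=False))
            continue
        g1, g2 = tested_groups[gene]
        l2fc, p = _nb_wald(g1, g2, max(dispersions[gene], central_disp))
        results.append(DEGResult(gene, species,
                                 float(np.concatenate([g1, g2]).mean()),
                                 float(l2fc), p, np.nan, False))
        tested_idx.append(len(results) - 1)
        p_values.append(p)

    if tested_idx:
        adjusted = multipletests(p_values, method="fdr_bh")[1]
        for i, padj in zip(tested_idx, adjusted):
            r = results[i]
            r.adjusted_p = max(float(padj), r.p_value)
            fold = 2.0 ** abs(r.log2_fold_change)
            r.is_deg = bool(r.adjusted_p <= alpha and fold > min_fold)
    return results


def degs_to_frame(results: list[DEGResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "species_id": [r.species_id for r in results],
            "base_mean": [r.base_mean for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "is_deg": [r.is_deg for r in results],
            "tested": [r.tested for r in results],
        }
    ).set_index("gene_id")


def deg_percentage(n_degs: int, n_genes: int) -> float:
    """Percentage of the genome that is differentially expressed,
    100·n_degs/n_genes rounded half-even to two decimals."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if not 0 <= n_degs <= n_genes:
        raise ValueError("need 0 <= n_degs <= n_genes")
    pct = Decimal(100 * n_degs) / Decimal(n_genes)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def abundance_profile(matrix: ExpressionMatrix) -> AbundanceProfile:
    """Species read fractions per sample, group mean ± sd, and the
    between-time-point fold change with a Welch t test per species."""
    matrix.validate()
    totals = matrix.counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total reads")
    species_sums = matrix.counts.groupby(matrix.gene_map).sum()
    fractions = species_sums.div(totals, axis=1)

    records = []
    comparisons = []
    cols = {tp: matrix.group_columns(tp) for tp in TIME_POINTS}
    for species in fractions.index:
        per_group = {}
        for tp in TIME_POINTS:
            values = fractions.loc[species, cols[tp]].to_numpy(dtype=float)
            per_group[tp] = values
            records.append({"species_id": species, "time_point": tp,
                            "mean": values.mean(),
                            "sd": values.std(ddof=1)})
        m70 = per_group["70h"].mean()
        m118 = per_group["118h"].mean()
        fold = np.inf if m70 == 0 else m118 / m70
        p = stats.ttest_ind(per_group["118h"], per_group["70h"],
                            equal_var=False).pvalue
        comparisons.append({"species_id": species, "fold_change": fold,
                            "p_value": float(p)})
    return AbundanceProfile(
        fractions=fractions,
        group_stats=pd.DataFrame(records).set_index(["species_id", "time_point"]),
        comparison=pd.DataFrame(comparisons).set_index("species_id"),
    )


def metabolite_diff(table: pd.DataFrame, groups: pd.Series,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-metabolite fold change (ratio of group means, second group over
    first) and BH-adjusted Welch t significance on log abundances.

    ``table`` is metabolite × sample; ``groups`` maps sample → group label
    with exactly two levels, each with ≥ 2 replicates; group order follows
    first appearance (e.g. 70h samples first, 118h second, giving the
    118h-over-70h fold).  Metabolites with any nonpositive abundance are
    excluded with a warning.
    """
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    cols = {lv: list(groups.index[groups == lv]) for lv in levels}
    for lv in levels:
        if len(cols[lv]) < 2:
            raise ValueError(f"group {lv!r} has < 2 replicates")

    rows = []
    p_values = []
    for metabolite in table.index:
        values = table.loc[metabolite]
        if (values <= 0).any():
            logger.warning("metabolite %s has nonpositive abundance, excluded",
                           metabolite)
            continue
        g1 = values[cols[levels[0]]].to_numpy(dtype=float)
        g2 = values[cols[levels[1]]].to_numpy(dtype=float)
        p = stats.ttest_ind(np.log(g2), np.log(g1), equal_var=False).pvalue
        rows.append({"metabolite": metabolite,
                     "fold_change": g2.mean() / g1.mean(),
                     "p_value": float(p)})
        p_values.append(float(p))
    frame = pd.DataFrame(rows).set_index("metabolite")
    if len(frame):
        frame["adjusted_p"] = multipletests(p_values, method="fdr_bh")[1]
        frame["significant"] = frame["adjusted_p"] <= alpha
    else:
        frame["adjusted_p"] = []
        frame["significant"] = []
    return frame


def category_coverage(annotations: dict[str, set[str]],
                      expressed_genes: dict[str, set[str]],
                      categories: dict[str, set[str]]) -> pd.DataFrame:
    """Genomic-potential vs expressed fraction of each functional category.

    ``annotations`` maps species → set of terms in its genome,
    ``expressed_genes`` maps species → set of terms actually expressed;
    a category's fraction is the share of its term set present.
    """
    if not categories:
        raise ValueError("categories must be nonempty")
    rows = []
    for species in sorted(annotations):
        genome = annotations[species]
        expressed = expressed_genes.get(species, set())
        for category, terms in sorted(categories.items()):
            rows.append({
                "species_id": species,
                "category": category,
                "genomic_fraction": len(genome & terms) / len(terms),
                "expressed_fraction": len(expressed & terms) / len(terms),
            })
    return pd.DataFrame(rows).set_index(["species_id", "category"])
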