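"""Omics summaries: normalization, DEG calling, abundances, metabolites."""

import numpy as np
import pandas as pd
import pytest

from crossfeed.omics import (
    ExpressionMatrix,
    abundance_profile,
    call_degs,
    category_coverage,
    deg_percentage,
    degs_to_frame,
    metabolite_diff,
    normalize_counts,
    size_factors,
)
from crossfeed.synth import gen_counts, gen_metabolites


def make_matrix(counts: dict, species: dict, n_reps=2) -> ExpressionMatrix:
    sample_ids = [f"{tp}_r{r}" for tp in ("70h", "118h")
                  for r in range(1, n_reps + 1)]
    frame = pd.DataFrame(counts, index=sample_ids).T
    samples = pd.DataFrame(
        {"time_point": [s.split("_")[0] for s in sample_ids],
         "replicate": [int(s.split("_r")[1]) for s in sample_ids]},
        index=sample_ids)
    gene_map = pd.Series(species)
    return ExpressionMatrix(counts=frame, samples=samples, gene_map=gene_map)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 40, 7], "s2": [10, 40, 7]},
                              index=["g1", "g2", "g3"])
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_gets_factor_two(self):
        base = np.array([10, 40, 7, 100, 23])
        counts = pd.DataFrame({"s1": base, "s2": 2 * base},
                              index=[f"g{i}" for i in range(5)])
        factors = size_factors(counts)
        # factors are defined up to the geometric-mean reference; their
        # ratio is what matters
        assert factors["s2"] / factors["s1"] == pytest.approx(2.0)

    def test_all_zero_submatrix_warns_and_returns_ones(self, caplog):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [0, 0]},
                              index=["g1", "g2"])
        with caplog.at_level("WARNING"):
            factors = size_factors(counts)
        assert np.allclose(factors, 1.0)

    def test_matches_pydeseq2_reference(self):
        """Dual route: our median-of-ratios vs pydeseq2's fit on one species."""
        from pydeseq2.dds import DeseqDataSet

        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(50, size=(30, 6)) + 1,
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(6)])
        metadata = pd.DataFrame(
            {"condition": ["a"] * 3 + ["b"] * 3}, index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=metadata,
                           design="~condition", quiet=True)
        dds.fit_size_factors()
        ours = size_factors(counts)
        assert np.allclose(ours.to_numpy(),
                           dds.obs["size_factors"].to_numpy(), rtol=1e-6)


class TestNormalizeCounts:
    def test_species_confounded_shift_leaves_other_species_unchanged(self):
        # tripling species-A genes in one sample must not move species-B
        # factors: normalization is per species
        counts = {
            "a_g1": [30, 10, 10, 10], "a_g2": [90, 30, 30, 30],
            "b_g1": [20, 20, 20, 20], "b_g2": [50, 50, 50, 50],
        }
        species = {"a_g1": "A", "a_g2": "A", "b_g1": "B", "b_g2": "B"}
        matrix = make_matrix(counts, species)
        normalized, factors = normalize_counts(matrix)
        assert np.allclose(factors.loc["B"], 1.0)
        # factors are relative to the geometric-mean reference; the shifted
        # sample's factor is 3x the others'
        assert factors.loc["A", "70h_r1"] / factors.loc["A", "70h_r2"] == \
            pytest.approx(3.0)
        # after normalization the species-A shift is gone: every sample
        # carries the same normalized value per gene
        for gene in ("a_g1", "a_g2"):
            assert np.allclose(normalized.loc[gene],
                               normalized.loc[gene].iloc[0])

    def test_scaled_sample_normalizes_back_to_identity(self):
        counts = {"a_g1": [10, 20, 10, 10], "a_g2": [40, 80, 40, 40],
                  "a_g3": [7, 14, 7, 7], "a_g4": [100, 200, 100, 100],
                  "a_g5": [23, 46, 23, 23]}
        species = {g: "A" for g in counts}
        normalized, factors = normalize_counts(make_matrix(counts, species))
        assert factors.loc["A", "70h_r2"] / factors.loc["A", "70h_r1"] == \
            pytest.approx(2.0)
        assert np.allclose(normalized["70h_r2"], normalized["70h_r1"])


class TestCallDegs:
    def test_planted_degs_recovered_with_fdr_control(self):
        """Planted 4-fold effects, NB dispersion 0.1: empirical FDR ≤ 0.1."""
        matrix, truth = gen_counts(effect_fold=4.0, dispersion=0.1, seed=7)
        results = call_degs(matrix, alpha=0.05, min_fold=2.0)
        called = {r.gene_id for r in results if r.is_deg}
        planted = set(truth["planted_degs"])
        assert called, "no DEGs recovered at all"
        fdr = len(called - planted) / len(called)
        assert fdr <= 0.1
        # the majority of planted genes are found
        assert len(called & planted) / len(planted) > 0.5

    def test_fold_below_two_is_not_deg_despite_tiny_p(self):
        # exact 1.9-fold shift with no replicate noise: p is minute but the
        # fold filter rejects the gene
        counts = {"a_g1": [1000, 1000, 1900, 1900],
                  "a_g2": [500, 500, 500, 500],
                  "a_g3": [80, 80, 80, 80]}
        species = {g: "A" for g in counts}
        results = call_degs(make_matrix(counts, species))
        by_gene = {r.gene_id: r for r in results}
        assert by_gene["a_g1"].adjusted_p < 0.05
        assert 2.0 ** abs(by_gene["a_g1"].log2_fold_change) < 2.0
        assert not by_gene["a_g1"].is_deg

    def test_null_matrix_yields_almost_no_calls(self):
        """Type-I control: ≤ 2 false calls per 1,000 genes, seed-averaged."""
        false_calls = []
        for seed in range(5):
            matrix, _ = gen_counts(n_planted_degs=0, n_genes_per_species=125,
                                   seed=seed)
            false_calls.append(sum(r.is_deg for r in call_degs(matrix)))
        assert np.mean(false_calls) <= 2.0

    def test_all_zero_gene_reported_untested(self):
        counts = {"a_g1": [0, 0, 0, 0], "a_g2": [10, 12, 30, 28],
                  "a_g3": [5, 5, 5, 5]}
        species = {g: "A" for g in counts}
        results = call_degs(make_matrix(counts, species))
        by_gene = {r.gene_id: r for r in results}
        assert not by_gene["a_g1"].tested
        assert not by_gene["a_g1"].is_deg
        assert by_gene["a_g2"].tested

    def test_bh_adjustment_monotone_and_bounded(self):
        matrix, _ = gen_counts(seed=2)
        tested = [r for r in call_degs(matrix) if r.tested]
        frame = pd.DataFrame({"p": [r.p_value for r in tested],
                              "padj": [r.adjusted_p for r in tested]})
        assert (frame["padj"] <= 1.0).all()
        assert (frame["padj"] >= frame["p"] - 1e-12).all()
        ordered = frame.sort_values("p")
        assert ordered["padj"].is_monotonic_increasing

    def test_deg_flag_equals_brute_force_filter(self):
        matrix, _ = gen_counts(seed=4)
        frame = degs_to_frame(call_degs(matrix, alpha=0.05, min_fold=2.0))
        tested = frame[frame["tested"]]
        oracle = (tested["adjusted_p"] <= 0.05) & \
            (2.0 ** tested["log2_fold_change"].abs() > 2.0)
        assert (tested["is_deg"] == oracle).all()


class TestDegPercentage:
    @pytest.mark.parametrize("n_degs,n_genes,expected", [
        (3909, 7526, 51.94),
        (0, 6281, 0.00),
        (48, 7143, 0.67),
    ])
    def test_printed_table_arithmetic(self, n_degs, n_genes, expected):
        assert deg_percentage(n_degs, n_genes) == expected

    def test_half_even_rounding(self):
        # 0.125% rounds to 0.12 under banker's rounding
        assert deg_percentage(1, 800) == 0.12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            deg_percentage(1, 0)
        with pytest.raises(ValueError):
            deg_percentage(5, 3)


class TestAbundanceProfile:
    def test_single_species_fraction_is_one(self):
        counts = {"a_g1": [10, 20, 30, 40], "a_g2": [5, 5, 5, 5]}
        species = {g: "A" for g in counts}
        profile = abundance_profile(make_matrix(counts, species))
        assert np.allclose(profile.fractions.loc["A"], 1.0)

    def test_three_to_one_split_gives_expected_fractions(self):
        counts = {"a_g1": [30, 30, 30, 30], "b_g1": [10, 10, 10, 10]}
        species = {"a_g1": "A", "b_g1": "B"}
        profile = abundance_profile(make_matrix(counts, species))
        assert np.allclose(profile.fractions.loc["A"], 0.75)
        assert np.allclose(profile.fractions.loc["B"], 0.25)
        assert profile.comparison.loc["A", "fold_change"] == pytest.approx(1.0)

    def test_fractions_sum_to_one_per_sample(self):
        matrix, _ = gen_counts(seed=9)
        profile = abundance_profile(matrix)
        assert np.allclose(profile.fractions.sum(axis=0), 1.0, atol=1e-9)

    def test_planted_eightfold_shift_recovered(self):
        """An 8-fold abundance shift of a rare species is detected with the
        fold estimate in [6, 10] and p < 0.05, averaged over seeds."""
        abundances = {"a": 0.40, "b": 0.25, "c": 0.15, "d": 0.10,
                      "e": 0.05, "f": 0.03, "g": 0.018, "h": 0.002}
        folds, pvals = [], []
        for seed in range(10):
            matrix, _ = gen_counts(abundance_shifts={"h": 8.0},
                                   species_abundances=abundances, seed=seed)
            profile = abundance_profile(matrix)
            folds.append(profile.comparison.loc["h", "fold_change"])
            pvals.append(profile.comparison.loc["h", "p_value"])
        assert 6.0 <= np.mean(folds) <= 10.0
        assert np.mean(pvals) < 0.05

    def test_zero_total_reads_rejected(self):
        counts = {"a_g1": [0, 10, 10, 10]}
        species = {"a_g1": "A"}
        with pytest.raises(ValueError):
            abundance_profile(make_matrix(counts, species))


class TestMetaboliteDiff:
    @staticmethod
    def groups(n=5):
        ids = [f"{tp}_r{r}" for tp in ("70h", "118h") for r in range(1, n + 1)]
        return pd.Series([s.split("_")[0] for s in ids], index=ids)

    def test_identical_groups_fold_one_no_calls(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(5, 0.2, size=5)
        table = pd.DataFrame(
            np.tile(values[:, None], 10),
            index=[f"m{i}" for i in range(5)],
            columns=self.groups().index)
        diff = metabolite_diff(table, self.groups())
        assert np.allclose(diff["fold_change"], 1.0)
        assert not diff["significant"].any()

    def test_planted_sixfold_shift_flagged_with_fold_recovered(self):
        table, groups, truth = gen_metabolites(
            n_metabolites=100, n_diff=1, fold=6.5, sigma=0.1, n_reps=5,
            seed=3)
        diff = metabolite_diff(table, groups)
        planted = truth["shifted"][0]
        assert diff.loc[planted, "significant"]
        assert 5.5 <= diff.loc[planted, "fold_change"] <= 7.5

    def test_null_calls_rare_across_seeds(self):
        calls = []
        for seed in range(5):
            table, groups, _ = gen_metabolites(n_diff=0, seed=seed)
            calls.append(int(metabolite_diff(table, groups)
                             ["significant"].sum()))
        assert np.mean(calls) <= 1.0

    def test_single_replicate_groups_rejected(self):
        table, groups, _ = gen_metabolites(n_reps=1, seed=0)
        with pytest.raises(ValueError):
            metabolite_diff(table, groups)

    def test_nonpositive_abundances_excluded(self, caplog):
        table, groups, _ = gen_metabolites(n_metabolites=3, n_diff=0, seed=0)
        table.iloc[0, 0] = 0.0
        with caplog.at_level("WARNING"):
            diff = metabolite_diff(table, groups)
        assert len(diff) == 2


class TestCategoryCoverage:
    def test_counting_example(self):
        categories = {"cat": {f"t{i}" for i in range(10)}}
        annotations = {"sp": {"t0", "t1", "t2", "t3"}}
        expressed = {"sp": {"t0", "t1"}}
        frame = category_coverage(annotations, expressed, categories)
        row = frame.loc[("sp", "cat")]
        assert row["genomic_fraction"] == pytest.approx(0.4)
        assert row["expressed_fraction"] == pytest.approx(0.2)

    def test_expressed_subset_never_exceeds_genomic(self):
        rng = np.random.default_rng(3)
        terms = [f"t{i}" for i in range(20)]
        categories = {f"c{j}": set(rng.choice(terms, 8, replace=False))
                      for j in range(4)}
        genome = set(rng.choice(terms, 12, replace=False))
        expressed = set(rng.choice(sorted(genome), 5, replace=False))
        frame = category_coverage({"sp": genome}, {"sp": expressed},
                                  categories)
        assert (frame["expressed_fraction"] <=
                frame["genomic_fraction"] + 1e-12).all()

    def test_full_category_gives_both_fractions_one(self):
        categories = {"cat": {"t1", "t2"}}
        frame = category_coverage({"sp": {"t1", "t2"}}, {"sp": {"t1", "t2"}},
                                  categories)
        assert (frame.loc[("sp", "cat")] == 1.0).all()

    def test_empty_categories_rejected(self):
        with pytest.raises(ValueError):
            category_coverage({"sp": set()}, {"sp": set()}, {})
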