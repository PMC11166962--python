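import dataclasses

import numpy as np
import pandas as pd
import pytest

from crosstrait import ConfigurationError
from crosstrait.enrichment import EnrichmentAnalysis, enrich, read_gmt, write_gmt
from crosstrait.locus import select_suggestive_snps, filter_by_traits
from crosstrait.synthetic import (
    GWAS_P_THRESHOLD,
    SimulationConfig,
    _gene_key,
    generate_annotations,
    generate_dataset,
    generate_eqtl_table,
    generate_expression,
    generate_gwas_table,
)


def _records_from_frame(frame: pd.DataFrame):
    import io

    from crosstrait.locus import read_associations

    return read_associations(io.StringIO(frame.to_csv(sep="\t", index=False)))


class TestGwasGenerator:
    def test_exact_significant_count(self):
        config = SimulationConfig(seed=1, n_snps_per_trait=100, frac_significant=0.5)
        frame = generate_gwas_table(config, ["only trait"])
        trait_rows = frame[frame["DISEASE/TRAIT"] == "only trait"]
        n_sig = (trait_rows["P-VALUE"].astype(float) < GWAS_P_THRESHOLD).sum()
        assert n_sig == 50

    def test_determinism(self):
        config = SimulationConfig(seed=1, n_snps_per_trait=50)
        f1 = generate_gwas_table(config, ["t"])
        f2 = generate_gwas_table(config, ["t"])
        pd.testing.assert_frame_equal(f1, f2)

    def test_zero_significant_fraction_selects_nothing(self):
        config = SimulationConfig(seed=2, n_snps_per_trait=40, frac_significant=0.0)
        frame = generate_gwas_table(config, ["t"])
        records = filter_by_traits(_records_from_frame(frame), ["t"])
        assert len(select_suggestive_snps(records)) == 0

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="frac_significant"):
            generate_gwas_table(
                SimulationConfig(seed=0, frac_significant=1.5), ["t"]
            )

    def test_empty_trait_labels_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_gwas_table(SimulationConfig(), [])


class TestEqtlGenerator:
    def test_planted_shared_genes_exact(self, small_config):
        _, truth = generate_eqtl_table(small_config)
        a, b = truth.trait_labels
        shared = set(truth.gene_sets[a]) & set(truth.gene_sets[b])
        assert shared == set(truth.shared_genes)
        assert len(shared) == small_config.planted_shared_genes

    def test_zero_shared_genes_possible(self):
        config = dataclasses.replace(SimulationConfig(seed=3), planted_shared_genes=0)
        _, truth = generate_eqtl_table(config)
        a, b = truth.trait_labels
        assert not set(truth.gene_sets[a]) & set(truth.gene_sets[b])

    def test_oversized_shared_request_rejected(self):
        config = dataclasses.replace(
            SimulationConfig(), planted_shared_genes=500
        )
        with pytest.raises(ConfigurationError, match="planted_shared_genes"):
            generate_eqtl_table(config)

    def test_pairs_exceeding_significant_snps_rejected(self):
        config = SimulationConfig(seed=0, n_snps_per_trait=50, frac_significant=0.5,
                                  n_eqtl_pairs_a=30, n_genes_a=20)
        with pytest.raises(ConfigurationError, match="n_eqtl_pairs"):
            generate_eqtl_table(config)

    def test_determinism(self, small_config):
        f1, _ = generate_eqtl_table(small_config)
        f2, _ = generate_eqtl_table(small_config)
        pd.testing.assert_frame_equal(f1, f2)


class TestExpressionGenerator:
    def test_determinism(self):
        config = SimulationConfig(seed=4, n_samples=20, module_spec=((5, 0.7),),
                                  n_background_genes=10)
        m1, _ = generate_expression(config, ["S1"])
        m2, _ = generate_expression(config, ["S1"])
        pd.testing.assert_frame_equal(m1, m2)

    def test_too_few_samples_rejected(self):
        config = SimulationConfig(seed=0, n_samples=2)
        with pytest.raises(ConfigurationError, match="n_samples"):
            generate_expression(config, ["S1"])

    def test_invalid_rho_rejected(self):
        config = SimulationConfig(seed=0, module_spec=((5, 1.0),))
        with pytest.raises(ConfigurationError, match="rho"):
            generate_expression(config, ["S1"])

    def test_each_module_contains_a_seed(self):
        config = SimulationConfig(seed=5, n_samples=30,
                                  module_spec=((4, 0.5), (5, 0.5)), n_background_genes=5)
        _, modules = generate_expression(config, ["S1", "S2", "S3"])
        seeds = {"S1", "S2", "S3"}
        for module in modules:
            assert module & seeds

    def test_global_null_keeps_family_wise_error_controlled(self):
        """rho=0 everywhere: across seeded runs the chance of any Bonferroni
        edge stays near the nominal 5% level."""
        from scipy.stats import binom

        from crosstrait.coexpression import CoexpressionScreen

        n_runs, hits = 60, 0
        for run in range(n_runs):
            config = SimulationConfig(seed=1000 + run, n_samples=40,
                                      module_spec=(), n_background_genes=60)
            mat, _ = generate_expression(config, [f"SEED{i}" for i in range(4)])
            res = CoexpressionScreen(mat, [f"SEED{i}" for i in range(4)]).fit(alpha=0.05)
            hits += len(res.retained) > 0
        assert hits <= binom.isf(0.01, n_runs, 0.05)


class TestAnnotationGenerator:
    def test_gmt_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "x.gmt"
        write_gmt(small_dataset.terms, path)
        back = read_gmt(path)
        assert {(t.term_id, t.members) for t in back} == {
            (t.term_id, t.members) for t in small_dataset.terms
        }

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_annotations(SimulationConfig(), [])

    def test_term_sizes_within_range(self, small_dataset, small_config):
        lo, hi = small_config.term_size_range
        for term in small_dataset.terms:
            assert lo <= len(term.members) <= hi

    def test_planted_term_enriched_in_planted_set(self):
        """80%-planted terms come out enriched (p < 0.01) in >= 95% of seeded runs."""
        ok = 0
        runs = 100
        for seed in range(runs):
            config = SimulationConfig(seed=seed)
            _, truth = generate_eqtl_table(config)
            a_label = truth.trait_labels[0]
            planted_set = sorted(truth.gene_sets[a_label])
            universe = sorted(
                set(planted_set) | {_gene_key(i) for i in range(config.n_annotation_universe)}
            )
            terms, planted_ids = generate_annotations(
                config, universe, planted_gene_sets=[planted_set]
            )
            results = {r.term.term_id: r for r in enrich(
                set(planted_set), terms, universe
            )}
            ok += all(results[tid].p < 0.01 for tid in planted_ids)
        assert ok / runs >= 0.95

    def test_uniform_terms_have_unit_enrichment_on_average(self):
        factors = []
        for seed in range(20):
            config = SimulationConfig(
                seed=seed, planted_enriched_terms=0, n_terms=20,
            )
            universe = [_gene_key(i) for i in range(config.n_annotation_universe)]
            terms, _ = generate_annotations(config, universe)
            rng = np.random.default_rng(seed)
            query = set(rng.choice(universe, size=400, replace=False).tolist())
            factors += [r.enrichment_factor for r in enrich(query, terms, universe)]
        from scipy.stats import sem

        assert abs(np.mean(factors) - 1.0) < 3 * sem(factors)


class TestDataset:
    def test_fully_deterministic(self, small_config, small_dataset):
        again = generate_dataset(small_config)
        pd.testing.assert_frame_equal(again.gwas, small_dataset.gwas)
        pd.testing.assert_frame_equal(again.eqtl, small_dataset.eqtl)
        pd.testing.assert_frame_equal(again.expression, small_dataset.expression)
        assert again.terms == small_dataset.terms
        assert again.modules == small_dataset.modules

    def test_written_files_exist_and_parse(self, small_inputs):
        from crosstrait.coexpression import read_expression
        from crosstrait.eqtl import read_eqtl_table
        from crosstrait.locus import read_associations

        assert read_associations(small_inputs["gwas"])
        assert read_eqtl_table(small_inputs["eqtl"])
        assert read_expression(small_inputs["universe"].parent / "expression.tsv").shape[0] > 0
        assert read_gmt(small_inputs["gmt"])
        assert small_inputs["truth"].exists()

    def test_expanded_sets_cover_eqtl_genes_and_module_comembers(self, small_dataset):
        truth = small_dataset.eqtl_truth
        for label in truth.trait_labels:
            expanded = small_dataset.expanded_sets[label]
            assert set(truth.gene_sets[label]) <= expanded
            for module in small_dataset.modules:
                if module & set(truth.gene_sets[label]):
                    assert module <= expanded
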