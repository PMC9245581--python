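"""Generators: determinism, null calibration, planted-effect structure."""

import numpy as np
import pytest
from scipy import stats

from metasoil import synthetic
from metasoil.genotype_qc import single_snp_association
from metasoil.types import SimulationConfig


class TestSimulateGenotypes:
    def test_deterministic_given_seed(self, tiny_config):
        a, ta = synthetic.simulate_genotypes(tiny_config)
        b, tb = synthetic.simulate_genotypes(tiny_config)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.phenotype, b.phenotype)
        assert ta.epistatic_pairs == tb.epistatic_pairs

    def test_requested_counts_and_coding(self, tiny_config):
        study, _ = synthetic.simulate_genotypes(tiny_config)
        assert study.phenotype.sum() == tiny_config.n_cases
        assert (study.phenotype == 0).sum() == tiny_config.n_controls
        assert set(np.unique(study.genotypes)) <= {0, 1, 2}
        maf = study.snp_table["maf"]
        assert ((maf >= 0) & (maf <= 0.5)).all()

    def test_null_model_gives_uniform_association_p(self):
        """With no planted pairs the phenotype is independent of every SNP."""
        cfg = SimulationConfig(
            n_cases=400, n_controls=400, n_snps=2000, n_epistatic_pairs=0, seed=3
        )
        study, truth = synthetic.simulate_genotypes(cfg)
        assert truth.epistatic_pairs == []
        p = single_snp_association(study)["p"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_planted_pairs_are_epistatic_not_marginal(self):
        """Interaction z is large while single-SNP z stays small.

        Direct logistic fits on the simulated draws are the oracle: planted
        SNPs must carry their phenotype information in the product term
        only (mean marginal |z| < 2, mean interaction |z| > 3 over seeds).
        """
        import statsmodels.api as sm

        marg, inter = [], []
        for seed in range(20):
            cfg = SimulationConfig(
                n_cases=400, n_controls=400, n_snps=12, n_epistatic_pairs=1,
                maf_range=(0.3, 0.3), interaction_odds_ratio=3.0,
                marginal_effect=0.0, seed=seed,
            )
            study, truth = synthetic.simulate_genotypes(cfg)
            idx = {s: k for k, s in enumerate(study.snp_ids)}
            y = study.phenotype
            g = study.genotypes.astype(float)
            (a, b), = truth.epistatic_pairs or [(None, None)]
            i, j = idx[a], idx[b]
            for k in (i, j):
                X = np.column_stack([np.ones(len(y)), g[:, k]])
                marg.append(abs(sm.Logit(y, X).fit(disp=0).tvalues[1]))
            X = np.column_stack([np.ones(len(y)), g[:, i], g[:, j], g[:, i] * g[:, j]])
            inter.append(abs(sm.Logit(y, X).fit(disp=0).tvalues[3]))
        assert np.mean(marg) < 2.0
        assert np.mean(inter) > 3.0

    def test_unreachable_counts_raise(self, monkeypatch):
        """A huge marginal effect makes controls too rare to collect."""
        monkeypatch.setattr(synthetic, "_MAX_BATCHES", 1)
        cfg = SimulationConfig(
            n_cases=400, n_controls=400, n_snps=10, n_epistatic_pairs=1,
            interaction_odds_ratio=1.0, marginal_effect=30.0,
            maf_range=(0.5, 0.5), seed=0,
        )
        with pytest.raises(RuntimeError, match="n_controls"):
            synthetic.simulate_genotypes(cfg)


class TestSimulateExpression:
    def test_deterministic(self, tiny_config):
        a, ta = synthetic.simulate_expression(tiny_config)
        b, tb = synthetic.simulate_expression(tiny_config)
        assert a.values.equals(b.values)
        assert ta.true_regulons == tb.true_regulons

    def test_roles_and_truth_consistency(self, tiny_config):
        expr, truth = synthetic.simulate_expression(tiny_config)
        genes = set(expr.genes)
        assert truth.dysregulated_genes <= genes
        assert truth.hazard_gene_set <= genes
        assert truth.stemness_genes <= genes
        for tf, targets in truth.true_regulons.items():
            assert tf in genes and targets <= genes
        assert expr.roles.value_counts()["tumour"] == tiny_config.n_tumour_samples

    def test_null_shift_calibrates_expression_index(self):
        """With no dysregulation the tumour index sits at the |Z|>1.96 tail."""
        from metasoil.expression import expression_index, zscore_vs_reference

        cfg = SimulationConfig(
            n_genes=400, n_tfs=2, regulon_size_range=(2, 3), n_dysregulated=0,
            dysregulation_shift=0.0, n_control_samples=150, n_tumour_samples=150,
            seed=11,
        )
        expr, _ = synthetic.simulate_expression(cfg)
        idx = expression_index(zscore_vs_reference(expr, "tumour", "control"))
        assert abs(idx["index"].mean() - 0.05) < 0.01

    def test_planted_edge_dominates_pairwise_mi(self):
        """At tiny regulon noise the TF is its target's best MI partner."""
        from metasoil.regulatory import mutual_information

        cfg = SimulationConfig(
            n_genes=40, n_tfs=2, regulon_size_range=(3, 3), n_dysregulated=0,
            regulon_noise_sd=0.05, n_control_samples=10, n_tumour_samples=120,
            n_metastasis_samples=10, seed=5,
        )
        expr, truth = synthetic.simulate_expression(cfg)
        tumour = expr.samples_with_role("tumour")
        mat = expr.values[tumour]
        tf = sorted(truth.true_regulons)[0]
        target = sorted(truth.true_regulons[tf])[0]
        mi_true = mutual_information(mat.loc[tf], mat.loc[target])
        others = [
            mutual_information(mat.loc[g], mat.loc[target])
            for g in expr.genes
            if g not in (tf, target)
        ]
        assert mi_true == pytest.approx(max([mi_true] + others))

    def test_infeasible_regulons_raise(self):
        with pytest.raises(ValueError, match="infeasible"):
            synthetic.simulate_expression(
                SimulationConfig(n_genes=20, n_tfs=5, regulon_size_range=(10, 10))
            )


class TestSimulateSurvival:
    def test_deterministic_and_censoring_extremes(self, tiny_config):
        expr, truth = synthetic.simulate_expression(tiny_config)
        a = synthetic.simulate_survival(expr, truth, tiny_config)
        b = synthetic.simulate_survival(expr, truth, tiny_config)
        assert a.equals(b)

        from dataclasses import replace

        all_cens = replace(tiny_config, censoring_rate=1.0)
        tbl = synthetic.simulate_survival(expr, truth, all_cens)
        assert (tbl["event"] == 0).all()
        from metasoil.survival import km_curve

        km = km_curve(tbl["time"].to_numpy(), tbl["event"].to_numpy())
        assert (km["survival"] == 1.0).all()

    @pytest.mark.parametrize(
        "coef,expect_signif", [(0.0, False), (1.0, True)]
    )
    def test_hazard_coupling_drives_logrank(self, coef, expect_signif):
        """Null hazard leaves the split non-significant; coef=1 separates it."""
        from dataclasses import replace

        from metasoil.survival import score_and_split

        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_genes=60, n_tfs=2, regulon_size_range=(2, 3), n_dysregulated=5,
                n_control_samples=10, n_tumour_samples=300, n_metastasis_samples=5,
                gene_set_hazard_coef=coef, censoring_rate=0.2, seed=seed,
            )
            expr, truth = synthetic.simulate_expression(cfg)
            surv = synthetic.simulate_survival(expr, truth, cfg)
            (stat, p), _ = score_and_split(expr, truth.hazard_gene_set, surv)
            hits += p < 0.05
        if expect_signif:
            assert hits >= 0.9 * n_seeds
        else:
            assert (n_seeds - hits) >= 0.9 * n_seeds


def test_generator_streams_are_independent(tiny_config):
    """Running one generator never perturbs another's output."""
    expr_a, _ = synthetic.simulate_expression(tiny_config)
    synthetic.simulate_genotypes(tiny_config)
    expr_b, _ = synthetic.simulate_expression(tiny_config)
    assert expr_a.values.equals(expr_b.values)


def test_write_study_emits_plain_text_fixtures(tmp_path, tiny_config):
    paths = synthetic.write_study(tmp_path, tiny_config)
    for key in ("expression", "samples", "survival", "annotation", "tfs", "truth"):
        assert (tmp_path / paths[key].split("/")[-1]).exists()
    from metasoil import plink

    study = plink.read_bed(paths["bfile"])
    assert study.n_snps == tiny_config.n_snps
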