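"""QC filters, HWE exact test, trend test, LD pruning, ReliefF, MAF summary."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metasoil import genotype_qc as qc
from tests.conftest import make_study


def hwe_exact_oracle(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact-rational enumeration of the Levene-Haldane two-sided p."""
    from fractions import Fraction

    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n == 0 or n_minor == 0 or n_minor == 2 * n:
        return 1.0
    rare = min(n_minor, 2 * n - n_minor)
    probs = {}
    total = Fraction(0)
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        w = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(h) * math.factorial(hr) * math.factorial(hc),
        )
        probs[h] = w
        total += w
    obs = probs[n_het]
    p = sum(w for w in probs.values() if w <= obs)
    return float(Fraction(p, total))


class TestHweExact:
    @pytest.mark.parametrize(
        "het,hom_minor,hom_major,expected",
        [
            (0, 0, 100, 1.0),  # monomorphic boundary
            (50, 25, 25, None),  # balanced table, oracle-checked
            (0, 50, 50, None),  # maximal disequilibrium
        ],
    )
    def test_matches_exact_enumeration(self, het, hom_minor, hom_major, expected):
        p = qc.hwe_exact_p(het, hom_minor, hom_major)
        oracle = hwe_exact_oracle(het, hom_minor, hom_major)
        assert p == pytest.approx(oracle, rel=1e-9)
        if expected is not None:
            assert p == pytest.approx(expected)

    def test_equilibrium_table_is_retained_at_1e6(self):
        assert qc.hwe_exact_p(50, 25, 25) > 1e-6

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        het=st.integers(0, 80),
        hom_minor=st.integers(0, 60),
        hom_major=st.integers(0, 60),
    )
    def test_enumeration_property(self, het, hom_minor, hom_major):
        """Gamma-ln implementation equals exact rational enumeration, n<=200."""
        p = qc.hwe_exact_p(het, hom_minor, hom_major)
        assert 0 <= p <= 1
        assert p == pytest.approx(hwe_exact_oracle(het, hom_minor, hom_major), rel=1e-9)


class TestApplyQc:
    def test_callrate_thresholds_and_report(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, size=(100, 10)).astype(np.int8)
        g[:11, 3] = -1  # 11% missing -> below the 0.90 call-rate threshold
        study = make_study(g, np.r_[np.ones(50), np.zeros(50)])
        out, report = qc.apply_qc(study)
        assert report.snps_removed_callrate == 1
        assert out.n_snps == 9
        assert "rs3" not in out.snp_ids

    def test_monomorphic_snp_retained(self):
        g = np.zeros((60, 3), dtype=np.int8)
        g[:, 1] = np.random.default_rng(1).binomial(2, 0.4, 60)
        study = make_study(g, np.r_[np.ones(30), np.zeros(30)])
        out, report = qc.apply_qc(study)
        assert "rs0" in out.snp_ids  # HWE p = 1 for the constant SNP
        assert report.snps_removed_hwe == 0

    def test_idempotent(self):
        # sparse missingness (2%): no sample or SNP straddles the 90%
        # call-rate boundary, so a second QC pass must be a no-op
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.2, size=(80, 20)).astype(np.int8)
        g[rng.random(g.shape) < 0.02] = -1
        study = make_study(g, np.r_[np.ones(40), np.zeros(40)])
        once, _ = qc.apply_qc(study)
        twice, rep = qc.apply_qc(once)
        assert np.array_equal(once.genotypes, twice.genotypes)
        assert rep.snps_removed_callrate == rep.snps_removed_hwe == 0


class TestTrendTest:
    def test_printed_table_value(self):
        """Cochran-Armitage on cases (10,20,10) / controls (30,10,0).

        Frozen from the direct formula: U = sum w (r - R n / N) = 15,
        Var = (R/N)(1-R/N)(sum w^2 n - (sum w n)^2/N) = 9.6875,
        chi2 = U^2/Var = 23.22580645.
        """
        g = np.array([0] * 10 + [1] * 20 + [2] * 10 + [0] * 30 + [1] * 10)
        y = np.r_[np.ones(40), np.zeros(40)]
        study = make_study(g[:, None], y)
        table = qc.single_snp_association(study)
        assert table["statistic"].iloc[0] == pytest.approx(225 / 9.6875, rel=1e-12)

    def test_constant_snp_and_flagging(self):
        g = np.column_stack([np.ones(40), np.random.default_rng(0).binomial(2, 0.3, 40)])
        study = make_study(g, np.r_[np.ones(20), np.zeros(20)])
        table = qc.single_snp_association(study)
        assert table["statistic"].iloc[0] == 0
        assert table["p"].iloc[0] == 1.0
        assert not table["genome_wide_significant"].any()

    def test_single_class_phenotype_fails(self):
        study = make_study(np.zeros((10, 2), dtype=np.int8), np.ones(10))
        with pytest.raises(ValueError):
            qc.single_snp_association(study)


class TestLdPrune:
    def test_duplicated_column_keeps_one(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.4, 200).astype(np.int8)
        g = np.column_stack([base, base, rng.binomial(2, 0.4, 200)])
        study = make_study(g, np.r_[np.ones(100), np.zeros(100)])
        out = qc.ld_prune(study)
        assert out.n_snps == 2

    def test_high_r2_pair_loses_lower_maf_member(self):
        """Toy with pairwise r2 ~ {0.9, ~0, ~0}: only the correlated pair prunes."""
        rng = np.random.default_rng(4)
        a = rng.binomial(2, 0.5, 500).astype(np.int8)
        b = a.copy()
        flip = rng.random(500) < 0.04
        b[flip] = rng.binomial(2, 0.25, flip.sum())  # drags MAF of b below a's
        c = rng.binomial(2, 0.3, 500).astype(np.int8)
        study = make_study(np.column_stack([a, b, c]), np.r_[np.ones(250), np.zeros(250)])
        r2 = np.corrcoef(np.column_stack([a, b, c]).T) ** 2
        assert r2[0, 1] > 0.8 and r2[0, 2] < 0.2 and r2[1, 2] < 0.2
        out = qc.ld_prune(study)
        lower_maf = "rs0" if study.snp_table["maf"][0] < study.snp_table["maf"][1] else "rs1"
        assert out.n_snps == 2
        assert lower_maf not in out.snp_ids

    def test_independent_snps_untouched(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, size=(300, 30)).astype(np.int8)
        study = make_study(g, np.r_[np.ones(150), np.zeros(150)])
        assert qc.ld_prune(study).n_snps == 30


class TestRelief:
    def test_constant_snp_scores_zero_and_separator_is_max(self):
        """Brute-force check on a 20-sample toy.

        The perfectly class-separating SNP must attain the maximal ReliefF
        score and a constant SNP exactly zero.
        """
        rng = np.random.default_rng(6)
        y = np.r_[np.ones(10), np.zeros(10)].astype(np.int8)
        sep = (2 * y).astype(np.int8)
        const = np.ones(20, dtype=np.int8)
        noise = rng.binomial(2, 0.5, size=(20, 4)).astype(np.int8)
        g = np.column_stack([sep, const, noise])
        study = make_study(g, y)
        scores = qc.relief_scores(study, k_neighbors=3)
        assert scores[1] == 0.0
        assert np.argmax(scores) == 0

    def test_keep_all_is_identity_and_bounds(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.3, size=(30, 8)).astype(np.int8)
        study = make_study(g, np.r_[np.ones(15), np.zeros(15)])
        out = qc.relief_filter(study, keep=8, k_neighbors=3)
        assert out.snp_ids == study.snp_ids
        with pytest.raises(ValueError):
            qc.relief_filter(study, keep=3, k_neighbors=20)


class TestMafSummary:
    def test_published_top_snp_table(self):
        """The 20 non-missing published MAFs give median .09, IQR (.05, .17)."""
        table = qc.load_top_snp_table()
        out = qc.maf_summary(table["maf"])
        assert out["n"] == 20
        assert out["median"] == 0.09
        assert (out["q1"], out["q3"]) == (0.05, 0.17)

    def test_single_value_and_welch(self):
        out = qc.maf_summary([0.3])
        assert out["median"] == out["q1"] == out["q3"] == 0.3
        both = qc.maf_summary([0.1, 0.2, 0.3], comparison=[0.3, 0.4, 0.5])
        assert both["welch_t"] < 0
        with pytest.raises(ValueError):
            qc.maf_summary([np.nan])
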