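"""Gene-score aggregation: per-variant formulas, norms, piecewise limits."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwaskit.aggregation import (
    AggregationParams,
    GenotypeProbabilities,
    build_gene_score_matrices,
    dominant_score,
    recessive_score,
    retention_prob,
    single_hit_prob,
)
from pwaskit.variants import VariantRecord

from conftest import enumerate_hit_distribution

HARD = {0: (1, 0, 0), 1: (0, 1, 0), 2: (0, 0, 1)}
S_GRID = [0.0, 0.25, 0.5, 0.75, 1.0]


class TestGenotypeProbabilities:
    def test_renormalizes_within_tolerance(self):
        g = GenotypeProbabilities(0.5, 0.3, 0.2 - 5e-7)
        assert g.p0 + g.p1 + g.p2 == pytest.approx(1.0, abs=1e-15)

    def test_rejects_sum_far_from_one(self):
        with pytest.raises(ValueError, match="sum"):
            GenotypeProbabilities(0.5, 0.3, 0.1)

    def test_rejects_out_of_range_component(self):
        with pytest.raises(ValueError):
            GenotypeProbabilities(1.2, -0.2, 0.0)


class TestPerVariantFormulas:
    @pytest.mark.parametrize(
        "s,g,mu,expected",
        [
            (0.5, (0, 1, 0), 1.0, 0.5),  # heterozygous reduces to s
            (0.5, (0, 0, 1), 0.0, 0.25),  # independent homozygous is s^2
            (0.5, (0, 0, 1), 0.5, 0.375),  # 0.5*0.5 + 0.5*0.25
            (0.3, (1, 0, 0), 0.7, 1.0),  # reference genotype retains fully
        ],
    )
    def test_retention_prob(self, s, g, mu, expected):
        assert retention_prob(s, g, mu) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "s,g,mu,expected",
        [
            (0.4, (0, 1, 0), 0.0, 0.6),  # heterozygous term is 1 - s
            (0.4, (0, 1, 0), 1.0, 0.6),  # ... independent of mu
            (0.5, (0, 0, 1), 1.0, 0.0),  # dependent copies cannot hit once
            (0.5, (0, 0, 1), 0.0, 0.5),  # binomial 2 s (1 - s)
            (0.2, (1, 0, 0), 0.5, 0.0),  # reference genotype cannot hit
        ],
    )
    def test_single_hit_prob(self, s, g, mu, expected):
        assert single_hit_prob(s, g, mu) == pytest.approx(expected)

    @given(st.floats(0, 1), st.sampled_from([0, 1, 2]), st.floats(0, 1))
    @settings(deadline=None, max_examples=200)
    def test_x_and_y_stay_in_unit_interval(self, s, g, mu):
        x = retention_prob(s, HARD[g], mu)
        y = single_hit_prob(s, HARD[g], mu)
        assert 0.0 <= x <= 1.0
        assert 0.0 <= y <= 1.0
        # one damaging hit is at most as likely as "not zero hits"... and
        # x + y = P(<=1 hit) under the per-variant model
        assert x + y <= 1.0 + 1e-12


class TestDominantScore:
    def test_single_element_norm(self):
        assert dominant_score([0.5], 2.0) == pytest.approx(0.5)

    def test_p1_is_product_law(self):
        assert dominant_score([0.8, 0.5], 1.0) == pytest.approx(0.4)

    def test_p125_matches_high_precision_oracle(self):
        # exp(-||(log 1/0.8, log 1/0.5)||_1.25), mpmath at 40 digits
        assert dominant_score([0.8, 0.5], 1.25) == pytest.approx(
            0.43839600698903855, abs=1e-15
        )

    def test_infinite_p_is_min(self):
        assert dominant_score([0.8, 0.5, 0.9], math.inf) == pytest.approx(0.5)

    def test_large_p_converges_to_infinity_branch(self):
        x = [0.8, 0.5, 0.61]
        assert dominant_score(x, 1e6) == pytest.approx(
            dominant_score(x, math.inf), abs=1e-6
        )

    def test_any_zero_forces_zero(self):
        assert dominant_score([0.9, 0.0, 0.7], 1.25) == 0.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            dominant_score([], 1.25)

    def test_p_below_one_rejected(self):
        with pytest.raises(ValueError, match="p must be"):
            dominant_score([0.5], 0.5)

    @given(
        st.lists(st.floats(0.01, 1), min_size=1, max_size=5),
        st.floats(1, 50),
    )
    @settings(deadline=None, max_examples=200)
    def test_bracketed_by_product_and_min(self, x, p):
        # the p-norm of a non-negative vector decreases in p, so D
        # increases from the product (p=1) to the min (p=inf)
        d = dominant_score(x, p)
        assert np.prod(x) - 1e-9 <= d <= min(x) + 1e-9


class TestRecessiveScore:
    @pytest.mark.parametrize("s", [0.1, 0.4, 0.7, 1.0])
    def test_single_heterozygous_variant_is_harmless(self, s):
        # one het variant cannot hit both gene copies: R = 1 for any s > 0
        x, y = s, 1.0 - s
        assert recessive_score([x], [y], math.inf, 3.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("s", S_GRID)
    def test_homozygous_symbolic_expansion(self, s):
        # mu = 0.5: x = (s + s^2)/2, y = s(1-s); R = x + y = 1.5 s - 0.5 s^2
        x = 0.5 * s + 0.5 * s * s
        y = 0.5 * 2.0 * s * (1.0 - s)
        expected = 1.5 * s - 0.5 * s * s
        if x == 0:
            assert recessive_score([x], [y], math.inf, 3.0) == pytest.approx(y)
        else:
            assert recessive_score([x], [y], math.inf, 3.0) == pytest.approx(expected)

    def test_two_zero_retentions_force_zero(self):
        assert recessive_score([0.0, 0.0], [1.0, 1.0], 1.25, 3.0) == 0.0

    def test_single_zero_with_p_above_one_returns_its_y(self):
        assert recessive_score([0.5, 0.0], [0.1, 0.7], 1.25, 3.0) == pytest.approx(0.7)

    def test_single_zero_with_p_one_multiplies_remaining_x(self):
        assert recessive_score([0.5, 0.0, 0.8], [0.1, 0.7, 0.1], 1.0, 3.0) == (
            pytest.approx(0.7 * 0.5 * 0.8)
        )

    def test_no_zero_uses_zeta_correction(self):
        x, y = [0.8, 0.5], [0.1, 0.3]
        zeta = (( (0.1 / 0.8) ** 3 + (0.3 / 0.5) ** 3 )) ** (1 / 3)
        expected = min(1.0, (1 + zeta) * min(x))
        assert recessive_score(x, y, math.inf, 3.0) == pytest.approx(expected)

    def test_result_clipped_to_one(self):
        # q = 1 with large ratios can push (1 + zeta) D above 1
        assert recessive_score([0.9, 0.9], [0.9, 0.9], math.inf, 1.0) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            recessive_score([0.5], [0.5, 0.5], 1.0, 1.0)


class TestEnumerationOracle:
    """Independent-allele brute force vs. the closed-form aggregation."""

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_mu0_p1_q1_matches_enumeration(self, k):
        params_grid = product(product(S_GRID, repeat=k), product([0, 1, 2], repeat=k))
        for scores, genotypes in params_grid:
            x = [retention_prob(s, HARD[g], 0.0) for s, g in zip(scores, genotypes)]
            y = [single_hit_prob(s, HARD[g], 0.0) for s, g in zip(scores, genotypes)]
            dist = enumerate_hit_distribution(scores, genotypes)
            D = dominant_score(x, 1.0)
            R = recessive_score(x, y, 1.0, 1.0)
            assert D == pytest.approx(dist.get(0, 0.0), abs=1e-12)
            assert R == pytest.approx(dist.get(0, 0.0) + dist.get(1, 0.0), abs=1e-12)


def make_gene_variants(specs):
    return [
        VariantRecord(f"1:{i + 1}:A:T", gene, "missense", score=s)
        for i, (gene, s) in enumerate(specs)
    ]


def probs_from_hard(genotypes):
    return np.array([[HARD[g] for g in row] for row in genotypes], dtype=float)


class TestBuildMatrices:
    def test_reference_genotypes_score_one(self):
        variants = make_gene_variants([("G1", 0.3), ("G1", 0.6)])
        probs = probs_from_hard([[0, 0]])
        dom, rec = build_gene_score_matrices(variants, probs, ["S0"])
        assert dom.values[0, 0] == 1.0
        assert rec.values[0, 0] == 1.0

    def test_homozygous_nonsense_knocks_out_both_models(self):
        variants = make_gene_variants([("G1", 0.0)])
        probs = probs_from_hard([[2]])
        dom, rec = build_gene_score_matrices(variants, probs, ["S0"])
        assert dom.values[0, 0] == 0.0
        assert rec.values[0, 0] == 0.0

    def test_compound_heterozygous_lof_is_recessive_damage(self):
        # two het LoF variants: each copy hit once -> D = 0 and R = 0
        variants = make_gene_variants([("G1", 0.0), ("G1", 0.0)])
        probs = probs_from_hard([[1, 1]])
        dom, rec = build_gene_score_matrices(variants, probs, ["S0"])
        assert dom.values[0, 0] == 0.0
        assert rec.values[0, 0] == 0.0
        dist = enumerate_hit_distribution([0.0, 0.0], [1, 1])
        assert dist[2] == pytest.approx(1.0)

    def test_single_het_lof_spares_recessive(self):
        variants = make_gene_variants([("G1", 0.0)])
        probs = probs_from_hard([[1]])
        dom, rec = build_gene_score_matrices(variants, probs, ["S0"])
        assert dom.values[0, 0] == 0.0
        assert rec.values[0, 0] == 1.0

    def test_variant_free_gene_scores_exactly_one(self):
        variants = make_gene_variants([("G1", 0.5)])
        probs = probs_from_hard([[1]])
        dom, rec = build_gene_score_matrices(
            variants, probs, ["S0"], gene_ids=["G1", "G_EMPTY"]
        )
        assert dom.values[0, 1] == 1.0
        assert rec.values[0, 1] == 1.0

    def test_unknown_gene_rejected(self):
        variants = make_gene_variants([("G1", 0.5)])
        probs = probs_from_hard([[1]])
        with pytest.raises(ValueError, match="unknown gene"):
            build_gene_score_matrices(variants, probs, ["S0"], gene_ids=["G2"])

    def test_dimension_mismatch_rejected(self):
        variants = make_gene_variants([("G1", 0.5)])
        with pytest.raises(ValueError, match="shape"):
            build_gene_score_matrices(variants, np.zeros((2, 3, 3)), ["S0", "S1"])

    def test_mu_is_per_model(self):
        # homozygous missense: dominant x uses mu_D = 1 (-> s), recessive
        # x uses mu_R = 0.5 (-> (s + s^2)/2)
        s = 0.4
        variants = make_gene_variants([("G1", s)])
        probs = probs_from_hard([[2]])
        dom, rec = build_gene_score_matrices(variants, probs, ["S0"])
        assert dom.values[0, 0] == pytest.approx(s)
        assert rec.values[0, 0] == pytest.approx(1.5 * s - 0.5 * s * s)

    def test_recessive_dominates_dominant_on_random_configs(self):
        rng = np.random.default_rng(17)
        n, trials = 200, 50
        for _ in range(trials):
            k = int(rng.integers(1, 6))
            variants = make_gene_variants(
                [("G1", float(rng.uniform())) for _ in range(k)]
            )
            probs = probs_from_hard(rng.integers(0, 3, size=(n, k)))
            dom, rec = build_gene_score_matrices(variants, probs, [f"S{i}" for i in range(n)])
            assert (rec.values >= dom.values - 1e-12).all()
            assert (dom.values >= 0).all() and (rec.values <= 1).all()

    def test_dominant_monotone_in_scores_and_genotypes(self):
        # raising a variant's s raises D; moving a sample from het to hom
        # alt (for s < 1) lowers D
        base = [("G1", 0.3), ("G1", 0.6)]
        lifted = [("G1", 0.5), ("G1", 0.6)]
        geno_het = probs_from_hard([[1, 1]])
        geno_hom = probs_from_hard([[2, 1]])
        d = lambda v, g: build_gene_score_matrices(make_gene_variants(v), g, ["S0"])[0].values[0, 0]
        assert d(lifted, geno_het) >= d(base, geno_het)
        assert d(base, geno_hom) <= d(base, geno_het)


class TestAggregationParams:
    def test_defaults_are_published_values(self):
        p = AggregationParams()
        assert (p.mu_D, p.p_D, p.mu_R, p.q_R) == (1.0, 1.25, 0.5, 3.0)
        assert math.isinf(p.p_R)

    @pytest.mark.parametrize(
        "kwargs", [dict(mu_D=1.5), dict(p_D=0.9), dict(q_R=float("nan"))]
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AggregationParams(**kwargs)
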