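"""Restandardized random-set enrichment, the DEC statistic and the
core-set validation machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcnet import (
    SyntheticConfig,
    core_set_comparison,
    core_set_score,
    dec_enrichment,
    dec_statistic,
    generate_dataset,
    meta_combine,
    restandardized_score,
    rs_de_enrichment,
)
from dcnet.enrichment import EnrichmentTable
from dcnet.io import GeneSetCollection
from dcnet.stats import bh_fdr, fisher_combined


def _table(names, p, mode="de", n_resamples=1000):
    p = np.asarray(p, dtype=float)
    return EnrichmentTable(
        names=list(names), sizes=np.full(len(names), 5), score=np.zeros(len(names)),
        p_emp=p, fdr=bh_fdr(p), n_resamples=n_resamples, mode=mode,
    )


class TestRestandardizedScore:
    def test_set_at_universe_mean_scores_zero(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert restandardized_score(scores, [0, 4]) == pytest.approx(0.0)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            restandardized_score(np.ones(6), [0, 1])

    def test_exact_mean_zero_variance_one_over_exhaustive_subsets(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=6)
        zs = [
            restandardized_score(scores, idx)
            for idx in itertools.combinations(range(6), 3)
        ]
        zs = np.array(zs)
        assert len(zs) == 20
        assert zs.mean() == pytest.approx(0.0, abs=1e-10)
        assert zs.var(ddof=0) == pytest.approx(1.0, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(4, 12), st.integers(0, 1000))
    def test_standardization_exact_for_any_small_universe(self, g, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=g)
        m = rng.integers(1, g)
        zs = np.array(
            [restandardized_score(scores, idx)
             for idx in itertools.combinations(range(g), int(m))]
        )
        assert zs.mean() == pytest.approx(0.0, abs=1e-10)
        assert zs.var(ddof=0) == pytest.approx(1.0, abs=1e-10)


class TestRsDeEnrichment:
    def test_planted_de_set_is_significant(self):
        cfg = SyntheticConfig(
            n_genes=150, n_blocks=0, block_size=0, rho=0.0,
            samples_per_group=30, dc_fraction=0, de_fraction=0.1,
            effect_size=1.0, seed=31,
        )
        ds, truth = generate_dataset(cfg)
        rng = np.random.default_rng(1)
        decoys = {
            f"R{i}": sorted(rng.choice(ds.gene_ids, 15, replace=False))
            for i in range(5)
        }
        sets = GeneSetCollection({"PLANTED": sorted(truth.planted_de_genes), **decoys})
        table = rs_de_enrichment(ds, sets, n_perm=200, seed=2)
        p = table.p_by_name()
        assert p["PLANTED"] <= 0.05
        assert np.all(table.p_emp * 200 == np.round(table.p_emp * 200))

    def test_observed_z_inside_own_null_under_exchangeability(self, null_study):
        ds, _ = null_study
        rng = np.random.default_rng(3)
        sets = GeneSetCollection(
            {f"R{i}": sorted(rng.choice(ds.gene_ids, 10, replace=False))
             for i in range(10)}
        )
        table = rs_de_enrichment(ds, sets, n_perm=150, seed=4)
        # under the null the observed score should not be extreme for most sets
        inside = np.mean((table.p_emp > 0.005) & (table.p_emp < 0.995))
        assert inside >= 0.9


class TestDecStatistic:
    def test_unit_pvalues_give_zero(self):
        u = dec_statistic(np.array([1.0]), np.array([1.0]), floor=1e-3)
        assert u[0] == pytest.approx(0.0)

    def test_simple_log_value(self):
        u = dec_statistic(np.array([0.01]), np.array([1.0]), floor=1e-3)
        assert u[0] == pytest.approx(2.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_equals_floored_min_p_transform(self, seed):
        rng = np.random.default_rng(seed)
        p1 = rng.random(30)
        p2 = rng.random(30)
        floor = 10.0 ** -rng.integers(1, 6)
        u = dec_statistic(p1, p2, floor)
        expected = -np.log10(np.maximum(np.minimum(p1, p2), floor))
        np.testing.assert_allclose(u, expected, atol=1e-12)
        # monotone: shrinking either p never decreases u
        u2 = dec_statistic(p1 / 2, p2, floor)
        assert np.all(u2 >= u - 1e-12)

    def test_floor_must_be_positive(self):
        with pytest.raises(ValueError):
            dec_statistic(np.array([0.5]), np.array([0.5]), floor=0.0)


class TestDecEnrichment:
    def test_top_gene_set_beats_every_draw(self):
        u = np.array([9.0, 8.0, 7.0, 0.1, 0.2, 0.3, 0.1, 0.2])
        genes = [f"g{i}" for i in range(8)]
        sets = GeneSetCollection({"TOP": ["g0", "g1", "g2"]})
        table = dec_enrichment(u, genes, sets, n_draws=500, seed=0)
        # only one of C(8,3)=56 subsets ties the observed mean, so random
        # draws essentially never reach it; exhaustive check confirms
        best = max(
            np.mean(u[list(idx)]) for idx in itertools.combinations(range(8), 3)
        )
        assert best == pytest.approx(table.score[0])
        # only the identical subset (1 of C(8,3)=56) ties the observed mean
        assert table.p_emp[0] <= 0.05

    def test_constant_u_everything_p_one(self):
        u = np.ones(10)
        genes = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection({"A": genes[:3], "B": genes[2:6]})
        table = dec_enrichment(u, genes, sets, n_draws=100, seed=1)
        assert np.all(table.p_emp == 1.0)

    def test_doubling_draws_stays_within_monte_carlo_error(self):
        rng = np.random.default_rng(2)
        u = rng.exponential(size=60)
        genes = [f"g{i}" for i in range(60)]
        sets = GeneSetCollection({"S": genes[:12]})
        p1 = dec_enrichment(u, genes, sets, n_draws=400, seed=3).p_emp[0]
        p2 = dec_enrichment(u, genes, sets, n_draws=800, seed=4).p_emp[0]
        se = np.sqrt(max(p1, 1 / 400) * (1 - min(p1, 1 - 1 / 400)) / 400)
        assert abs(p1 - p2) <= 4 * se + 1 / 400


class TestMetaCombine:
    def test_single_table_is_identity_after_flooring(self):
        t = _table(["A", "B"], [0.05, 0.5], n_resamples=100)
        out = meta_combine([t])
        assert out["A"] == pytest.approx(0.05, abs=1e-12)

    def test_all_ones_combine_to_one(self):
        tables = [_table(["A"], [1.0]) for _ in range(5)]
        assert meta_combine(tables)["A"] == pytest.approx(1.0)

    def test_matches_fisher_combined_oracle(self):
        tables = [_table(["A"], [0.05]), _table(["A"], [0.2])]
        assert meta_combine(tables)["A"] == pytest.approx(
            fisher_combined([0.05, 0.2]), abs=1e-12
        )

    def test_zero_p_floored_before_log(self):
        tables = [_table(["A"], [0.0], n_resamples=100), _table(["A"], [0.5])]
        assert meta_combine(tables)["A"] == pytest.approx(
            fisher_combined([0.01, 0.5]), abs=1e-12
        )


class TestCoreSetScore:
    def test_no_significant_core_pathway_scores_zero(self):
        assert core_set_score({"A": 0.5, "B": 0.02}, ["A", "B"], alpha=0.01) == 0.0

    def test_all_zero_pvalues_count_fully(self):
        assert core_set_score({"A": 0.0, "B": 0.0}, ["A", "B"]) == 2.0

    def test_weighted_arithmetic(self):
        p = {"A": 0.001, "B": 0.005, "C": 0.02}
        assert core_set_score(p, ["A", "B", "C"], alpha=0.01) == pytest.approx(1.4)

    def test_unknown_core_pathway_rejected(self):
        with pytest.raises(ValueError):
            core_set_score({"A": 0.1}, ["A", "MISSING"])


class TestCoreSetComparison:
    def test_identical_tables_give_zero_difference(self):
        names = [f"P{i}" for i in range(6)]
        p = [0.001, 0.02, 0.3, 0.004, 0.5, 0.05]
        comp = core_set_comparison(
            _table(names, p), _table(names, p, mode="dec"),
            core=["P0", "P3"], n_draws=500, seed=0,
        )
        assert comp.d == 0.0
        assert comp.p_perm >= 0.5  # every draw ties or exceeds a zero difference

    def test_matches_exhaustive_enumeration(self):
        names = [f"P{i}" for i in range(6)]
        p_de = [0.5, 0.3, 0.009, 0.2, 0.008, 0.6]
        p_dec = [0.002, 0.004, 0.009, 0.5, 0.3, 0.6]
        de_t, dec_t = _table(names, p_de), _table(names, p_dec, mode="dec")
        core = ["P0", "P1"]
        comp = core_set_comparison(de_t, dec_t, core, n_draws=3000, seed=1)

        def score(pv, subset):
            return sum(max(0.0, 1 - pv[names.index(s)] / 0.01) for s in subset)

        d_obs = score(p_dec, core) - score(p_de, core)
        draws = list(itertools.combinations(names, 2))
        exact = np.mean(
            [score(p_dec, s) - score(p_de, s) >= d_obs for s in draws]
        )
        assert comp.p_perm == pytest.approx(exact, abs=1 / 15)

    def test_dec_dominance_detected(self):
        # constructed study: core pathways are strongly significant under
        # DEC, indistinguishable under DE
        rng = np.random.default_rng(5)
        names = [f"P{i}" for i in range(40)]
        core = names[:5]
        p_de = rng.uniform(0.2, 1.0, 40)
        p_dec = rng.uniform(0.2, 1.0, 40)
        p_dec[:5] = 1e-4
        comp = core_set_comparison(
            _table(names, p_de), _table(names, p_dec, mode="dec"),
            core, n_draws=2000, seed=6,
        )
        assert comp.p_perm <= 0.05
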