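"""Interaction model, permutation null, q-values, enrichment bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigqtl import gxe
from sigqtl.gxe import (
    GxeError,
    NullStore,
    batch_interaction,
    build_permutation_null,
    correct_and_qvalue,
    effect_concordance,
    empirical_pvalues,
    fit_interaction,
    inverse_normal_transform,
    qvalues,
    replication_enrichment,
    twas_overlap,
)


class TestInverseNormalTransform:
    def test_blom_quantiles_n3(self):
        out = inverse_normal_transform(np.array([5.0, 1.0, 9.0]))
        expect = stats.norm.ppf((np.array([2, 1, 3]) - 0.375) / 3.25)
        assert np.allclose(out, expect, atol=1e-3)
        assert abs(out[0]) < 1e-12

    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.standard_normal(100)
        assert np.allclose(inverse_normal_transform(x),
                           inverse_normal_transform(np.exp(3 * x)))

    def test_moments_at_n250(self, rng):
        out = inverse_normal_transform(rng.standard_normal(250))
        assert abs(out.mean()) < 1e-6
        assert 0.9 <= out.std(ddof=1) <= 1.0

    def test_ties_get_average_ranks(self):
        out = inverse_normal_transform(np.array([1.0, 1.0, 5.0, 9.0]))
        assert out[0] == out[1]

    def test_nan_preserved_and_errors(self):
        x = np.array([1.0, np.nan, 3.0, 2.0])
        out = inverse_normal_transform(x)
        assert np.isnan(out[1]) and np.isfinite(out[0])
        with pytest.raises(GxeError):
            inverse_normal_transform(np.array([2.0, 2.0, 2.0]))
        with pytest.raises(GxeError):
            inverse_normal_transform(np.array([1.0, 2.0]))

    def test_series_roundtrip(self, rng):
        s = pd.Series(rng.standard_normal(10), index=list("abcdefghij"))
        out = inverse_normal_transform(s)
        assert isinstance(out, pd.Series)
        assert out.index.equals(s.index)


class TestFitInteraction:
    def _sim(self, rng, n=250, b_gxe=0.5, cov=None):
        d = rng.binomial(2, 0.3, size=n).astype(float)
        e = rng.standard_normal(n)
        y = 0.3 * d + 0.2 * e + b_gxe * d * e + rng.standard_normal(n)
        if cov is not None:
            y = y + cov @ np.zeros(cov.shape[1])
        return y, d, e

    def test_matches_statsmodels_oracle(self, rng):
        import statsmodels.api as sm

        y, d, e = self._sim(rng, n=80)
        res = fit_interaction(y, d, e)
        X = sm.add_constant(np.column_stack([d, e, d * e]))
        fit = sm.OLS(y, X).fit()
        for i, term in enumerate(["intercept", "dosage", "signature",
                                  "interaction"]):
            assert res[f"b_{term}"] == pytest.approx(fit.params[i], abs=1e-8)
            assert res[f"se_{term}"] == pytest.approx(fit.bse[i], abs=1e-8)
            assert res[f"p_{term}"] == pytest.approx(fit.pvalues[i], abs=1e-8)

    def test_matches_statsmodels_with_covariates(self, rng):
        import statsmodels.api as sm

        n = 100
        y, d, e = self._sim(rng, n=n)
        C = rng.standard_normal((n, 3))
        res = fit_interaction(y, d, e, covariates=C)
        X = sm.add_constant(np.column_stack([d, C, e, d * e]))
        fit = sm.OLS(y, X).fit()
        assert res["b_interaction"] == pytest.approx(fit.params[-1], abs=1e-8)
        assert res["se_interaction"] == pytest.approx(fit.bse[-1], abs=1e-8)
        assert res["p_intercept"] == pytest.approx(fit.pvalues[0], abs=1e-8)

    def test_constant_env_rank_error_names_term(self, rng):
        y, d, _ = self._sim(rng, n=50)
        with pytest.raises(GxeError, match="signature|interaction"):
            fit_interaction(y, d, np.zeros(50))

    def test_orthogonal_covariates_leave_interaction_unchanged(self, rng):
        n = 200
        y, d, e = self._sim(rng, n=n)
        X = np.column_stack([np.ones(n), d, e, d * e])
        C = rng.standard_normal((n, 2))
        C = C - X @ np.linalg.lstsq(X, C, rcond=None)[0]  # orthogonalize
        plain = fit_interaction(y, d, e)
        adj = fit_interaction(y, d, e, covariates=C)
        assert adj["b_interaction"] == pytest.approx(plain["b_interaction"],
                                                     abs=1e-8)

    def test_batch_matches_single_fits(self, rng):
        T, n = 7, 60
        Y = rng.standard_normal((T, n))
        D = rng.binomial(2, 0.4, size=(T, n)).astype(float)
        E = rng.standard_normal((T, n))
        C = rng.standard_normal((n, 2))
        for cov in (None, C):
            res = batch_interaction(Y, D, E, covariates=cov)
            for t in range(T):
                single = fit_interaction(Y[t], D[t], E[t], covariates=cov)
                for term in gxe.TERMS:
                    for w in ("b", "se", "p"):
                        assert res[f"{w}_{term}"][t] == pytest.approx(
                            single[f"{w}_{term}"], abs=1e-8
                        )


class TestQvalues:
    def test_pi0_one_equals_benjamini_hochberg(self, rng):
        from statsmodels.stats.multitest import multipletests

        for m in (20, 1000):
            p = rng.uniform(size=m)
            p[: m // 10] = rng.uniform(0, 1e-3, size=m // 10)
            q = qvalues(p, pi0=1.0)
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, bh, atol=1e-12)

    def test_monotone_in_p_and_bounded(self, rng):
        p = rng.uniform(size=500)
        q = qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert q.max() <= 1.0

    def test_pi0_estimate_below_one_with_signal(self, rng):
        p = np.concatenate([rng.uniform(0, 1e-4, 300), rng.uniform(size=700)])
        q_storey = qvalues(p)
        q_bh = qvalues(p, pi0=1.0)
        assert (q_storey <= q_bh + 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(GxeError):
            qvalues(np.array([0.1, 1.2]))
        with pytest.raises(GxeError):
            qvalues(np.array([0.1, np.nan]))


class TestEmpiricalPvalues:
    def test_pseudocount_formula(self):
        null = np.linspace(0.001, 0.999, 999)
        assert empirical_pvalues(np.array([0.0]), null)[0] == pytest.approx(
            1.0 / 1000.0
        )

    def test_hand_count(self):
        null = np.concatenate([np.full(5, 0.0005), np.linspace(0.01, 1, 994)])
        p = empirical_pvalues(np.array([0.001]), null)[0]
        assert p == pytest.approx(6.0 / 1000.0)

    def test_monotone_in_observed(self, rng):
        null = rng.uniform(size=1000)
        obs = np.sort(rng.uniform(size=50))
        p = empirical_pvalues(obs, null)
        assert np.all(np.diff(p) >= 0)


class TestNullStore:
    def test_deterministic_and_exact_count(self, rng):
        n = 60
        pairs = [(rng.standard_normal(n),
                  rng.binomial(2, 0.4, n).astype(float)) for _ in range(10)]
        env = rng.standard_normal(n)
        s1 = build_permutation_null(pairs, env, n_null=1000, seed=3)
        s2 = build_permutation_null(pairs, env, n_null=1000, seed=3)
        assert s1.n_null == 1000
        assert np.array_equal(s1.null_p, s2.null_p)
        s3 = build_permutation_null(pairs, env, n_null=1000, seed=4)
        assert not np.array_equal(s1.null_p, s3.null_p)

    def test_round_count_bookkeeping(self, rng):
        # 10^3 null values on 10 pairs: 100 rounds each, all pairs used
        n = 40
        pairs = [(rng.standard_normal(n),
                  rng.binomial(2, 0.4, n).astype(float)) for _ in range(10)]
        env = rng.standard_normal(n)
        store = build_permutation_null(pairs, env, n_null=1000, seed=0)
        assert store.n_null == 1000

    def test_null_uniformity(self, rng):
        n = 150
        pairs = [(rng.standard_normal(n),
                  rng.binomial(2, 0.3, n).astype(float)) for _ in range(20)]
        env = inverse_normal_transform(rng.standard_normal(n))
        store = build_permutation_null(pairs, env, n_null=20_000, seed=5)
        assert stats.kstest(store.null_p, "uniform").pvalue > 0.01

    def test_save_load_roundtrip(self, tmp_path, rng):
        store = NullStore("sig", rng.uniform(size=100), seed=9)
        path = tmp_path / "null.txt.gz"
        store.save(path)
        loaded = NullStore.load(path)
        assert loaded.signature_name == "sig"
        assert loaded.seed == 9
        assert np.allclose(loaded.null_p, store.null_p, atol=1e-7)

    def test_min_null_factor_guard(self, rng):
        pairs = [(rng.standard_normal(20), np.ones(20))]
        with pytest.raises(GxeError):
            build_permutation_null(pairs, rng.standard_normal(20), n_null=5,
                                   seed=0, min_null_factor=10)
        with pytest.raises(GxeError):
            build_permutation_null([], rng.standard_normal(20), 10, 0)

    def test_null_pvals_match_batch_solver(self, rng):
        # the moment-based fast path equals the generic batched OLS
        n = 50
        y = rng.standard_normal(n)
        d = rng.binomial(2, 0.4, n).astype(float)
        e = rng.standard_normal(n)
        r = np.random.default_rng(7)
        p_fast = gxe._null_pvals_one_pair(y, d, e, 20, r)
        r2 = np.random.default_rng(7)
        order = np.argsort(r2.random((20, n)), axis=1)
        Dp = d[order]
        res = batch_interaction(np.tile(y, (20, 1)), Dp, np.tile(e, (20, 1)))
        assert np.allclose(p_fast, res["p_interaction"], atol=1e-10)


class TestCorrectAndQvalue:
    def _records(self, p):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(p))],
            "variant_id": [f"v{i}" for i in range(len(p))],
            "p_interaction": p,
            "signature_name": "sig",
        })

    def test_formula_and_monotonicity(self, rng):
        null = NullStore("sig", rng.uniform(size=999), seed=0)
        p = np.sort(rng.uniform(size=30))
        out = correct_and_qvalue(self._records(p), null)
        pc = out["p_interaction_permcorrected"].to_numpy()
        assert np.all(np.diff(pc) >= 0)
        assert np.all((pc >= 1e-3) & (pc <= 1.0))
        q = out["q_interaction_permcorrected"].to_numpy()
        assert np.all(np.diff(q) >= -1e-12)

    def test_signature_mismatch_and_empty_null(self, rng):
        recs = self._records(np.array([0.5]))
        with pytest.raises(GxeError):
            correct_and_qvalue(recs, NullStore("other", rng.uniform(size=10),
                                               seed=0))
        with pytest.raises(GxeError):
            correct_and_qvalue(recs, NullStore("sig", np.array([]), seed=0))


class TestReplicationEnrichment:
    def test_hand_table(self):
        universe = {f"g{i}" for i in range(200)}
        a_and_b = {f"g{i}" for i in range(20)}
        a_only = {f"g{i}" for i in range(20, 50)}
        b_only = {f"g{i}" for i in range(50, 60)}
        set_a = a_and_b | a_only
        set_b = a_and_b | b_only
        orr, p, table = replication_enrichment(set_a, set_b, universe)
        assert table == (20, 30, 10, 140)
        assert orr == pytest.approx(20 * 140 / (30 * 10))

    def test_random_split_near_null(self, rng):
        universe = {f"g{i}" for i in range(2000)}
        genes = sorted(universe)
        picks = rng.permutation(2000)
        set_a = {genes[i] for i in picks[:1000]}
        set_b = {genes[i] for i in rng.permutation(2000)[:1000]}
        orr, p, _ = replication_enrichment(set_a, set_b, universe)
        assert 0.7 <= orr <= 1.4

    def test_zero_cell_continuity_correction(self):
        universe = {"a", "b", "c", "d"}
        orr, p, table = replication_enrichment({"a"}, {"a"}, universe)
        assert 0 in table
        assert np.isfinite(orr) and orr > 0

    def test_empty_universe_rejected(self):
        with pytest.raises(GxeError):
            replication_enrichment(set(), set(), set())

    def test_matches_exhaustive_hypergeometric_enumeration(self):
        # two-sided Fisher p == sum of hypergeometric pmf <= observed pmf
        def oracle(a, b, c, d):
            n = a + b + c + d
            r, k = a + b, a + c
            lo, hi = max(0, r + k - n), min(r, k)
            support = np.arange(lo, hi + 1)
            pmf = stats.hypergeom.pmf(support, n, r, k)
            obs = stats.hypergeom.pmf(a, n, r, k)
            return pmf[pmf <= obs * (1 + 1e-10)].sum()

        rng = np.random.default_rng(0)
        tables = [(a, b, c, d)
                  for a in range(4) for b in range(4)
                  for c in range(4) for d in range(4)]
        tables += [tuple(rng.integers(0, 13, size=4)) for _ in range(300)]
        for a, b, c, d in tables:
            if a + b + c + d == 0:
                continue
            p_impl = stats.fisher_exact([[a, b], [c, d]])[1]
            assert p_impl == pytest.approx(oracle(a, b, c, d), abs=1e-10)


class TestEffectConcordance:
    def _recs(self, z, sign=1.0):
        m = len(z)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(m)],
            "variant_id": [f"v{i}" for i in range(m)],
            "signature_name": "sig",
            "b_interaction": sign * z,
            "se_interaction": np.ones(m),
        })

    def test_identical_and_flipped(self, rng):
        z = rng.standard_normal(20)
        r, p, n = effect_concordance(self._recs(z), self._recs(z))
        assert r == pytest.approx(1.0)
        assert n == 20
        r2, _, _ = effect_concordance(self._recs(z), self._recs(z, sign=-1.0))
        assert r2 == pytest.approx(-1.0)

    def test_too_few_pairs(self, rng):
        z = rng.standard_normal(2)
        with pytest.raises(GxeError):
            effect_concordance(self._recs(z), self._recs(z))


class TestTwasOverlap:
    def _records(self):
        return pd.DataFrame({
            "gene_id": ["g1", "g2", "g3", "g4"],
            "signature_name": "sig",
            "q_signature": [0.01, 0.05, 0.5, 0.2],
            "q_interaction_permcorrected": [0.05, 0.05, 0.01, 0.9],
        })

    def test_toy_set_arithmetic(self):
        twas = pd.DataFrame({
            "gene_id": ["g2", "g3", "g9"],
            "trait": "asthma",
            "significant": True,
        })
        out = twas_overlap(self._records(), twas)
        gxe_row = out[out["gene_set"] == "gxe"].iloc[0]
        assert gxe_row["n_overlap"] == 2
        assert gxe_row["overlap_genes"] == "g2,g3"

    def test_empty_twas_table(self):
        twas = pd.DataFrame(columns=["gene_id", "trait", "significant"])
        out = twas_overlap(self._records(), twas)
        assert out.empty

    def test_all_genes_significant_recovers_sets(self):
        twas = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3", "g4"],
            "trait": "asthma",
            "significant": True,
        })
        out = twas_overlap(self._records(), twas)
        marg = out[out["gene_set"] == "marginal_env"].iloc[0]
        assert marg["n_overlap"] == marg["n_genes"]

    def test_missing_columns_named(self):
        with pytest.raises(GxeError, match="significant"):
            twas_overlap(self._records(),
                         pd.DataFrame({"gene_id": [], "trait": []}))


def test_map_interactions_layout(small_expr, small_cohort, rng):
    genes = list(small_expr.residual.index[:8])
    variants = [small_cohort.genotypes.variant_ids[i] for i in range(8)]
    leads = pd.DataFrame({"gene_id": genes, "variant_id": variants})
    sig_vals = pd.DataFrame(
        {"sigA": rng.standard_normal(small_expr.residual.shape[1]),
         "sigB": rng.standard_normal(small_expr.residual.shape[1])},
        index=small_expr.residual.columns,
    )
    records, stores = gxe.map_interactions(
        leads, small_expr.residual, small_cohort.genotypes.dosages,
        sig_vals, n_null=2000, seed=1,
    )
    assert list(records.columns) == gxe.GXE_COLUMNS + ["significant"]
    assert len(records) == 16  # leads x signatures
    assert set(stores) == {"sigA", "sigB"}
    assert stores["sigA"].n_null == 2000
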