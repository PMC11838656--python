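"""Pairwise causal tests: Beta null laws, local FDR, global FDR selection."""

import numpy as np
import pytest
from scipy import stats

from cpnet import causal_tests as ct
from cpnet.preprocess import supernormalize_matrix
from cpnet.pqtl import map_cis_pqtls
from cpnet.synthetic_data import (
    TruthNetwork,
    generate_genotypes,
    simulate_proteins,
)

from conftest import cis_only_truth


class TestMergeCategories:
    def test_three_full_categories(self):
        e = np.array([0] * 5 + [1] * 5 + [2] * 5)
        codes, k = ct.merge_genotype_categories(e)
        assert k == 3 and set(codes) == {0, 1, 2}

    def test_singleton_category_merged_to_nearest(self):
        e = np.array([0] * 10 + [1] * 10 + [2])
        codes, k = ct.merge_genotype_categories(e)
        assert k == 2
        assert codes[-1] == codes[10]  # lone 2 joins the dosage-1 group

    def test_single_category_errors(self):
        with pytest.raises(ValueError):
            ct.merge_genotype_categories(np.zeros(20))


class TestSecondaryLinkage:
    def test_identical_balanced_group_means_gives_zero(self):
        e = np.array([0] * 10 + [1] * 10)
        b = np.concatenate([np.arange(10.0), np.arange(10.0)])
        res = ct.llr_secondary(e, b)
        assert res.llr == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_null_pvalues_uniform(self, rng):
        # median KS over independent batches guards against the 1%-level
        # false alarm a single KS draw carries
        n, reps = 500, 10_000
        ks_ps = []
        for _ in range(3):
            e = rng.integers(0, 3, n)
            codes, k = ct.merge_genotype_categories(e)
            B = rng.standard_normal((n, reps))
            out = ct._pair_tests_vectorized(codes, k, B)
            ks_ps.append(stats.kstest(out["p2_pvalue"], "uniform").pvalue)
        assert np.median(ks_ps) > 0.01

    def test_beta_pvalue_matches_permutation_oracle(self, rng):
        n, P = 30, 100_000
        e = rng.integers(0, 3, n)
        b = rng.standard_normal(n) + 0.5 * (e == 2)
        res = ct.llr_secondary(e, b)

        # independent oracle: one-way ANOVA explained fraction via group sums
        codes, k = ct.merge_genotype_categories(e)
        G = np.zeros((n, k))
        G[np.arange(n), codes] = 1
        counts = G.sum(axis=0)

        def rho2(mat):  # columns are (permuted) b vectors
            mc = (mat - mat.mean(axis=0)) / mat.std(axis=0)
            mu = (G.T @ mc) / counts[:, None]
            return (counts[:, None] / n * mu**2).sum(axis=0)

        obs = rho2(b[:, None])[0]
        perms = np.array([rng.permutation(b) for _ in range(P)]).T
        p_perm = (rho2(perms) >= obs - 1e-12).mean()
        se = np.sqrt(p_perm * (1 - p_perm) / P)
        assert abs(res.p_value - p_perm) < 4 * se + 2 / P


class TestControlledTest:
    def test_b_equals_a_gives_capped_llr(self, rng):
        n = 100
        e = rng.integers(0, 3, n)
        a = rng.standard_normal(n)
        res = ct.llr_controlled(e, a, a.copy())
        assert res.llr == ct.LLR_CAP
        assert res.p_value < 1e-10

    def test_null_pvalues_uniform(self, rng):
        n, reps = 500, 10_000
        ks_ps = []
        for _ in range(3):
            e = rng.integers(0, 3, n)
            codes, k = ct.merge_genotype_categories(e)
            a = rng.standard_normal(n)
            # B depends on genotype means only: controlled-test null
            B = 0.4 * (e == 1)[:, None] + rng.standard_normal((n, reps))
            out = ct._pair_tests_vectorized(codes, k, B, A=a)
            ks_ps.append(stats.kstest(out["p5_pvalue"], "uniform").pvalue)
        assert np.median(ks_ps) > 0.01

    def test_algebraic_equivalence_with_nested_ols(self, rng):
        # llr5 = (n/2) ln(RSS_null / RSS_alt) for the explicit nested models
        n = 200
        e = rng.integers(0, 3, n)
        a = rng.standard_normal(n)
        b = 0.3 * a + 0.2 * (e == 2) + rng.standard_normal(n)
        res = ct.llr_controlled(e, a, b)

        codes, k = ct.merge_genotype_categories(e)
        bs = (b - b.mean()) / b.std()
        G = np.zeros((n, k))
        G[np.arange(n), codes] = 1
        beta0, *_ = np.linalg.lstsq(G, bs, rcond=None)
        rss_null = np.sum((bs - G @ beta0) ** 2)
        X = np.column_stack([G, a])
        beta1, *_ = np.linalg.lstsq(X, bs, rcond=None)
        rss_alt = np.sum((bs - X @ beta1) ** 2)
        assert res.llr == pytest.approx((n / 2) * np.log(rss_null / rss_alt), abs=1e-8)

    def test_beta_pvalue_matches_permutation_oracle(self, rng):
        n, P = 30, 100_000
        e = rng.integers(0, 3, n)
        a = rng.standard_normal(n)
        b = 0.4 * a + rng.standard_normal(n)
        res = ct.llr_controlled(e, a, b)

        codes, k = ct.merge_genotype_categories(e)
        G = np.zeros((n, k))
        G[np.arange(n), codes] = 1
        counts = G.sum(axis=0)
        residA = a - (G @ ((G.T @ a) / counts))

        def r2_partial(mat):
            mc = (mat - mat.mean(axis=0)) / mat.std(axis=0)
            resid = mc - G @ ((G.T @ mc) / counts[:, None])
            num = residA @ resid
            return num**2 / ((residA @ residA) * (resid**2).sum(axis=0))

        obs = r2_partial(b[:, None])[0]
        perms = np.array([rng.permutation(b) for _ in range(P)]).T
        p_perm = (r2_partial(perms) >= obs - 1e-12).mean()
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-12) / P)
        assert abs(res.p_value - p_perm) < 4 * se + 2 / P


class TestLocalFdr:
    def _null_llrs(self, rng, n=500, m=400):
        e = rng.integers(0, 3, n)
        codes, k = ct.merge_genotype_categories(e)
        B = rng.standard_normal((n, m))
        out = ct._pair_tests_vectorized(codes, k, B)
        return out["llr2"], n, k

    def test_pure_null_row_mean_posterior_small(self, rng):
        llrs, n, k = self._null_llrs(rng)
        model = ct.fit_local_fdr(llrs, n, k, test="secondary")
        assert np.nanmean(model.posterior(llrs)) <= 0.05

    def test_mixture_recovery(self, rng):
        n, m = 800, 400
        e = rng.integers(0, 3, n)
        codes, k = ct.merge_genotype_categories(e)
        B = rng.standard_normal((n, m))
        B[:, : m // 2] += 0.35 * (e - e.mean())[:, None]  # strong signal half
        out = ct._pair_tests_vectorized(codes, k, B)
        model = ct.fit_local_fdr(out["llr2"], n, k, test="secondary")
        post = model.posterior(out["llr2"])
        assert abs(post.mean() - 0.5) < 0.1
        assert post[: m // 2].mean() > 0.8
        assert post[m // 2 :].mean() < 0.25

    def test_posterior_monotone_in_llr(self, rng):
        llrs, n, k = self._null_llrs(rng)
        model = ct.fit_local_fdr(llrs, n, k)
        assert np.all(np.diff(model.posterior_bins) >= -1e-12)
        grid = np.linspace(0, llrs.max(), 50)
        assert np.all(np.diff(model.posterior(grid)) >= -1e-12)

    def test_degenerate_all_equal_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="degenerate"):
            model = ct.fit_local_fdr(np.full(200, 2.0), 100, 3)
        assert np.all(model.posterior(np.array([0.0, 2.0])) == 0.0)


def _two_protein_truth(beta: float, cis: float, loadings: np.ndarray | None = None):
    n_conf = 0 if loadings is None else loadings.shape[1]
    return TruthNetwork(
        n_proteins=2,
        edges=np.array([[0, 1]]) if beta else np.zeros((0, 2), dtype=int),
        betas=np.array([beta]) if beta else np.zeros(0),
        cis_snp=np.array([0, -1]),
        cis_var=np.array([cis, 0.0]),
        confounder_loadings=np.zeros((2, n_conf)) if loadings is None else loadings,
    )


def _score_pair(truth, n, seed, extra_null_proteins=120):
    """Score the (0 -> 1) pair inside a row padded with null proteins."""
    import dataclasses

    rng = np.random.default_rng(seed)
    geno = generate_genotypes(n, 2, seed=seed, pos=[1_000_000, 2_000_000])
    prot = simulate_proteins(geno, truth, seed=seed + 1000)
    pad = rng.standard_normal((n, extra_null_proteins))
    values = np.column_stack([prot.values, pad])
    p = 2 + extra_null_proteins
    prot = dataclasses.replace(
        prot,
        values=values,
        aptamer_ids=np.array([f"APT{i:04d}" for i in range(p)], dtype=object),
        gene=np.array([f"GENE{i:04d}" for i in range(p)], dtype=object),
        gene_chrom=np.array(["1"] * p, dtype=object),
        gene_tss=(np.arange(p) + 1) * 1_000_000,
    )
    vals = supernormalize_matrix(prot.values)
    import pandas as pd

    instruments = pd.DataFrame(
        {"aptamer_id": ["APT0000"], "lead_snp": ["rs000000"], "lead_snp_idx": [0]}
    )
    scores = ct.score_all_pairs(instruments, prot, geno, values=vals)
    return scores


class TestScoreAllPairs:
    def test_planted_edge_recovers_high_pp(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            truth = _two_protein_truth(beta=0.5, cis=0.2)
            scores = _score_pair(truth, n=2000, seed=seed)
            pp = scores.loc[scores["b"] == "APT0001", "pp"].iloc[0]
            hits += pp > 0.9
        assert hits >= 0.9 * n_seeds

    def test_confounded_only_pair_stays_low(self):
        pps = []
        for seed in range(11):
            loadings = np.array([[0.6], [0.6]])  # shared latent factor, no edge
            truth = _two_protein_truth(beta=0.0, cis=0.2, loadings=loadings)
            scores = _score_pair(truth, n=2000, seed=100 + seed)
            pps.append(scores.loc[scores["b"] == "APT0001", "pp"].iloc[0])
        assert np.median(pps) < 0.2

    def test_own_gene_aptamers_excluded(self, rng):
        import dataclasses
        import pandas as pd

        n = 300
        geno = generate_genotypes(n, 1, seed=3, pos=[1_000_000])
        truth = cis_only_truth(1, [0], 0.3)
        prot = simulate_proteins(geno, truth, seed=4)
        # three aptamers: two map to GENE0000 (one is A itself), one to another gene
        values = np.column_stack([prot.values[:, 0], rng.standard_normal((n, 2))])
        prot = dataclasses.replace(
            prot,
            values=values,
            aptamer_ids=np.array(["APT0000", "APT0001", "APT0002"], dtype=object),
            gene=np.array(["GENE0000", "GENE0000", "GENE0002"], dtype=object),
            gene_chrom=np.array(["1"] * 3, dtype=object),
            gene_tss=np.array([1_000_000, 1_000_000, 3_000_000]),
        )
        instruments = pd.DataFrame(
            {"aptamer_id": ["APT0000"], "lead_snp": ["rs000000"], "lead_snp_idx": [0]}
        )
        scores = ct.score_all_pairs(
            instruments, prot, geno, values=supernormalize_matrix(prot.values)
        )
        assert set(scores["b"]) == {"APT0002"}


class TestBayesianFdrSelect:
    def test_hand_computed_prefix(self):
        thr, mask, achieved = ct.bayesian_fdr_select(np.array([0.99, 0.99, 0.96]), 0.02)
        assert mask.all()
        assert thr == pytest.approx(0.96)
        assert achieved == pytest.approx(1 - np.mean([0.99, 0.99, 0.96]))

    def test_single_low_pp_empty_selection(self):
        thr, mask, achieved = ct.bayesian_fdr_select(np.array([0.9]), 0.01)
        assert thr is None and achieved is None and not mask.any()

    def test_all_high_pp_selected(self):
        pp = np.full(10, 0.995)
        thr, mask, achieved = ct.bayesian_fdr_select(pp, 0.01)
        assert mask.all()
        assert achieved == pytest.approx(0.005)

    def test_selection_grows_with_target(self, rng):
        pp = rng.uniform(size=300) ** 0.3
        prev = np.zeros(300, dtype=bool)
        for target in (0.01, 0.05, 0.10, 0.2):
            _, mask, _ = ct.bayesian_fdr_select(pp, target)
            assert (prev & ~mask).sum() == 0  # never shrinks
            prev = mask

    def test_invalid_pp_rejected(self):
        with pytest.raises(ValueError):
            ct.bayesian_fdr_select(np.array([0.5, 1.2]), 0.05)

    def test_selected_pp_bounded_by_threshold(self, rng):
        pp = rng.uniform(size=500)
        thr, mask, _ = ct.bayesian_fdr_select(pp, 0.3)
        if thr is not None:
            assert pp[mask].min() == pytest.approx(thr)
            assert pp[~mask].max() <= thr + 1e-12
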