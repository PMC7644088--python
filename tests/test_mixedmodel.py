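"""Kinship, variance components, the Gxtheta LRT, scans, inflation, replication."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import gxtheta as gx
from gxtheta.data_model import AncestryVector, GenotypeMatrix, KinshipMatrix, PhenotypeTable
from gxtheta.mixedmodel import (
    LMMSolver,
    compute_grm,
    fit_variance_components,
    genome_scan,
    genomic_inflation,
    gxtheta_test,
    replication_rate,
    replication_test,
)
from gxtheta.simulate import mvn_factor, simulate_phenotype


def _geno(dosages):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(m)],
        "chrom": ["1"] * m,
        "bp": list(range(1, m + 1)),
    })
    return GenotypeMatrix([f"ind{i}" for i in range(n)], snps, dosages)


class TestComputeGrm:
    def test_duplicate_individuals_have_equal_entries(self):
        G = _geno([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]])
        K = compute_grm(G, standardize=False).values
        assert K[0, 0] == pytest.approx(K[0, 1])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_hand_computed_toy_matrix(self):
        D = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        K = compute_grm(_geno(D), standardize=False).values
        Z = D - D.mean(axis=0)
        np.testing.assert_allclose(K, Z @ Z.T / 2, atol=1e-12)

    def test_column_permutation_invariant(self):
        rng = np.random.default_rng(2)
        D = rng.choice([0.0, 1.0], size=(10, 30))
        K1 = compute_grm(_geno(D)).values
        K2 = compute_grm(_geno(D[:, rng.permutation(30)])).values
        np.testing.assert_allclose(K1, K2, atol=1e-12)

    def test_standardized_diagonal_near_one(self, ri_panel, ri_K):
        assert np.diag(ri_K.values).mean() == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_snp_dropped_with_warning(self):
        D = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            compute_grm(_geno(D))


class TestVarianceComponents:
    def test_identity_kinship_matches_ols_residual_variance(self):
        rng = np.random.default_rng(0)
        n = 60
        y = rng.standard_normal(n)
        C = np.column_stack([np.ones(n), rng.uniform(size=n)])
        vc = fit_variance_components(y, C, np.eye(n))
        ols_ml_var = sm.OLS(y, C).fit().ssr / n
        assert vc.sigma_g2 + vc.sigma_e2 == pytest.approx(ols_ml_var, abs=1e-6)

    def test_optimum_beats_grid_search(self, ri_panel, ri_K):
        rng = np.random.default_rng(12)
        n = ri_K.n
        L = mvn_factor(ri_K, sigma_g2=0.5, sigma_e2=0.5)
        y = L @ rng.standard_normal(n)
        C = np.ones((n, 1))
        solver = LMMSolver(ri_K.values)
        vc = solver.fit(y, C)
        # independent 50-point grid oracle over the heritability ratio
        S, U = np.linalg.eigh(ri_K.values)
        S = np.clip(S, 0, None)
        yr, Cr = U.T @ y, U.T @ C
        best = -np.inf
        for h in np.linspace(0.0, 0.99, 50):
            w = np.maximum(h * S + (1 - h), 1e-12)
            beta, *_ = np.linalg.lstsq(Cr / np.sqrt(w)[:, None], yr / np.sqrt(w), rcond=None)
            rss = np.sum((yr - Cr @ beta) ** 2 / w)
            s2 = rss / n
            ll = -0.5 * (n * np.log(2 * np.pi * s2) + np.sum(np.log(w)) + n)
            best = max(best, ll)
        assert vc.loglik >= best - 1e-6

    def test_two_grm_nests_single_grm(self, ri_panel, ri_K):
        rng = np.random.default_rng(13)
        n = ri_K.n
        y = mvn_factor(ri_K, sigma_g2=0.4, sigma_e2=0.6) @ rng.standard_normal(n)
        C = np.ones((n, 1))
        # distinct second GRM from an unrelated random genotype block
        D2 = rng.choice([0.0, 1.0], size=(n, 80))
        K_A = compute_grm(_geno(D2))
        ll1 = LMMSolver(ri_K.values).fit(y, C).loglik
        vc2 = LMMSolver(ri_K.values, K_A.values).fit(y, C)
        assert vc2.loglik >= ll1 - 1e-3

    def test_misaligned_inputs_error(self):
        with pytest.raises(ValueError, match="misaligned"):
            LMMSolver(np.eye(5)).fit(np.zeros(4), np.ones((4, 1)))


class TestGxthetaTest:
    def test_identity_kinship_equals_ols_lrt(self):
        rng = np.random.default_rng(0)
        n = 60
        y = rng.standard_normal(n)
        x = rng.integers(0, 2, n).astype(float)
        th = rng.uniform(0.3, 0.7, n)
        r = gxtheta_test(y, x, th, K=np.eye(n))
        X0 = sm.add_constant(np.column_stack([x, th]))
        X1 = sm.add_constant(np.column_stack([x, th, th * x]))
        lrt_ols = 2 * (sm.OLS(y, X1).fit().llf - sm.OLS(y, X0).fit().llf)
        assert r.lrt_stat == pytest.approx(lrt_ols, abs=1e-6)
        assert r.p_gxt == pytest.approx(stats.chi2.sf(lrt_ols, 1), abs=1e-9)

    def test_invariant_to_affine_y_and_theta_centering(self, ri_panel, ri_K, ri_theta):
        rng = np.random.default_rng(3)
        G = ri_panel.genotypes
        x = G.dosages[:, 40]
        y = rng.standard_normal(ri_K.n)
        solver = LMMSolver(ri_K.values)
        r1 = gxtheta_test(y, x, ri_theta, solver=solver)
        r2 = gxtheta_test(3.5 * y - 2.0, x, ri_theta, solver=solver)
        r3 = gxtheta_test(y, x, ri_theta - ri_theta.mean() + 0.0, solver=solver)
        assert r1.lrt_stat == pytest.approx(r2.lrt_stat, abs=1e-6)
        assert r1.lrt_stat == pytest.approx(r3.lrt_stat, abs=1e-6)

    def test_constant_snp_and_constant_theta_error(self):
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="invariant"):
            gxtheta_test(y, np.ones(10), np.linspace(0, 1, 10), K=np.eye(10))
        with pytest.raises(ValueError, match="theta"):
            gxtheta_test(y, np.arange(10.0) % 2, np.full(10, 0.5), K=np.eye(10))

    def test_null_pvalues_uniform(self, ri_panel, ri_K, ri_theta):
        """Kolmogorov-Smirnov check of p_gxt under the null on the RI panel."""
        rng = np.random.default_rng(100)
        G = ri_panel.genotypes
        solver = LMMSolver(ri_K.values)
        L = mvn_factor(ri_K, sigma_g2=0.4, sigma_e2=0.6)
        elig = np.flatnonzero(
            (G.dosages.mean(axis=0) > 0.25) & (G.dosages.mean(axis=0) < 0.75)
        )
        ps = []
        for _ in range(2000):
            j = elig[rng.integers(elig.size)]
            y = L @ rng.standard_normal(ri_K.n)
            ps.append(gxtheta_test(y, G.dosages[:, j], ri_theta, solver=solver).p_gxt)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_pure_main_effect_does_not_inflate_interaction(self, ri_panel, ri_K, ri_theta):
        rng = np.random.default_rng(101)
        G = ri_panel.genotypes
        solver = LMMSolver(ri_K.values)
        L = mvn_factor(ri_K, sigma_g2=0.4, sigma_e2=0.6)
        elig = np.flatnonzero(
            (G.dosages.mean(axis=0) > 0.25) & (G.dosages.mean(axis=0) < 0.75)
        )
        hits = 0
        n_reps = 400
        for _ in range(n_reps):
            j = elig[rng.integers(elig.size)]
            x = G.dosages[:, j]
            y = simulate_phenotype(x, ri_theta, beta=1.5, rng=rng, factor=L)
            hits += gxtheta_test(y, x, ri_theta, solver=solver).p_gxt < 0.05
        assert 0.02 <= hits / n_reps <= 0.09


@pytest.fixture(scope="module")
def scan_inputs(ri_panel, ri_K):
    G = ri_panel.genotypes
    rng = np.random.default_rng(55)
    L = mvn_factor(ri_K, sigma_g2=0.4, sigma_e2=0.6)
    noise = L @ rng.standard_normal(ri_K.n)
    return G, ri_panel.theta, ri_K, noise


class TestGenomeScan:

    def test_spike_in_recovery(self, scan_inputs):
        G, theta, K, noise = scan_inputs
        target = 777
        x = G.dosages[:, target]
        y = 4.0 * theta.theta * x + 0.5 * noise
        Y = PhenotypeTable(G.sample_ids, pd.DataFrame({"t": y}))
        results, _ = genome_scan(Y, "t", G, theta, K, maf_min=0.05)
        best = results.loc[results["p_gxt"].idxmin(), "snp_id"]
        assert best == G.snps["snp_id"].iloc[target]

    def test_deterministic_and_row_count(self, scan_inputs):
        G, theta, K, noise = scan_inputs
        Y = PhenotypeTable(G.sample_ids, pd.DataFrame({"t": noise}))
        r1, s1 = genome_scan(Y, "t", G, theta, K, maf_min=0.05)
        r2, s2 = genome_scan(Y, "t", G, theta, K, maf_min=0.05)
        pd.testing.assert_frame_equal(r1, r2)
        f = G.dosages.mean(axis=0)
        expected_rows = int(((np.minimum(f, 1 - f)) > 0.05).sum())
        assert len(r1) == expected_rows
        assert s1.n_snps_tested == s2.n_snps_tested

    def test_null_scan_lambda_calibrated(self, scan_inputs):
        G, theta, K, noise = scan_inputs
        Y = PhenotypeTable(G.sample_ids, pd.DataFrame({"t": noise}))
        _, summary = genome_scan(Y, "t", G, theta, K, maf_min=0.05)
        assert 0.8 <= summary.lambda_gxtc <= 1.2

    def test_constant_theta_aborts(self, scan_inputs):
        G, theta, K, noise = scan_inputs
        Y = PhenotypeTable(G.sample_ids, pd.DataFrame({"t": noise}))
        flat = AncestryVector(G.sample_ids, np.full(len(G.sample_ids), 0.5))
        with pytest.raises(ValueError, match="constant"):
            genome_scan(Y, "t", G, flat, K)


class TestGenomicInflation:
    def test_single_median_p(self):
        assert genomic_inflation([0.5]) == pytest.approx(1.0)

    def test_uniform_null(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=100_000)
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_halving_increases_lambda(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=5000)
        assert genomic_inflation(p / 2) > genomic_inflation(p)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            genomic_inflation([])


class TestReplication:
    def test_enumeration_oracle_small_case(self):
        from math import comb

        _, _, frac, p = replication_test(10, 3, 0.05)
        exact = sum(comb(10, k) * 0.05**k * 0.95 ** (10 - k) for k in range(3, 11))
        assert p == pytest.approx(exact, rel=1e-12)
        assert frac == pytest.approx(0.3)

    def test_null_rate_input_not_significant(self):
        n = 400
        k = round(0.05 * n)
        *_, p = replication_test(n, k, 0.05)
        assert p >= 0.4

    def test_matching_on_keys(self):
        a = pd.DataFrame({"snp_id": ["a", "b", "c"]})
        b = pd.DataFrame({"snp_id": ["b", "c", "d"], "p_gxt": [0.01, 0.5, 0.001]})
        n_total, n_rep, frac, p = replication_rate(a, b, alpha=0.05)
        assert (n_total, n_rep) == (2, 1)
        assert frac == pytest.approx(0.5)

    def test_no_overlap_errors(self):
        a = pd.DataFrame({"snp_id": ["a"]})
        b = pd.DataFrame({"snp_id": ["z"], "p_gxt": [0.5]})
        with pytest.raises(ValueError):
            replication_rate(a, b)
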