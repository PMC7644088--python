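"""Allelic-imbalance Wald scan, BH correction, region chaining, binomial tails."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxtheta.imbalance import (
    bh_correct,
    binomial_imbalance_probability,
    cluster_regions,
    expected_distorted_snps,
    wald_scan,
)


class TestWaldScan:
    def test_null_site_has_zero_statistic(self):
        rec = wald_scan([0.5, 0.5, 0.6], theta_bar=0.5, var_theta=0.01)
        assert rec["W"].iloc[0] == 0.0
        assert rec["p"].iloc[0] == 1.0

    def test_direct_formula(self):
        rec = wald_scan([0.8], theta_bar=0.5, var_theta=0.0081)
        W = rec["W"].iloc[0]
        assert W == pytest.approx(0.09 / 0.0081)
        assert rec["p"].iloc[0] == pytest.approx(stats.chi2.sf(W, 1))
        assert rec["p"].iloc[0] == pytest.approx(8.6e-4, rel=0.02)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            wald_scan([0.5, 0.5], var_theta=0.0)

    def test_nan_sites_excluded(self):
        rec = wald_scan([0.5, np.nan, 0.7], theta_bar=0.5, var_theta=0.01)
        assert len(rec) == 2

    def test_null_panel_calibrated_and_planted_locus_top(self):
        """On a selected RI panel the planted locus dominates W and the rest
        of the genome stays roughly calibrated."""
        from gxtheta.panels import ChromosomeSpec, PanelSpec, simulate_ri_panel
        from gxtheta.mixedmodel import genomic_inflation

        spec = PanelSpec(
            n_strains=100,
            chromosomes=[ChromosomeSpec(str(c + 1), 80.0, 400) for c in range(5)],
            panel_type="RI",
            selection=[("3", 80_000_000, "A", 0.9)],
            seed=2024,
        )
        res = simulate_ri_panel(spec)
        theta_i = res.genotypes.dosages.mean(axis=0)
        # a whole-chromosome sweep inflates the all-site variance, so anchor
        # the null scale on the unselected chromosomes (supplied var_theta)
        off_mask = (res.genotypes.snps["chrom"] != "3").to_numpy()
        rec = wald_scan(
            theta_i, snps=res.genotypes.snps,
            theta_bar=float(theta_i[off_mask].mean()),
            var_theta=float(theta_i[off_mask].var()),
        )
        top = rec.loc[rec["W"].idxmax()]
        assert top["chrom"] == "3"
        # off-target chromosomes stay near-calibrated
        off = rec[rec["chrom"] != "3"]
        lam = genomic_inflation(off["p"].to_numpy())
        assert 0.8 <= lam <= 1.2


class TestBhCorrect:
    def test_all_null(self):
        q, sig = bh_correct(np.ones(10))
        assert not sig.any()

    def test_hand_computed_step_up(self):
        q, sig = bh_correct([0.01, 0.02, 0.03, 0.5], q_target=0.05)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.5])
        assert list(sig) == [True, True, True, False]

    def test_order_invariance(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=50) ** 3
        perm = rng.permutation(50)
        q1, sig1 = bh_correct(p)
        q2, sig2 = bh_correct(p[perm])
        np.testing.assert_allclose(q1[perm], q2)
        np.testing.assert_array_equal(sig1[perm], sig2)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bh_correct([])


def _records(chroms, bps, theta=0.8, p=1e-4):
    return pd.DataFrame({
        "chrom": chroms, "bp": bps,
        "theta_i": theta, "p": p,
    })


class TestClusterRegions:
    def test_gap_splits_chain(self):
        df = _records(["1"] * 6, [1e6, 1.2e6, 1.4e6, 1.6e6, 1.8e6, 12e6])
        regions = cluster_regions(df, min_cluster=5, max_gap_bp=2_000_000)
        assert len(regions) == 1
        assert regions[0].n_snps == 5
        assert regions[0].end_bp == int(1.8e6)

    def test_below_min_cluster_no_region(self):
        df = _records(["1"] * 4, [1e6, 1.1e6, 1.2e6, 1.3e6])
        assert cluster_regions(df) == []

    def test_mean_ancestry_reported_as_percent(self):
        df = _records(["2"] * 5, np.arange(5) * 1e5, theta=0.82)
        r = cluster_regions(df)[0]
        assert r.mean_ancestry_pct == pytest.approx(82.0)

    def test_matches_brute_force_interval_merge(self):
        rng = np.random.default_rng(23)
        rows = []
        for chrom in ["1", "2", "3"]:
            bp = np.sort(rng.choice(np.arange(1, 200) * 500_000, size=60, replace=False))
            rows.append(pd.DataFrame({"chrom": chrom, "bp": bp, "theta_i": 0.8, "p": 1e-3}))
        df = pd.concat(rows, ignore_index=True)
        regions = cluster_regions(df, min_cluster=5, max_gap_bp=2_000_000)
        # independent chaining oracle
        oracle = []
        for chrom in ["1", "2", "3"]:
            bps = sorted(df[df.chrom == chrom]["bp"])
            chain = [bps[0]]
            for b in bps[1:]:
                if b - chain[-1] <= 2_000_000:
                    chain.append(b)
                else:
                    if len(chain) >= 5:
                        oracle.append((chrom, chain[0], chain[-1], len(chain)))
                    chain = [b]
            if len(chain) >= 5:
                oracle.append((chrom, chain[0], chain[-1], len(chain)))
        got = [(r.chrom, r.start_bp, r.end_bp, r.n_snps) for r in regions]
        assert got == oracle

    def test_empty_in_empty_out(self):
        assert cluster_regions(_records([], [])) == []


class TestBinomialImbalance:
    def test_two_lines_fully_imbalanced(self):
        # Binomial(2, 0.5): P(X=2) + P(X=0) = 0.5
        assert binomial_imbalance_probability(2, 1.0) == pytest.approx(0.5)

    def test_full_enumeration_n10(self):
        # P(X>=8) + P(X<=2) = 2*(45+10+1)/1024
        expected = 2 * (45 + 10 + 1) / 1024
        assert binomial_imbalance_probability(10, 0.8) == pytest.approx(expected, rel=1e-12)

    def test_one_sided_is_half_of_symmetric_two_sided(self):
        two = binomial_imbalance_probability(10, 0.8, two_sided=True)
        one = binomial_imbalance_probability(10, 0.8, two_sided=False)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_monotone_in_fraction_and_n(self):
        fr = [0.6, 0.7, 0.8, 0.9]
        vals = [binomial_imbalance_probability(50, f) for f in fr]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        ns = [20, 50, 100, 200]
        vals = [binomial_imbalance_probability(n, 0.7) for n in ns]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_imbalance_probability(10, 0.5)
        with pytest.raises(ValueError):
            binomial_imbalance_probability(0, 0.8)


class TestExpectedDistortedSnps:
    def test_zero_snps(self):
        assert expected_distorted_snps(0, 0.5) == 0.0

    def test_unit_product(self):
        assert expected_distorted_snps(10**6, 1e-6) == pytest.approx(1.0)
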