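"""Linear mixed models for the Gxtheta interaction test.

The model for one SNP i is

    y = mu + beta_i x_i + delta theta + beta_gxt_i (theta * x_i) + u + e,

with u ~ N(0, sigma_g^2 K) the polygenic random effect (optionally plus a
second component sigma_theta^2 K_A on an ancestry-informative GRM) and
e ~ N(0, sigma_e^2 I).  The Gxtheta test is a 1-df likelihood-ratio test of
beta_gxt_i = 0.

Fitting follows the EMMA/pyLMM lineage: maximum likelihood (not REML), with
the single-GRM likelihood profiled over the heritability ratio
h = sigma_g^2 / (sigma_g^2 + sigma_e^2) after a one-time eigendecomposition
of K.  Variance components are estimated once per trait under the no-SNP
covariate model and the resulting covariance is then held fixed for all
per-SNP generalized-least-squares fits (the standard EMMAX approximation);
``exact=True`` re-optimizes the components under both the null and the
alternative model for every SNP.

With the covariance fixed and the residual scale profiled by ML, the LRT
reduces to n * log(RSS_null / RSS_alt) on whitened data, which coincides
with the classic nested-OLS likelihood-ratio statistic when K = I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from gxtheta.data_model import (
    AncestryVector,
    GenotypeMatrix,
    KinshipMatrix,
    PhenotypeTable,
    filter_maf,
    mean_impute,
)

__all__ = [
    "VarianceComponents",
    "GxThetaResult",
    "ScanSummary",
    "LMMSolver",
    "compute_grm",
    "fit_variance_components",
    "gxtheta_test",
    "genome_scan",
    "genomic_inflation",
    "replication_rate",
    "replication_test",
]

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)

#: numerical floor applied to reported p-values
P_FLOOR = 1e-300

#: LRT statistics in [-LRT_TOL, 0) are treated as exact zeros
LRT_TOL = 1e-8


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

def compute_grm(G: GenotypeMatrix, standardize: bool = True, label: str = "K") -> KinshipMatrix:
    """Genetic relationship matrix K = Z Z^T / m from column-centered dosages.

    Under ``standardize`` each centered column is also scaled to unit
    variance (zero-variance SNPs are dropped with a warning), which puts the
    diagonal mean at ~1.  Missing dosages must be imputed beforehand.
    """
    D = np.asarray(G.dosages, dtype=float)
    if not np.isfinite(D).all():
        raise ValueError("compute_grm requires imputed (non-missing) dosages")
    if D.shape[1] < 2:
        raise ValueError("need at least 2 SNPs to form a GRM")
    Z = D - D.mean(axis=0)
    if standardize:
        sd = Z.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {np.count_nonzero(~keep)} zero-variance SNPs from GRM",
                UserWarning,
            )
        Z = Z[:, keep] / sd[keep]
    m = Z.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs left for the GRM")
    K = Z @ Z.T / m
    K = (K + K.T) / 2.0
    return KinshipMatrix(G.sample_ids, K, label=label)


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """ML variance-component estimates for one trait.

    ``sigma_g2``/``sigma_e2`` (and ``sigma_theta2`` for the two-GRM model)
    are on the scale of the phenotype; ``loglik`` is the profile maximum.
    ``whitener`` is the matrix W with W V W^T = sigma^2 I used for the
    per-SNP GLS fits; it is an implementation detail and excluded from repr.
    """

    sigma_g2: float
    sigma_e2: float
    loglik: float
    sigma_theta2: float | None = None
    whitener: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        for name in ("sigma_g2", "sigma_e2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.sigma_theta2 is not None and (
            not np.isfinite(self.sigma_theta2) or self.sigma_theta2 < 0
        ):
            raise ValueError("sigma_theta2 must be finite and non-negative")
        total = self.sigma_g2 + self.sigma_e2 + (self.sigma_theta2 or 0.0)
        if total <= 0:
            raise ValueError("total variance must be positive")

    @property
    def heritability(self) -> float:
        """sigma_g^2 / (total variance)."""
        return self.sigma_g2 / (
            self.sigma_g2 + self.sigma_e2 + (self.sigma_theta2 or 0.0)
        )


def _ml_loglik_weighted(yr: np.ndarray, Xr: np.ndarray, w: np.ndarray):
    """Profile ML log-likelihood given rotated data and variance weights w.

    Model: y ~ N(X b, sigma^2 diag(w)) in the rotated basis; b and sigma^2
    are profiled out analytically.
    """
    n = yr.shape[0]
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(Xr / sw[:, None], yr / sw, rcond=None)
    resid = yr - Xr @ beta
    rss = float(np.sum(resid**2 / w))
    sigma2 = rss / n
    ll = -0.5 * (
        n * np.log(2 * np.pi * sigma2) + np.sum(np.log(w)) + n
    )
    return ll, sigma2, beta


class LMMSolver:
    """Caches the eigendecomposition of K for repeated per-trait fits.

    Parameters
    ----------
    K : KinshipMatrix or ndarray
        Genome-wide GRM.
    K_A : KinshipMatrix or ndarray, optional
        Second GRM (ancestry-informative SNPs); switches fitting to the
        two-variance-component path, which cannot be jointly diagonalized
        and uses Cholesky factorizations per likelihood evaluation instead.
    """

    #: grid used both for initialization and as an optimizer safety net
    H_GRID = np.concatenate([np.linspace(0.0, 0.95, 20), [0.99]])

    def __init__(self, K, K_A=None):
        Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
        self.K = Kv
        self.n = Kv.shape[0]
        self.K_A = (
            K_A.values if isinstance(K_A, KinshipMatrix) else None if K_A is None else np.asarray(K_A, float)
        )
        if self.K_A is None:
            S, U = np.linalg.eigh(Kv)
            self.S = np.clip(S, 0.0, None)
            self.U = U

    # -- single-GRM path ----------------------------------------------------

    def _fit_1k(self, y, X):
        yr = self.U.T @ y
        Xr = self.U.T @ X
        n = self.n

        def neg_ll(h):
            w = h * self.S + (1.0 - h)
            w = np.maximum(w, 1e-12)
            return -_ml_loglik_weighted(yr, Xr, w)[0]

        grid_vals = np.array([neg_ll(h) for h in self.H_GRID])
        i = int(np.argmin(grid_vals))
        lo = self.H_GRID[max(i - 1, 0)]
        hi = min(self.H_GRID[min(i + 1, len(self.H_GRID) - 1)], 0.999999)
        res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded")
        h = float(res.x) if res.fun <= grid_vals[i] else float(self.H_GRID[i])
        w = np.maximum(h * self.S + (1.0 - h), 1e-12)
        ll, sigma2, _ = _ml_loglik_weighted(yr, Xr, w)
        whitener = (self.U / np.sqrt(w)).T  # rows: u_j^T / sqrt(w_j)
        return VarianceComponents(
            sigma_g2=h * sigma2,
            sigma_e2=(1.0 - h) * sigma2,
            loglik=ll,
            whitener=whitener,
        )

    # -- two-GRM path -------------------------------------------------------

    def _chol_whiten(self, a, b):
        M = a * self.K + (1.0 - a - b) * np.eye(self.n)
        if b:
            M = M + b * self.K_A
        L = np.linalg.cholesky(M + 1e-10 * np.eye(self.n))
        return L

    def _ll_2k(self, params, y, X):
        a, b = params
        if a < 0 or b < 0 or a + b > 0.999:
            return -np.inf, None, None
        try:
            L = self._chol_whiten(a, b)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        from scipy.linalg import solve_triangular

        yw = solve_triangular(L, y, lower=True)
        Xw = solve_triangular(L, X, lower=True)
        n = self.n
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rss = float(np.sum((yw - Xw @ beta) ** 2))
        sigma2 = rss / n
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
        return ll, sigma2, L

    def _fit_2k(self, y, X):
        # coarse simplex grid, then Nelder-Mead in softmax coordinates
        best = (-np.inf, (0.0, 0.0))
        for a in np.linspace(0.0, 0.8, 5):
            for b in np.linspace(0.0, 0.8, 5):
                if a + b > 0.95:
                    continue
                ll, _, _ = self._ll_2k((a, b), y, X)
                if ll > best[0]:
                    best = (ll, (a, b))

        def neg_ll_z(z):
            e1, e2 = np.exp(z[0]), np.exp(z[1])
            tot = 1.0 + e1 + e2
            ll, _, _ = self._ll_2k((0.999 * e1 / tot, 0.999 * e2 / tot), y, X)
            return -ll

        a0, b0 = best[1]
        c0 = max(1.0 - a0 - b0, 1e-3)
        z0 = np.log([max(a0, 1e-3) / c0, max(b0, 1e-3) / c0])
        res = optimize.minimize(neg_ll_z, z0, method="Nelder-Mead",
                                options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 200})
        e1, e2 = np.exp(res.x)
        tot = 1.0 + e1 + e2
        a, b = 0.999 * e1 / tot, 0.999 * e2 / tot
        ll, sigma2, L = self._ll_2k((a, b), y, X)
        if ll < best[0]:  # fall back to the grid optimum
            a, b = best[1]
            ll, sigma2, L = self._ll_2k((a, b), y, X)
        from scipy.linalg import solve_triangular

        whitener = solve_triangular(L, np.eye(self.n), lower=True)
        return VarianceComponents(
            sigma_g2=a * sigma2,
            sigma_e2=(1.0 - a - b) * sigma2,
            sigma_theta2=b * sigma2,
            loglik=ll,
            whitener=whitener,
        )

    def fit(self, y, X) -> VarianceComponents:
        y = np.asarray(y, float)
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != self.n or y.shape != (self.n,):
            raise ValueError("y/X misaligned with the kinship matrix")
        if not np.isfinite(y).all() or not np.isfinite(X).all():
            raise ValueError("y and X must be finite (drop missing values first)")
        if self.n < X.shape[1] + 2:
            raise ValueError("need n >= number of fixed effects + 2")
        if self.K_A is None:
            return self._fit_1k(y, X)
        return self._fit_2k(y, X)

    def max_loglik(self, y, X) -> float:
        """Full-ML maximized log-likelihood for fixed effects X (exact path)."""
        return self.fit(y, X).loglik


def fit_variance_components(y, C, K, K_A=None) -> VarianceComponents:
    """ML variance components of y given fixed effects C and GRM(s).

    ``C`` should include the intercept (a column of ones is prepended when
    absent).  Single-GRM fits profile the likelihood over the heritability
    ratio after one eigendecomposition; two-GRM fits optimize over both
    component proportions.
    """
    C = _with_intercept(np.asarray(C, float), len(np.asarray(y)))
    return LMMSolver(K, K_A).fit(np.asarray(y, float), C)


def _with_intercept(C, n):
    if C is None or C.size == 0:
        return np.ones((n, 1))
    C = np.atleast_2d(C)
    if C.shape[0] != n:
        C = C.T
    if not np.any(np.all(C == C[0, :], axis=0) & (C[0, :] != 0)):
        C = np.column_stack([np.ones(n), C])
    return C


# ---------------------------------------------------------------------------
# The Gxtheta test
# ---------------------------------------------------------------------------

@dataclass
class GxThetaResult:
    """Per-SNP estimates and tests from the interaction model."""

    snp_id: str
    beta_g: float
    delta: float
    beta_gxt: float
    lrt_stat: float
    p_gxt: float
    p_g: float
    n_used: int


def _ols_rss(Xw, yw, label=""):
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < Xw.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient{(' for ' + label) if label else ''}"
        )
    resid = yw - Xw @ beta
    return float(resid @ resid), beta


def gxtheta_test(
    y,
    x,
    theta,
    C=None,
    K=None,
    K_A=None,
    vc: VarianceComponents | None = None,
    solver: LMMSolver | None = None,
    exact: bool = False,
    snp_id: str = "",
) -> GxThetaResult:
    """Likelihood-ratio test of a SNP-by-ancestry interaction for one SNP.

    The alternative model regresses y on (intercept, C, x, theta, theta*x);
    the null drops only the interaction column.  Both are fitted by GLS
    under the covariance implied by ``vc`` (estimated under the no-SNP
    covariate model when not supplied).  ``p_g`` is the Wald test of the
    SNP main effect in the alternative model.

    With ``exact=True`` the variance components are re-optimized under both
    models and the LRT uses the full ML log-likelihoods.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    th = theta.theta if isinstance(theta, AncestryVector) else np.asarray(theta, float)
    n = y.shape[0]
    if x.shape != (n,) or th.shape != (n,):
        raise ValueError("y, x and theta must have equal length")
    if np.ptp(x) == 0:
        raise ValueError(f"SNP {snp_id or '<unnamed>'} is invariant in the analyzed samples")
    if np.ptp(th) == 0:
        raise ValueError("theta is constant; the interaction test is undefined")

    Cmat = _with_intercept(None if C is None else np.asarray(C, float), n)
    if solver is None:
        solver = LMMSolver(K if K is not None else np.eye(n), K_A)
    X0 = np.column_stack([Cmat, x, th])
    X1 = np.column_stack([X0, th * x])

    if exact:
        ll0 = solver.max_loglik(y, X0)
        vc1 = solver.fit(y, X1)
        ll1, W = vc1.loglik, vc1.whitener
        lrt = 2.0 * (ll1 - ll0)
    else:
        if vc is None:
            vc = solver.fit(y, np.column_stack([Cmat, th]))
        W = vc.whitener
        yw = W @ y
        try:
            rss0, _ = _ols_rss(W @ X0, yw, label=f"null model of SNP {snp_id}")
            rss1, beta1 = _ols_rss(W @ X1, yw, label=f"SNP {snp_id} (theta*x collinear?)")
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(str(e)) from None
        lrt = n * np.log(rss0 / rss1)

    if lrt < 0:
        if lrt < -LRT_TOL:
            warnings.warn(f"negative LRT {lrt:.3g} clipped to 0", UserWarning)
        lrt = 0.0
    p_gxt = max(float(stats.chi2.sf(lrt, 1)), P_FLOOR)

    # Wald z for the SNP main effect from the (approximate) alternative fit
    if exact:
        yw = W @ y
        rss1, beta1 = _ols_rss(W @ X1, yw)
    Xw1 = W @ X1
    sigma2_ml = rss1 / n
    XtX_inv = np.linalg.inv(Xw1.T @ Xw1)
    k_x = Cmat.shape[1]  # column index of x in X1
    se = float(np.sqrt(sigma2_ml * XtX_inv[k_x, k_x]))
    z = beta1[k_x] / se if se > 0 else 0.0
    p_g = max(float(2.0 * stats.norm.sf(abs(z))), P_FLOOR)

    return GxThetaResult(
        snp_id=snp_id,
        beta_g=float(beta1[k_x]),
        delta=float(beta1[k_x + 1]),
        beta_gxt=float(beta1[k_x + 2]),
        lrt_stat=float(lrt),
        p_gxt=p_gxt,
        p_g=p_g,
        n_used=n,
    )


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

@dataclass
class ScanSummary:
    """Calibration and hit-count summary of one genome scan."""

    lambda_gc: float
    lambda_gxtc: float
    n_snps_tested: int
    threshold: float
    n_hits: int

    def __post_init__(self):
        if self.lambda_gc <= 0 or self.lambda_gxtc <= 0:
            raise ValueError("genomic inflation factors must be positive")


def genome_scan(
    Y: PhenotypeTable,
    trait: str,
    G: GenotypeMatrix,
    theta: AncestryVector,
    K: KinshipMatrix,
    K_A: KinshipMatrix | None = None,
    covariate_names=None,
    maf_min: float = 0.05,
    threshold: float = 4.2e-6,
    fdr: float | None = None,
    exact: bool = False,
):
    """Run the Gxtheta test across all MAF-passing SNPs for one trait.

    Samples with a missing phenotype (or covariate) are dropped pairwise;
    the GRM is subset accordingly.  Returns ``(results, summary)`` where
    ``results`` is a DataFrame with one row per tested SNP (columns
    ``snp_id chrom bp beta_g delta beta_gxt lrt p_gxt p_g n_used`` plus
    ``q_gxt``/``significant`` in FDR mode) and ``summary`` a
    :class:`ScanSummary` with both genomic inflation factors.
    """
    Ya = Y.align_to(G.sample_ids)
    y = Ya.traits[trait].to_numpy(dtype=float)
    Cdf = None
    if covariate_names:
        if Ya.covariates is None:
            raise ValueError("covariates requested but none present")
        Cdf = Ya.covariates[list(covariate_names)]
    keep = np.isfinite(y)
    if Cdf is not None:
        keep &= np.isfinite(Cdf.to_numpy(dtype=float)).all(axis=1)
    if keep.sum() < 3:
        raise ValueError(f"trait {trait!r}: fewer than 3 complete samples")
    idx = np.flatnonzero(keep)

    if theta.sample_ids != G.sample_ids:
        raise ValueError("theta must be aligned to the genotype samples")
    if K.sample_ids != G.sample_ids:
        raise ValueError("K must be aligned to the genotype samples")
    th = theta.theta[idx]
    if np.ptp(th) == 0:
        raise ValueError("theta is constant across analyzed samples; Gxtheta scan undefined")
    y = y[idx]
    Gs = G.take_samples(idx)
    Kv = K.values[np.ix_(idx, idx)]
    KAv = K_A.values[np.ix_(idx, idx)] if K_A is not None else None
    Cmat = Cdf.to_numpy(dtype=float)[idx] if Cdf is not None else None

    Gf = mean_impute(filter_maf(Gs, maf_min))
    if Gf.n_snps == 0:
        warnings.warn("no SNPs pass the MAF filter; empty scan", UserWarning)
        return (
            pd.DataFrame(
                columns="snp_id chrom bp beta_g delta beta_gxt lrt p_gxt p_g n_used".split()
            ),
            None,
        )

    solver = LMMSolver(Kv, KAv)
    base = _with_intercept(Cmat, len(y))
    vc = solver.fit(y, np.column_stack([base, th]))

    rows = []
    for j in range(Gf.n_snps):
        rec = Gf.snps.iloc[j]
        x = Gf.dosages[:, j]
        try:
            r = gxtheta_test(
                y, x, th, C=Cmat, solver=solver, vc=vc, exact=exact, snp_id=str(rec.snp_id)
            )
        except (ValueError, np.linalg.LinAlgError) as e:
            warnings.warn(f"SNP {rec.snp_id}: {e}; skipped", UserWarning)
            continue
        rows.append(
            (rec.snp_id, rec.chrom, rec.bp, r.beta_g, r.delta, r.beta_gxt,
             r.lrt_stat, r.p_gxt, r.p_g, r.n_used)
        )
    results = pd.DataFrame(
        rows,
        columns="snp_id chrom bp beta_g delta beta_gxt lrt p_gxt p_g n_used".split(),
    )
    if fdr is not None:
        from gxtheta.imbalance import bh_correct

        q, sig = bh_correct(results["p_gxt"].to_numpy(), q_target=fdr)
        results["q_gxt"] = q
        results["significant"] = sig
        n_hits = int(sig.sum())
    else:
        n_hits = int((results["p_gxt"] < threshold).sum())
    summary = ScanSummary(
        lambda_gc=genomic_inflation(results["p_g"].to_numpy()),
        lambda_gxtc=genomic_inflation(results["p_gxt"].to_numpy()),
        n_snps_tested=len(results),
        threshold=threshold,
        n_hits=n_hits,
    )
    return results, summary


# ---------------------------------------------------------------------------
# Calibration and replication summaries
# ---------------------------------------------------------------------------

def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor: median chi2(1) quantile over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2_obs = stats.chi2.isf(p, 1)
    return float(np.median(chi2_obs) / CHI2_1_MEDIAN)


def replication_test(n_total: int, n_replicated: int, alpha: float = 0.05):
    """Exact one-sided binomial test of a replication count against rate alpha.

    Returns ``(n_total, n_replicated, fraction, binomial_p)`` where
    ``binomial_p`` is P(X >= n_replicated) for X ~ Binomial(n_total, alpha).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_replicated <= n_total:
        raise ValueError("n_replicated must lie in [0, n_total]")
    res = stats.binomtest(n_replicated, n_total, alpha, alternative="greater")
    return n_total, n_replicated, n_replicated / n_total, float(res.pvalue)


def replication_rate(results_a, results_b, alpha: float = 0.05,
                     key="snp_id", p_col="p_gxt"):
    """Fraction of cohort-A associations replicating (p < alpha) in cohort B.

    ``results_a`` holds the cohort-A significant associations; ``results_b``
    the full cohort-B scan.  Associations are matched on ``key`` (a column
    name or list of column names) and a cohort-A association counts as
    replicated when its cohort-B ``p_col`` is below ``alpha``.  Significance
    of the replication fraction comes from the exact one-sided binomial test
    against a null replication rate of alpha.
    """
    keys = [key] if isinstance(key, str) else list(key)
    merged = pd.merge(
        results_a[keys], results_b[keys + [p_col]], on=keys, how="inner"
    )
    n_total = len(merged)
    if n_total == 0:
        raise ValueError("no associations match between cohorts")
    n_replicated = int((merged[p_col] < alpha).sum())
    return replication_test(n_total, n_replicated, alpha)
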