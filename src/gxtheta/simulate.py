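"""Phenotype simulation, power curves, and the composite-SNP epistasis experiment.

Four phenotype generators are supported, combining one fixed effect with a
multivariate-normal polygenic background:

    main-1k   y = beta * x              + MVN(0, sg2 K + se2 I)
    main-2k   y = beta * x              + MVN(0, sg2 K + st2 K_A + se2 I)
    int-1k    y = beta_gxt * theta * x  + MVN(0, sg2 K + se2 I)
    int-2k    y = beta_gxt * theta * x  + MVN(0, sg2 K + st2 K_A + se2 I)

Default variance fractions: sg2 = 0.4, st2 = 0.2 when the ancestry GRM is
included, and se2 the remainder so the background variance sums to 1.
Phenotypes are standardized to unit variance before testing (the LRT is
invariant to affine rescaling, so this only fixes the scale of reported
effects).

Higher-order epistasis is emulated with a *composite SNP*: the minor
(non-reference-founder) allele is assigned only to individuals carrying the
minor allele at the test SNP and at every interacting partner SNP.  Its
effect size is calibrated so the 1-df association test of the composite has
a chosen non-centrality (default 20), giving a consistent, observable
signal regardless of how many partners participate; the original test SNP
is then scanned for main and interaction effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gxtheta.data_model import AncestryVector, GenotypeMatrix, KinshipMatrix, filter_maf
from gxtheta.mixedmodel import LMMSolver, genomic_inflation, gxtheta_test, _with_intercept

__all__ = [
    "SimulationConfig",
    "simulate_phenotype",
    "mvn_factor",
    "power_curve",
    "composite_snp",
    "calibrate_beta_to_chisq",
    "epistasis_experiment",
]

MODELS = ("main-1k", "main-2k", "int-1k", "int-2k")


@dataclass
class SimulationConfig:
    """Grid and variance settings for a power-curve run.

    The defaults are the desk-scale grid (20 points x 200 replicates); the
    full-scale experiment (200 points 0.005 apart x 1,000 replicates) is
    obtained with ``grid=np.linspace(0, 1, 200)`` and ``n_reps=1000``.
    """

    model: str = "int-1k"
    grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 20))
    n_reps: int = 200
    sigma_g2: float = 0.4
    sigma_theta2: float = 0.2
    sigma_e2: float | None = None
    alpha: float = 0.05
    maf_window: tuple = (0.25, 0.5)
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.size == 0:
            raise ValueError("effect-size grid must be non-empty")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        st2 = self.sigma_theta2 if self.two_grm else 0.0
        if self.sigma_e2 is None:
            self.sigma_e2 = 1.0 - self.sigma_g2 - st2
        total = self.sigma_g2 + st2 + self.sigma_e2
        if min(self.sigma_g2, st2, self.sigma_e2) < 0 or abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"variance fractions must be non-negative and sum to 1 (got {total})"
            )

    @property
    def two_grm(self) -> bool:
        return self.model.endswith("2k")

    @property
    def vary(self) -> str:
        return "beta" if self.model.startswith("main") else "beta_gxt"


def mvn_factor(K=None, K_A=None, sigma_g2=0.4, sigma_theta2=0.0, sigma_e2=0.6,
               n=None) -> np.ndarray | None:
    """Cholesky factor L of sg2 K + st2 K_A + se2 I (None for zero covariance)."""
    def vals(M):
        return M.values if isinstance(M, KinshipMatrix) else np.asarray(M, float)

    if K is not None:
        n = vals(K).shape[0]
    if n is None:
        raise ValueError("need K or n to size the covariance")
    V = sigma_e2 * np.eye(n)
    if sigma_g2:
        if K is None:
            raise ValueError("sigma_g2 > 0 requires K")
        V = V + sigma_g2 * vals(K)
    if sigma_theta2:
        if K_A is None:
            raise ValueError("sigma_theta2 > 0 requires K_A")
        V = V + sigma_theta2 * vals(K_A)
    if not V.any():
        return None
    try:
        return np.linalg.cholesky(V + 1e-12 * np.eye(n))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"assembled covariance is not PSD: {e}") from None


def simulate_phenotype(x, theta, beta=0.0, beta_gxt=0.0, K=None, K_A=None,
                       sigma_g2=0.4, sigma_theta2=0.0, sigma_e2=0.6,
                       rng=None, factor=None) -> np.ndarray:
    """One draw of y = beta x + beta_gxt (theta * x) + MVN(0, sg2 K + st2 K_A + se2 I).

    ``factor`` accepts a precomputed Cholesky factor from :func:`mvn_factor`
    so simulation loops pay the decomposition only once.  Seed via ``rng``
    (a numpy Generator); draws are reproducible for a fixed generator state.
    """
    x = np.asarray(x, float)
    th = theta.theta if isinstance(theta, AncestryVector) else np.asarray(theta, float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    y = beta * x + beta_gxt * th * x
    if factor is None:
        factor = mvn_factor(K, K_A, sigma_g2, sigma_theta2, sigma_e2, n=x.shape[0])
    if factor is not None:
        y = y + factor @ rng.standard_normal(x.shape[0])
    return y


def _standardize(y):
    sd = y.std()
    return (y - y.mean()) / sd if sd > 0 else y - y.mean()


def _eligible_snps(G: GenotypeMatrix, maf_window) -> np.ndarray:
    """Indices of SNPs inside the MAF window (open interval on the MAF scale)."""
    lo, hi = maf_window
    kept = filter_maf(G, lo, hi)
    ids = set(kept.snps["snp_id"])
    return np.flatnonzero(G.snps["snp_id"].isin(ids).to_numpy())


def power_curve(G: GenotypeMatrix, theta, K, K_A=None,
                config: SimulationConfig | None = None,
                analyze_two_grm: bool | None = None) -> pd.DataFrame:
    """Rejection rates of the main-effect and interaction tests along an effect grid.

    At every grid point, each replicate draws a random SNP from the MAF
    window, simulates a phenotype under ``config.model``, and runs the
    Gxtheta test; powers are the rejection fractions at ``config.alpha``
    with Monte-Carlo standard errors sqrt(p(1-p)/n_reps).

    ``analyze_two_grm`` controls whether the *analysis* fits one or two
    variance components (default: match the generating model), so the same
    phenotypes can be scored under both analysis modes.
    """
    config = config or SimulationConfig()
    if config.two_grm and K_A is None:
        raise ValueError(f"model {config.model} requires K_A")
    if analyze_two_grm is None:
        analyze_two_grm = config.two_grm
    th = theta.theta if isinstance(theta, AncestryVector) else np.asarray(theta, float)
    rng = np.random.default_rng(config.seed)
    eligible = _eligible_snps(G, config.maf_window)
    if eligible.size == 0:
        raise ValueError("no SNPs inside the MAF window")

    st2 = config.sigma_theta2 if config.two_grm else 0.0
    L = mvn_factor(K, K_A, config.sigma_g2, st2, config.sigma_e2)
    solver = LMMSolver(K, K_A if analyze_two_grm else None)

    rows = []
    for effect in config.grid:
        beta = effect if config.vary == "beta" else 0.0
        bgxt = effect if config.vary == "beta_gxt" else 0.0
        hit_g = hit_gxt = 0
        for _ in range(config.n_reps):
            j = eligible[rng.integers(eligible.size)]
            x = G.dosages[:, j]
            y = _standardize(
                simulate_phenotype(x, th, beta=beta, beta_gxt=bgxt, rng=rng, factor=L)
            )
            r = gxtheta_test(y, x, th, solver=solver)
            hit_g += r.p_g < config.alpha
            hit_gxt += r.p_gxt < config.alpha
        pm, pi = hit_g / config.n_reps, hit_gxt / config.n_reps
        rows.append(
            (effect, pm, pi,
             np.sqrt(pm * (1 - pm) / config.n_reps),
             np.sqrt(pi * (1 - pi) / config.n_reps))
        )
    return pd.DataFrame(
        rows, columns=["effect", "power_main", "power_gxt", "se_main", "se_gxt"]
    )


# ---------------------------------------------------------------------------
# Composite-SNP epistasis
# ---------------------------------------------------------------------------

def composite_snp(snps) -> np.ndarray:
    """Composite dosage vector carrying the minor allele only where every input does.

    Inputs must be inbred dosages in {0, 1}; the minor allele is the
    non-reference-founder allele (dosage 0), so the composite is 0 exactly
    where all inputs are 0 and 1 elsewhere.  A single input returns itself.
    The caller should check the result for monomorphism (and redraw).
    """
    X = np.atleast_2d(np.asarray(list(snps), dtype=float))
    if X.size == 0:
        raise ValueError("need at least one SNP")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("composite SNPs require inbred {0, 1} dosages")
    return np.where((X == 0.0).all(axis=0), 0.0, 1.0)


def calibrate_beta_to_chisq(x, K=None, C=None, sigma_g2=0.4, sigma_e2=0.6,
                            target_chi2=20.0) -> float:
    """Effect size whose 1-df GLS association test has non-centrality target_chi2.

    Under V = sg2 K + se2 I, the association chi-square of regressor x
    (residualized against the covariates C, default an intercept) at effect
    beta has non-centrality beta^2 * x^T P x with
    P = V^-1 - V^-1 C (C^T V^-1 C)^-1 C^T V^-1; this returns
    beta = sqrt(target_chi2 / (x^T P x)).
    """
    if target_chi2 < 0:
        raise ValueError("target_chi2 must be >= 0")
    x = np.asarray(x, float)
    n = x.shape[0]
    Kv = np.eye(n) if K is None else (K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float))
    V = sigma_g2 * Kv + sigma_e2 * np.eye(n)
    C = _with_intercept(None if C is None else np.asarray(C, float), n)
    Vi_x = np.linalg.solve(V, x)
    Vi_C = np.linalg.solve(V, C)
    quad = float(x @ Vi_x - (C.T @ Vi_x) @ np.linalg.solve(C.T @ Vi_C, C.T @ Vi_x))
    if quad <= 1e-12:
        raise ValueError("regressor has no variance after residualization; target unreachable")
    return float(np.sqrt(target_chi2 / quad))


def epistasis_experiment(G: GenotypeMatrix, theta, K, n_partners_grid=range(1, 11),
                         n_reps=500, target_chi2=20.0, alpha=0.05,
                         sigma_g2=0.4, sigma_e2=0.6, maf_window=(0.25, 0.5),
                         seed=0, redraw_budget=200) -> pd.DataFrame:
    """Detection of a test SNP engaged in higher-order epistasis.

    For each number of interacting partners, every replicate draws a test
    SNP plus that many partner SNPs from the MAF window, forms the
    composite SNP (redrawing when monomorphic, within ``redraw_budget``
    attempts), calibrates its effect to non-centrality ``target_chi2``
    under sg2 K + se2 I, simulates the phenotype, and scores the *original*
    test SNP.  Returns per grid point the main-effect and interaction
    detection rates at ``alpha`` plus genomic-inflation diagnostics of the
    two p-value sets.
    """
    th = theta.theta if isinstance(theta, AncestryVector) else np.asarray(theta, float)
    rng = np.random.default_rng(seed)
    eligible = _eligible_snps(G, maf_window)
    if eligible.size < max(n_partners_grid) + 1:
        raise ValueError("not enough SNPs in the MAF window for the partner grid")
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    solver = LMMSolver(Kv)
    L = mvn_factor(Kv, sigma_g2=sigma_g2, sigma_e2=sigma_e2)

    rows = []
    for n_partners in n_partners_grid:
        p_main, p_gxt = [], []
        for _ in range(n_reps):
            comp = x_test = None
            for _attempt in range(redraw_budget):
                pick = rng.choice(eligible, size=n_partners + 1, replace=False)
                X = G.dosages[:, pick]
                c = composite_snp(X.T)
                if np.ptp(c) > 0:
                    comp, x_test = c, X[:, 0]
                    break
            if comp is None:
                raise RuntimeError(
                    f"no polymorphic composite within {redraw_budget} redraws "
                    f"at {n_partners} partners"
                )
            beta = calibrate_beta_to_chisq(
                comp, K=Kv, sigma_g2=sigma_g2, sigma_e2=sigma_e2, target_chi2=target_chi2
            )
            y = _standardize(
                simulate_phenotype(comp, th, beta=beta, rng=rng, factor=L)
            )
            r = gxtheta_test(y, x_test, th, solver=solver)
            p_main.append(r.p_g)
            p_gxt.append(r.p_gxt)
        p_main, p_gxt = np.array(p_main), np.array(p_gxt)
        rows.append(
            (n_partners,
             float((p_main < alpha).mean()), float((p_gxt < alpha).mean()),
             genomic_inflation(p_main), genomic_inflation(p_gxt))
        )
    out = pd.DataFrame(
        rows, columns=["n_partners", "power_main", "power_gxt", "lambda_main", "lambda_gxt"]
    )
    out["se"] = np.sqrt(0.25 / n_reps)  # worst-case Monte-Carlo SE at the given n_reps
    return out
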