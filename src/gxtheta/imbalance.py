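"""Transmission-ratio-distortion (allelic imbalance) scan for admixed panels.

In a balanced biparental panel, each founder should contribute ~50% of the
alleles at every locus.  Loci where the founder-ancestry frequency theta_i
deviates from the panel mean are candidates for selection during panel
derivation (fitness epistasis, meiotic drive) rather than drift.  The test
is a Wald statistic per site,

    W_i = (theta_bar - theta_i)^2 / var(theta),

with the *global* variance of the per-site frequencies in the denominator —
this assumes most sites are null and is conservative when that assumption
is violated.  W_i is referred to chi-square(1), sites are declared
significant by Benjamini-Hochberg at 5% FDR, and runs of nearby significant
sites are chained into distortion regions.

The expected background is Bernoulli: with n independent lines, the exact
two-sided binomial tail gives the chance that a site reaches a given
imbalance under neutrality (e.g. an 80/20 split across 122 lines has
probability ~8e-12, so even genome-wide such sites are not expected by
chance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ImbalanceRecord",
    "DistortionRegion",
    "wald_scan",
    "bh_correct",
    "cluster_regions",
    "binomial_imbalance_probability",
    "expected_distorted_snps",
]


@dataclass
class ImbalanceRecord:
    snp_id: str
    chrom: str
    bp: int
    theta_i: float
    W: float
    p: float
    q: float = np.nan
    significant: bool = False


@dataclass
class DistortionRegion:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    mean_ancestry_pct: float
    mean_significance: float

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("region start must not exceed end")


def wald_scan(theta_sites, snps: pd.DataFrame | None = None,
              theta_bar: float | None = None,
              var_theta: float | None = None) -> pd.DataFrame:
    """Per-site Wald test of founder-ancestry frequency against the panel mean.

    ``theta_sites`` are per-site frequencies in [0, 1] (NaN = site excluded,
    e.g. no eligible individuals).  ``theta_bar`` and ``var_theta`` default
    to the mean and variance across all (finite) sites.  Returns a
    DataFrame with columns ``snp_id chrom bp theta_i W p`` aligned with the
    input; use :func:`bh_correct` on ``p`` for significance calls.
    """
    t = np.asarray(theta_sites, dtype=float)
    finite = np.isfinite(t)
    if not finite.any():
        raise ValueError("no finite per-site frequencies")
    tf = t[finite]
    if np.any((tf < 0) | (tf > 1)):
        raise ValueError("per-site frequencies must lie in [0, 1]")
    if theta_bar is None:
        theta_bar = float(tf.mean())
    if var_theta is None:
        var_theta = float(tf.var())
    if var_theta <= 0:
        raise ValueError("global variance of theta must be positive")
    W = (theta_bar - t) ** 2 / var_theta
    p = stats.chi2.sf(W, 1)
    if snps is None:
        snps = pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(len(t))],
             "chrom": "0", "bp": np.arange(1, len(t) + 1)}
        )
    out = snps.reset_index(drop=True).copy()
    out["theta_i"] = t
    out["W"] = W
    out["p"] = p
    return out[finite].reset_index(drop=True)


def bh_correct(pvalues, q_target: float = 0.05):
    """Benjamini-Hochberg step-up q-values and the significance mask at q_target."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any(~np.isfinite(p)) or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    sig, q, *_ = multipletests(p, alpha=q_target, method="fdr_bh")
    return q, sig


def cluster_regions(records: pd.DataFrame, min_cluster: int = 5,
                    max_gap_bp: int = 2_000_000) -> list[DistortionRegion]:
    """Chain significant sites into distortion regions.

    ``records`` must hold the *significant* sites (columns ``chrom bp
    theta_i p``).  Sites on the same chromosome are chained greedily while
    the inter-site gap is at most ``max_gap_bp`` (single linkage); chains
    with at least ``min_cluster`` members are emitted with their mean
    founder ancestry (percent) and mean p-value.
    """
    regions: list[DistortionRegion] = []
    if len(records) == 0:
        return regions
    df = records.sort_values(["chrom", "bp"], kind="stable")
    for chrom, sub in df.groupby("chrom", sort=False):
        bp = sub["bp"].to_numpy()
        breaks = np.flatnonzero(np.diff(bp) > max_gap_bp)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [len(bp)]))
        for s, e in zip(starts, ends):
            if e - s < min_cluster:
                continue
            chunk = sub.iloc[s:e]
            regions.append(
                DistortionRegion(
                    chrom=str(chrom),
                    start_bp=int(chunk["bp"].iloc[0]),
                    end_bp=int(chunk["bp"].iloc[-1]),
                    n_snps=int(e - s),
                    mean_ancestry_pct=float(chunk["theta_i"].mean() * 100.0),
                    mean_significance=float(chunk["p"].mean()),
                )
            )
    return regions


def binomial_imbalance_probability(n_lines: int, fraction: float, p0: float = 0.5,
                                   two_sided: bool = True) -> float:
    """Exact binomial tail probability of an allelic imbalance this extreme.

    For X ~ Binomial(n_lines, p0), returns
    P(X >= ceil(fraction * n)) + P(X <= floor((1 - fraction) * n))
    (the one-sided upper tail alone with ``two_sided=False``), summed
    exactly in log space.  ``fraction`` must exceed 0.5: it is the majority
    founder's share, e.g. 0.8 for an 80/20 split.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if not 0.5 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0.5, 1]")
    n = int(n_lines)
    k = np.arange(n + 1)
    logpmf = stats.binom.logpmf(k, n, p0)
    # epsilon guards against float artifacts like (1 - 0.8) * 10 = 1.9999...
    k_hi = int(np.ceil(fraction * n - 1e-9))
    k_lo = int(np.floor((1.0 - fraction) * n + 1e-9))
    terms = [logpmf[k_hi:]] if k_hi <= n else []
    if two_sided and k_lo >= 0:
        terms.append(logpmf[: k_lo + 1])
    if not terms:
        return 0.0
    return float(np.exp(logsumexp(np.concatenate(terms))))


def expected_distorted_snps(n_snps: int, per_snp_probability: float) -> float:
    """Expected count of distorted sites under independence: n * p.

    Genome-wide sites are linked, so this overstates the effective number
    of independent trials; it is an upper-bound style expectation.
    """
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    return float(n_snps) * float(per_snp_probability)
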