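"""Ancestry calling from a biparental cross.

Ancestry-informative sites are the SNPs at which the two parental lines
carry different homozygous genotypes.  Global ancestry theta for an
individual is the unweighted mean, over informative sites, of the dosage of
the designated reference founder's allele — i.e. the fraction of informative
SNPs inherited from that founder.  Heterozygous cells contribute 0.5, so the
definition covers both inbred panels and segregating intercross populations.

The per-site analogue, the founder-ancestry frequency theta_i, averages over
individuals instead of sites and feeds the allelic-imbalance scan in
:mod:`gxtheta.imbalance`.  A site only enters an individual's cross-level
frequency when that individual's cross actually segregates the site
("cross eligibility"): in multi-subpanel designs different crosses share a
common founder but differ in the other parent, so a SNP may be informative
in one cross and monomorphic in another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gxtheta.data_model import AncestryVector, GenotypeMatrix

__all__ = [
    "InformativeSiteSet",
    "informative_sites",
    "compute_theta",
    "site_ancestry_frequency",
]


@dataclass
class InformativeSiteSet:
    """Indices of ancestry-informative SNPs plus founder orientation.

    ``ref_is_parent_a`` records which input parent is the designated
    reference founder; ``ref_dosage`` holds, per informative site, the
    dosage value carried by that founder (1.0 when the genotype matrix is
    already oriented to the reference founder, 0.0 when flipped).
    """

    indices: np.ndarray
    ref_dosage: np.ndarray
    ref_is_parent_a: bool = True

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.ref_dosage = np.asarray(self.ref_dosage, dtype=float)
        if self.indices.shape != self.ref_dosage.shape:
            raise ValueError("indices and ref_dosage must have the same length")

    def __len__(self) -> int:
        return len(self.indices)


def informative_sites(parent_a, parent_b, ref_parent: str = "A") -> InformativeSiteSet:
    """Call ancestry-informative sites from two parental genotype rows.

    Both parents must be homozygous at a site for it to be considered;
    heterozygous or missing parental calls are skipped.  The returned set
    contains exactly the sites where the two parental dosages differ.

    Parameters
    ----------
    parent_a, parent_b : array-like
        Parental dosage rows on the [0, 1] scale.
    ref_parent : {"A", "B"}
        Which parent is the designated reference founder; theta is the
        genome fraction inherited from this line.
    """
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parental rows must have equal length")
    if ref_parent not in ("A", "B"):
        raise ValueError("ref_parent must be 'A' or 'B'")
    homo = (
        np.isfinite(a) & np.isfinite(b) & np.isin(a, (0.0, 1.0)) & np.isin(b, (0.0, 1.0))
    )
    differ = homo & (a != b)
    idx = np.flatnonzero(differ)
    ref_dosage = (a if ref_parent == "A" else b)[idx]
    return InformativeSiteSet(idx, ref_dosage, ref_is_parent_a=(ref_parent == "A"))


def _oriented_dosages(G: GenotypeMatrix, sites: InformativeSiteSet) -> np.ndarray:
    """Reference-founder dosages at the informative sites (NaN preserved)."""
    D = G.dosages[:, sites.indices]
    # where the reference founder carries the alternate (0) allele, flip
    flip = sites.ref_dosage == 0.0
    D = np.where(flip, 1.0 - D, D)
    return D


def compute_theta(G: GenotypeMatrix, sites: InformativeSiteSet) -> AncestryVector:
    """Global ancestry proportion per individual.

    theta_k is the mean reference-founder dosage over informative sites,
    skipping cells missing for individual k.  Errors if any individual has
    zero observed informative sites.
    """
    if len(sites) == 0:
        raise ValueError("no ancestry-informative sites")
    D = _oriented_dosages(G, sites)
    obs = np.isfinite(D)
    n_obs = obs.sum(axis=1)
    if (n_obs == 0).any():
        k = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(
            f"individual {G.sample_ids[k]!r} has no observed informative sites"
        )
    theta = np.nansum(np.where(obs, D, 0.0), axis=1) / n_obs
    return AncestryVector(G.sample_ids, theta, n_obs)


def site_ancestry_frequency(
    G: GenotypeMatrix,
    sites: InformativeSiteSet,
    panel_membership=None,
    informative_crosses: dict | None = None,
) -> np.ndarray:
    """Per-site founder-ancestry frequency theta_i.

    theta_i is the mean reference-founder dosage at site i over the
    individuals whose cross segregates the site.  In a single biparental
    panel every individual is eligible at every informative site; in a
    multi-subpanel design, pass ``panel_membership`` (a cross label per
    individual) and ``informative_crosses`` (site index -> set of cross
    labels in which the site is informative).

    Returns an array aligned with ``sites.indices``; sites with zero
    eligible individuals come back NaN so callers can exclude them.
    """
    D = _oriented_dosages(G, sites)
    if panel_membership is None:
        eligible = np.ones(D.shape, dtype=bool)
    else:
        membership = np.asarray(panel_membership)
        if membership.shape != (G.n_samples,):
            raise ValueError("panel_membership must give one cross label per individual")
        if informative_crosses is None:
            raise ValueError("informative_crosses required with panel_membership")
        eligible = np.zeros(D.shape, dtype=bool)
        for j, snp_idx in enumerate(sites.indices):
            crosses = informative_crosses.get(int(snp_idx), ())
            eligible[:, j] = np.isin(membership, list(crosses))
    use = eligible & np.isfinite(D)
    n = use.sum(axis=0)
    with np.errstate(invalid="ignore"):
        theta_i = np.where(n > 0, np.nansum(np.where(use, D, 0.0), axis=0) / np.maximum(n, 1), np.nan)
    return theta_i
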