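"""Core containers and file IO shared by every analysis module.

Dosages are coded on the [0, 1] scale as the fraction of alleles inherited
from the designated *reference founder* (homozygous reference = 1,
heterozygous = 0.5, homozygous alternate = 0).  This keeps genotype dosages
commensurable with the ancestry proportion theta, which lives on the same
scale: fully inbred panels occupy {0, 1} and intercross panels {0, 0.5, 1}.
Missing genotypes are NaN.

Coordinates are 1-based; chromosome labels are opaque strings.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "AncestryVector",
    "KinshipMatrix",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "filter_maf",
    "mean_impute",
]

#: values a dosage cell may take after ingest (besides NaN)
VALID_DOSAGES = (0.0, 0.5, 1.0)


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be decoded."""


@dataclass
class GenotypeMatrix:
    """Individuals-by-SNPs dosage matrix with SNP coordinates.

    Parameters
    ----------
    sample_ids : list of str
        Unique identifiers, one per row of ``dosages``.
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id``, ``chrom``, ``bp``
        (integer, 1-based).
    dosages : numpy.ndarray, shape (n_samples, n_snps)
        Reference-founder allele dosage in {0, 0.5, 1}; NaN = missing.
    """

    sample_ids: list
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n} dosage rows"
            )
        if len(self.snps) != m:
            raise ValueError(f"{len(self.snps)} SNP records but {m} dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        self.snps = self.snps.reset_index(drop=True)
        if (self.snps["bp"] < 0).any():
            raise ValueError("basepair positions must be non-negative")
        obs = self.dosages[np.isfinite(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 1):
            raise ValueError("dosages must lie in [0, 1] (or NaN)")

    def validate_dosage_grid(self) -> "GenotypeMatrix":
        """Assert every observed dosage is exactly 0, 0.5 or 1 (ingest invariant)."""
        obs = self.dosages[np.isfinite(self.dosages)]
        bad = obs[~np.isin(obs, VALID_DOSAGES)]
        if bad.size:
            raise ValueError(
                f"dosage values must be in {{0, 0.5, 1}} or NaN; found {bad[:5]}"
            )
        return self

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def sort_by_position(self) -> "GenotypeMatrix":
        """Return a copy with SNPs sorted by (chrom, bp)."""
        order = self.snps.sort_values(["chrom", "bp"], kind="stable").index.to_numpy()
        return GenotypeMatrix(
            self.sample_ids, self.snps.iloc[order], self.dosages[:, order]
        )

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.sample_ids, self.snps.iloc[idx], self.dosages[:, idx])

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], self.snps, self.dosages[idx, :]
        )


@dataclass
class PhenotypeTable:
    """Trait values (and optional covariates) for a set of samples."""

    sample_ids: list
    traits: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        if len(self.traits) != len(self.sample_ids):
            raise ValueError("trait rows must match sample ids")
        if self.covariates is not None and len(self.covariates) != len(self.sample_ids):
            raise ValueError("covariate rows must match sample ids")

    def trait(self, name: str) -> np.ndarray:
        y = self.traits[name].to_numpy(dtype=float)
        if np.sum(np.isfinite(y)) < 3:
            raise ValueError(f"trait {name!r} has fewer than 3 non-missing values")
        return y

    def align_to(self, sample_ids) -> "PhenotypeTable":
        """Reorder/subset to ``sample_ids`` (explicit join; missing ids error)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} missing from phenotype table")
        cov = self.covariates.iloc[rows].reset_index(drop=True) if self.covariates is not None else None
        return PhenotypeTable(list(sample_ids), self.traits.iloc[rows].reset_index(drop=True), cov)


@dataclass
class AncestryVector:
    """Per-individual global ancestry proportion from the reference founder."""

    sample_ids: list
    theta: np.ndarray
    n_informative_sites: np.ndarray = field(default=None)

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (len(self.sample_ids),):
            raise ValueError("theta length must equal number of samples")
        if np.any((self.theta < 0) | (self.theta > 1)):
            raise ValueError("theta must lie in [0, 1]")
        if self.n_informative_sites is None:
            self.n_informative_sites = np.zeros(len(self.sample_ids), dtype=int)
        else:
            self.n_informative_sites = np.asarray(self.n_informative_sites, dtype=int)


@dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix over a set of samples.

    ``label`` distinguishes the genome-wide GRM ("K") from the
    ancestry-informative GRM ("K_A") used in two-variance-component models.
    """

    sample_ids: list
    values: np.ndarray
    label: str = "K"

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix must be n x n")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric (atol 1e-10)")
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -1e-8:
            raise ValueError(f"kinship matrix not PSD (min eigenvalue {w.min():.3g})")

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _decode_allele_pair(cell: str, ref_allele: str, line_no: int) -> float:
    alleles = cell.replace("|", "/").split("/")
    if len(alleles) == 1:  # haploid call, e.g. "A"
        alleles = alleles * 2
    if len(alleles) != 2:
        raise GenotypeParseError(
            f"line {line_no}: cannot parse allele code {cell!r}"
        )
    codes = set(alleles)
    known = codes <= {ref_allele} or len(codes - {ref_allele}) <= 1
    if not known:
        raise GenotypeParseError(
            f"line {line_no}: allele code {cell!r} has more than one non-reference allele"
        )
    return sum(a == ref_allele for a in alleles) / 2.0


def read_genotypes(path, format: str = "tsv", ref_parent_allele: str | None = None,
                   missing_codes=("NA", "nan", ".", "")) -> GenotypeMatrix:
    """Read a genotype TSV into a :class:`GenotypeMatrix`.

    Layout: header ``snp_id  chrom  bp  <sample1> ... <sampleN>``, one row
    per SNP.  Cells are either numeric dosages in {0, 0.5, 1, NA} or
    allele-pair codes such as ``A/A`` recoded against ``ref_parent_allele``.

    Lines starting with ``#`` are treated as provenance comments.
    """
    if format != "tsv":
        raise NotImplementedError(f"unsupported genotype format {format!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise GenotypeParseError(f"{path}: empty genotype file")
    header = lines[0].split("\t")
    if len(header) < 4:
        raise GenotypeParseError(f"{path}: header must have snp_id, chrom, bp + samples")
    sample_ids = header[3:]
    n_cols = len(header)

    snp_rows, dosage_cols = [], []
    for line_no, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_cols:
            raise GenotypeParseError(
                f"{path}: line {line_no} has {len(parts)} fields, expected {n_cols}"
            )
        snp_rows.append((parts[0], parts[1], int(parts[2])))
        row = np.empty(len(sample_ids))
        for j, cell in enumerate(parts[3:]):
            cell = cell.strip()
            if cell in missing_codes:
                row[j] = np.nan
            else:
                try:
                    row[j] = float(cell)
                except ValueError:
                    if ref_parent_allele is None:
                        raise GenotypeParseError(
                            f"{path}: line {line_no}: non-numeric cell {cell!r} "
                            "but no reference-parent allele given"
                        )
                    row[j] = _decode_allele_pair(cell, ref_parent_allele, line_no)
        dosage_cols.append(row)

    snps = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "bp"])
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids, snps, dosages).validate_dosage_grid()


def write_genotypes(G: GenotypeMatrix, path, header_comment: str | None = None) -> None:
    """Write ``G`` as the genotype TSV accepted by :func:`read_genotypes`."""
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    buf.write("snp_id\tchrom\tbp\t" + "\t".join(map(str, G.sample_ids)) + "\n")
    for i in range(G.n_snps):
        rec = G.snps.iloc[i]
        cells = [
            "NA" if not np.isfinite(d) else ("%g" % d) for d in G.dosages[:, i]
        ]
        buf.write(f"{rec.snp_id}\t{rec.chrom}\t{rec.bp}\t" + "\t".join(cells) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_phenotypes(path, covariate_path=None) -> PhenotypeTable:
    """Read a phenotype TSV (``sample_id`` column + one column per trait)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    traits = df.iloc[:, 1:].astype(float)
    cov = None
    if covariate_path is not None:
        cdf = pd.read_csv(covariate_path, sep="\t", comment="#")
        cdf = cdf.set_index(cdf.columns[0]).loc[sample_ids].reset_index(drop=True)
        cov = cdf.astype(float)
    return PhenotypeTable(sample_ids, traits, cov)


# ---------------------------------------------------------------------------
# Filtering / imputation
# ---------------------------------------------------------------------------

def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Per-SNP reference-founder allele frequency over observed cells."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return np.nanmean(G.dosages, axis=0)


def filter_maf(G: GenotypeMatrix, maf_min: float = 0.05, maf_max: float = 0.5) -> GenotypeMatrix:
    """Retain SNPs with minor-allele frequency in the open window (maf_min, maf_max].

    The reference-allele frequency f is the mean observed dosage; MAF is
    min(f, 1-f).  ``maf_max=0.5`` (the ceiling of a MAF) imposes no upper
    cut.  A window such as "frequency between 25% and 75%" is
    ``filter_maf(G, 0.25)``.
    """
    if not (0 <= maf_min <= maf_max <= 0.5):
        raise ValueError("require 0 <= maf_min <= maf_max <= 0.5")
    f = allele_frequencies(G)
    maf = np.minimum(f, 1.0 - f)
    keep = np.isfinite(maf) & (maf > maf_min)
    if maf_max < 0.5:
        keep &= maf < maf_max
    if not keep.any():
        warnings.warn("MAF filter removed every SNP", UserWarning)
    return G.take_snps(np.flatnonzero(keep))


def mean_impute(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-SNP mean of observed dosages.

    The result may contain off-grid dosage values, so it is returned as a
    plain (sample_ids, snps, dosages) matrix without the {0, 0.5, 1}
    validation; downstream association code accepts real-valued dosages.
    """
    D = G.dosages.copy()
    miss = ~np.isfinite(D)
    if not miss.any():
        return G
    n_obs = (~miss).sum(axis=0)
    empty = np.flatnonzero(n_obs == 0)
    if empty.size:
        raise ValueError(
            f"SNP {G.snps['snp_id'].iloc[empty[0]]!r} has no observed genotypes"
        )
    col_means = np.nansum(np.where(miss, 0.0, D), axis=0) / n_obs
    D[miss] = np.broadcast_to(col_means, D.shape)[miss]
    return GenotypeMatrix(list(G.sample_ids), G.snps, D)
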