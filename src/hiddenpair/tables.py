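"""Genotype containers and 3x3x2 genotype-genotype-phenotype contingency tables.

Genotypes are coded as minor-allele counts {0, 1, 2} (0 = major homozygote,
1 = heterozygote, 2 = minor homozygote); phenotype is binary (0 = control,
1 = case).  Missing values use the sentinel ``MISSING`` (-1).  For a SNP pair
(X_p, X_q) and phenotype Y the central object is the 3x3x2 table of cell
counts n_ijk with i the genotype of X_p, j the genotype of X_q and k the
phenotype stratum (k=0 controls, k=1 cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1

__all__ = [
    "MISSING",
    "InvalidInputError",
    "InvalidReferenceError",
    "GenotypeMatrix",
    "PairTable",
    "Margins",
    "as_genotype_vector",
    "as_phenotype_vector",
    "build_pair_table",
    "margins",
    "genotype_combination_odds_ratios",
]


class InvalidInputError(ValueError):
    """Raised when inputs cannot form a valid case-control table."""


class InvalidReferenceError(ValueError):
    """Raised when an odds-ratio reference cell is empty in either stratum."""


def as_genotype_vector(g) -> np.ndarray:
    """Coerce to an int8 vector of minor-allele counts; NaN becomes MISSING."""
    a = np.asarray(g)
    if a.dtype.kind == "f":
        out = np.where(np.isnan(a), MISSING, a)
        if not np.all((out == MISSING) | (out == np.round(out))):
            raise InvalidInputError("non-integer genotype values")
        a = out
    a = a.astype(np.int8, copy=False)
    if not np.all((a == MISSING) | ((a >= 0) & (a <= 2))):
        raise InvalidInputError("genotype entries must be in {0,1,2} or missing")
    return a


def as_phenotype_vector(y) -> np.ndarray:
    """Coerce to an int8 vector of {0 control, 1 case}; NaN becomes MISSING."""
    a = np.asarray(y)
    if a.dtype.kind == "f":
        a = np.where(np.isnan(a), MISSING, a)
    a = a.astype(np.int8, copy=False)
    if not np.all((a == MISSING) | (a == 0) | (a == 1)):
        raise InvalidInputError("phenotype entries must be 0, 1 or missing")
    return a


@dataclass
class GenotypeMatrix:
    """n samples x L SNPs of minor-allele counts, with per-SNP metadata.

    Parameters
    ----------
    values
        Integer matrix (n, L) with entries in {0, 1, 2} or ``MISSING``.
    snp_ids
        Unique SNP identifiers, length L.
    chrom
        Chromosome label per SNP, length L.
    pos
        Base-pair position per SNP (non-negative integers), length L.
    """

    values: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.int8))
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, L = self.values.shape
        for name, arr in (("snp_ids", self.snp_ids), ("chrom", self.chrom), ("pos", self.pos)):
            if arr.shape != (L,):
                raise InvalidInputError(f"{name} must have length {L}, got {arr.shape}")
        ok = (self.values == MISSING) | ((self.values >= 0) & (self.values <= 2))
        if not ok.all():
            raise InvalidInputError("genotype entries must be in {0,1,2} or missing")
        if len(set(self.snp_ids)) != L:
            raise InvalidInputError("snp_ids must be unique")
        if (self.pos < 0).any():
            raise InvalidInputError("positions must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def column(self, index: int) -> np.ndarray:
        return self.values[:, index]


@dataclass
class PairTable:
    """3x3x2 contingency table for one SNP pair versus phenotype.

    ``counts[i, j, k]`` is the number of samples with genotype i at the first
    SNP, genotype j at the second, and phenotype k (0 control, 1 case).
    """

    counts: np.ndarray
    n_used: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3, 2):
            raise InvalidInputError("counts must have shape (3, 3, 2)")
        if (self.counts < 0).any():
            raise InvalidInputError("counts must be non-negative")
        if int(self.counts.sum()) != int(self.n_used):
            raise InvalidInputError("sum of counts must equal n_used")

    @property
    def n_cases(self) -> int:
        return int(self.counts[:, :, 1].sum())

    @property
    def n_controls(self) -> int:
        return int(self.counts[:, :, 0].sum())

    def transpose_loci(self) -> "PairTable":
        """The same table with the roles of the two SNPs swapped (i <-> j)."""
        return PairTable(self.counts.transpose(1, 0, 2).copy(), self.n_used, self.n_dropped)


@dataclass
class Margins:
    """All dot-convention margins of a PairTable (n_ij., n_i.k, n_.jk, ...)."""

    n_ij: np.ndarray  # (3, 3) summed over phenotype
    n_ik: np.ndarray  # (3, 2) summed over locus q
    n_jk: np.ndarray  # (3, 2) summed over locus p
    n_i: np.ndarray   # (3,)
    n_j: np.ndarray   # (3,)
    n_k: np.ndarray   # (2,)
    n: int


def build_pair_table(gp, gq, y) -> PairTable:
    """Tally the 3x3x2 table of (X_p, X_q, Y) with listwise deletion.

    A sample missing any of the three values is excluded from the table for
    this pair and counted in ``n_dropped``.

    Raises
    ------
    InvalidInputError
        If vector lengths differ, everything is missing, or one phenotype
        stratum is empty after exclusion.
    """
    gp = as_genotype_vector(gp)
    gq = as_genotype_vector(gq)
    y = as_phenotype_vector(y)
    if not (gp.shape == gq.shape == y.shape) or gp.ndim != 1:
        raise InvalidInputError("gp, gq, y must be 1-D vectors of equal length")
    keep = (gp != MISSING) & (gq != MISSING) & (y != MISSING)
    n_total = gp.size
    n_used = int(keep.sum())
    if n_used == 0:
        raise InvalidInputError("all samples missing for this pair")
    code = (gp[keep].astype(np.int64) * 6 + gq[keep].astype(np.int64) * 2 + y[keep])
    counts = np.bincount(code, minlength=18).reshape(3, 3, 2)
    t = PairTable(counts, n_used=n_used, n_dropped=n_total - n_used)
    if t.n_cases == 0 or t.n_controls == 0:
        raise InvalidInputError("need at least one case and one control")
    return t


def margins(t: PairTable) -> Margins:
    """All one- and two-way margins of the table under the dot convention."""
    c = t.counts
    return Margins(
        n_ij=c.sum(axis=2),
        n_ik=c.sum(axis=1),
        n_jk=c.sum(axis=0),
        n_i=c.sum(axis=(1, 2)),
        n_j=c.sum(axis=(0, 2)),
        n_k=c.sum(axis=(0, 1)),
        n=int(c.sum()),
    )


def genotype_combination_odds_ratios(t: PairTable, ref_cell: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Per-genotype-combination odds ratios relative to a reference cell.

    Entry (i, j) is ``(n_ij,case / n_ij,control) / (n_ref,case / n_ref,control)``.
    Combinations with no controls (zero denominator) are reported as NaN
    (undefined), not errors.  The reference cell must be occupied in both
    strata.
    """
    i0, j0 = ref_cell
    case = t.counts[:, :, 1].astype(float)
    ctrl = t.counts[:, :, 0].astype(float)
    if case[i0, j0] == 0 or ctrl[i0, j0] == 0:
        raise InvalidReferenceError(f"reference cell {ref_cell} empty in a phenotype stratum")
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = case / ctrl
        grid = odds / odds[i0, j0]
    grid[ctrl == 0] = np.nan
    return grid
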