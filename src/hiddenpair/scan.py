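"""The exhaustive two-step scan for pair associations masked by unfaithfulness.

Step 1 removes SNPs with significant main effects (single-locus 2-df G^2
test, multiplicity-adjusted); Step 2 tests every remaining pair with the
joint likelihood-ratio statistic 2(L_MH - L_MB) and adjusts over all
L'(L'-1)/2 pairs by Bonferroni or Benjamini-Hochberg.  A reported pair
therefore has weak marginal effects at both loci but a strong joint effect
-- the unfaithfulness signature.

The pair stage is vectorized: all pair tables are accumulated by one-hot
matrix products per phenotype stratum and the homogeneous-association model
is fit to the whole batch of 3x3x2 tables by batched IPF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import loglinear
from .loglinear import DEFAULT_IPF_MAX_ITER, DEFAULT_IPF_TOL, DEFAULT_JOINT_DF
from .tables import MISSING, GenotypeMatrix, InvalidInputError, as_phenotype_vector

__all__ = [
    "ScanConfig",
    "PairTestResult",
    "ScanResult",
    "adjust_pvalues",
    "marginal_pvalues",
    "filter_main_effects",
    "pairwise_scan",
    "scan_dataset",
]

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Knobs of the two-step scan.

    ``marginal_threshold`` removes SNPs whose adjusted single-locus P-value
    falls at or below it (default 0.1, the same default threshold governs
    both steps); ``joint_threshold`` keeps pairs whose adjusted joint P-value
    falls at or below it.  ``use_adjusted_marginal=False`` applies the Step-1
    threshold to raw P-values instead.
    """

    marginal_threshold: float = 0.1
    joint_threshold: float = 0.1
    correction: str = "bonferroni"  # or "bh"
    min_distance_bp: int | None = None
    joint_df: int = DEFAULT_JOINT_DF
    ipf_tol: float = DEFAULT_IPF_TOL
    ipf_max_iter: int = DEFAULT_IPF_MAX_ITER
    use_adjusted_marginal: bool = True
    min_minor_allele_count: int = 5

    def __post_init__(self) -> None:
        for name in ("marginal_threshold", "joint_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.correction not in {"bonferroni", "bh"}:
            raise ValueError("correction must be 'bonferroni' or 'bh'")


@dataclass
class PairTestResult:
    """One reported SNP pair from the joint stage."""

    snp_p: str
    snp_q: str
    chrom_p: str
    chrom_q: str
    pos_p: int
    pos_q: int
    joint_stat: float
    joint_df: int
    joint_p_raw: float
    joint_p_adj: float
    marginal_p_p: float
    marginal_p_q: float
    distance: int | None
    converged: bool = True
    flags: str = ""


@dataclass
class ScanResult:
    """Reported pairs plus bookkeeping for the whole scan."""

    pairs: list[PairTestResult]
    n_snps: int                 # L: SNPs in the input panel
    n_kept: int                 # L': SNPs entering the pair stage
    n_pairs_tested: int
    marginal_p_raw: np.ndarray  # per input SNP
    kept: np.ndarray            # indices of SNPs entering the pair stage
    n_flagged: int = 0


def adjust_pvalues(p, method: str, m: int | None = None) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment with multiple factor m.

    ``m`` defaults to ``len(p)`` and may exceed it (tests performed but not
    retained).  Bonferroni returns ``min(1, p*m)``; BH returns monotone
    step-up adjusted values.
    """
    p = np.asarray(p, dtype=float)
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError("multiple factor m must be >= number of P-values")
    if k == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, k + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(k)
        out[order] = np.minimum(1.0, adj)
        return out
    raise ValueError("method must be 'bonferroni' or 'bh'")


def _genotype_onehot(values: np.ndarray) -> np.ndarray:
    """(n, L) genotypes -> (L, 3, n) one-hot; missing rows are all-zero."""
    return np.stack([(values.T == g) for g in range(3)], axis=1).astype(np.float64)


def marginal_pvalues(G: GenotypeMatrix, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-locus 2-df G^2 statistics and raw P-values for every SNP.

    Each SNP's 3x2 genotype-by-phenotype table (complete cases for that SNP)
    is tested against independence.  Monomorphic SNPs yield G^2 = 0 and
    P = 1.
    """
    y = as_phenotype_vector(y)
    if G.n_snps == 0 or G.n_samples == 0:
        raise InvalidInputError("empty genotype matrix")
    keep = y != MISSING
    vals = G.values[keep]
    yk = y[keep]
    if not ((yk == 1).any() and (yk == 0).any()):
        raise InvalidInputError("need at least one case and one control")
    onehot = _genotype_onehot(vals)                       # (L, 3, n)
    ybin = np.stack([(yk == 0), (yk == 1)], axis=1).astype(np.float64)  # (n, 2)
    counts = onehot @ ybin                                # (L, 3, 2)
    row = counts.sum(axis=2, keepdims=True)
    col = counts.sum(axis=1, keepdims=True)
    n = counts.sum(axis=(1, 2), keepdims=True)
    expected = row * col / np.maximum(n, 1)
    ratio = np.ones_like(counts)
    np.divide(counts, expected, out=ratio, where=(counts > 0) & (expected > 0))
    with np.errstate(divide="ignore"):
        g2 = 2.0 * np.where(counts > 0, counts * np.log(ratio), 0.0).sum(axis=(1, 2))
    g2 = np.maximum(g2, 0.0)
    return g2, stats.chi2.sf(g2, 2)


def filter_main_effects(G: GenotypeMatrix, y, cfg: ScanConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Step 1: drop SNPs with significant main effects; keep the rest.

    Returns ``(kept_indices, raw_marginal_p)``.  All L single-locus P-values
    are adjusted with the configured correction (factor L) and a SNP is
    removed when its adjusted (or raw, if so configured) P-value is at or
    below the marginal threshold.
    """
    cfg = cfg or ScanConfig()
    _, p_raw = marginal_pvalues(G, y)
    p_used = adjust_pvalues(p_raw, cfg.correction, m=G.n_snps) if cfg.use_adjusted_marginal else p_raw
    kept = np.nonzero(p_used > cfg.marginal_threshold)[0]
    return kept, p_raw


def _pair_tables(values: np.ndarray, y: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Batch of 3x3x2 tables for pairs (idx_a[t], idx_b[t]), complete cases per pair."""
    onehot = _genotype_onehot(values)  # (L, 3, n); missing -> zero column
    cases = onehot[:, :, y == 1]
    ctrls = onehot[:, :, y == 0]
    t_case = np.einsum("tan,tbn->tab", cases[idx_a], cases[idx_b])
    t_ctrl = np.einsum("tan,tbn->tab", ctrls[idx_a], ctrls[idx_b])
    return np.stack([t_ctrl, t_case], axis=-1)


def pairwise_scan(G: GenotypeMatrix, y, kept, cfg: ScanConfig | None = None) -> ScanResult:
    """Step 2: joint-test every pair of kept SNPs and adjust over all pairs.

    SNPs with minor-allele count below ``cfg.min_minor_allele_count`` are
    excluded from the pair stage (their tables are degenerate).  Pairs whose
    adjusted joint P-value is at or below the joint threshold (and which
    satisfy the optional same-chromosome distance constraint) are returned
    sorted by adjusted P, ties broken by SNP identifiers.
    """
    cfg = cfg or ScanConfig()
    y = as_phenotype_vector(y)
    kept = np.asarray(kept, dtype=np.int64)
    keep_samples = y != MISSING
    vals = G.values[keep_samples]
    yk = y[keep_samples]

    mac = np.where(vals[:, kept] != MISSING, vals[:, kept], 0).sum(axis=0)
    poly = mac >= cfg.min_minor_allele_count
    if (~poly).any():
        logger.warning("excluding %d near-monomorphic SNPs (minor-allele count < %d) from pair stage",
                       int((~poly).sum()), cfg.min_minor_allele_count)
    tested = kept[poly]
    L2 = tested.size
    _, p_marg_all = marginal_pvalues(G, y)

    if L2 < 2:
        return ScanResult([], G.n_snps, L2, 0, p_marg_all, tested)

    ia, ib = np.triu_indices(L2, k=1)
    n_pairs = ia.size
    m_factor = L2 * (L2 - 1) // 2

    # batch over chunks of pairs to bound memory
    stats_all = np.empty(n_pairs)
    conv_all = np.empty(n_pairs, dtype=bool)
    frozen_all = np.empty(n_pairs, dtype=bool)
    chunk = 200_000
    for lo in range(0, n_pairs, chunk):
        sl = slice(lo, min(lo + chunk, n_pairs))
        tabs = _pair_tables(vals, yk, tested[ia[sl]], tested[ib[sl]])
        mu_h, _, conv, _ = loglinear._ipf_homogeneous(tabs, tol=cfg.ipf_tol, max_iter=cfg.ipf_max_iter)
        dev = (loglinear._deviance_vs_saturated(tabs, loglinear._mu_block(tabs))
               - loglinear._deviance_vs_saturated(tabs, mu_h))
        stats_all[sl] = np.maximum(dev, 0.0)
        conv_all[sl] = conv
        # zero two-way margins (beyond structurally absent genotype classes)
        # signal collinearity-frozen cells
        frozen_all[sl] = ((tabs.sum(axis=-1) == 0).reshape(tabs.shape[0], -1).any(axis=1))

    p_raw = stats.chi2.sf(stats_all, cfg.joint_df)
    p_adj = adjust_pvalues(p_raw, cfg.correction, m=m_factor)

    sig = p_adj <= cfg.joint_threshold
    results: list[PairTestResult] = []
    for t in np.nonzero(sig)[0]:
        a, b = int(tested[ia[t]]), int(tested[ib[t]])
        same_chrom = G.chrom[a] == G.chrom[b]
        dist = int(abs(G.pos[a] - G.pos[b])) if same_chrom else None
        if cfg.min_distance_bp is not None and same_chrom and dist < cfg.min_distance_bp:
            continue
        flags = []
        if not conv_all[t]:
            flags.append("ipf_not_converged")
        if frozen_all[t]:
            flags.append("zero_margin")
        results.append(PairTestResult(
            snp_p=str(G.snp_ids[a]), snp_q=str(G.snp_ids[b]),
            chrom_p=str(G.chrom[a]), chrom_q=str(G.chrom[b]),
            pos_p=int(G.pos[a]), pos_q=int(G.pos[b]),
            joint_stat=float(stats_all[t]), joint_df=cfg.joint_df,
            joint_p_raw=float(p_raw[t]), joint_p_adj=float(p_adj[t]),
            marginal_p_p=float(p_marg_all[a]), marginal_p_q=float(p_marg_all[b]),
            distance=dist, converged=bool(conv_all[t]),
            flags=";".join(flags),
        ))
    results.sort(key=lambda r: (r.joint_p_adj, r.snp_p, r.snp_q))
    n_flagged = sum(1 for r in results if r.flags)
    logger.info("scan: L=%d, L'=%d, pairs tested=%d, reported=%d, flagged=%d",
                G.n_snps, L2, n_pairs, len(results), n_flagged)
    return ScanResult(results, G.n_snps, L2, n_pairs, p_marg_all, tested, n_flagged)


def scan_dataset(G: GenotypeMatrix, y, cfg: ScanConfig | None = None) -> ScanResult:
    """Run both steps: marginal filtering then the exhaustive pair scan."""
    cfg = cfg or ScanConfig()
    kept, _ = filter_main_effects(G, y, cfg)
    return pairwise_scan(G, y, kept, cfg)
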