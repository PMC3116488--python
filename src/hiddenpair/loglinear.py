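"""Log-linear model fits and likelihood-ratio tests on 3x3x2 tables.

Three hierarchical log-linear models are fit to the pair table of
(X_p, X_q, Y):

* block independence  M_B = [X_p X_q][Y]          -- phenotype jointly
  independent of both SNPs; equivalent to the intercept-only logistic model.
* partial independence M_P = [X_p X_q][X_p Y]      (or the symmetric q form)
  -- phenotype depends on one SNP only; equivalent to the one-SNP categorical
  logistic model.
* homogeneous association M_H = [X_p X_q][X_p Y][X_q Y] -- both SNP-phenotype
  associations but no three-way interaction; equivalent to the two-SNP
  additive-in-factors categorical logistic model.

M_B and M_P have closed-form MLEs; M_H is fit by iterative proportional
fitting (IPF) over its three two-way margins.  The deviance (G^2) between
nested fits is the likelihood-ratio statistic of the corresponding logistic
comparison, referred to a chi-square distribution.

Zero margins: a fitted cell whose defining margin is zero is set to zero and
stays frozen at zero throughout IPF; 0*log(0) is taken as 0 in all
likelihood sums.  Degrees of freedom are not reduced for frozen cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tables import InvalidInputError, PairTable

__all__ = [
    "FittedTable",
    "TestStatistic",
    "fit_block_independence",
    "fit_partial_independence",
    "fit_homogeneous_association",
    "table_loglik",
    "joint_test",
    "marginal_test",
    "chi2_pvalue",
    "DEFAULT_IPF_TOL",
    "DEFAULT_IPF_MAX_ITER",
    "DEFAULT_JOINT_DF",
]

DEFAULT_IPF_TOL = 1e-6
DEFAULT_IPF_MAX_ITER = 100
DEFAULT_JOINT_DF = 4

BLOCK_INDEPENDENCE = "block_independence"
PARTIAL_INDEPENDENCE_P = "partial_independence_p"
PARTIAL_INDEPENDENCE_Q = "partial_independence_q"
HOMOGENEOUS_ASSOCIATION = "homogeneous_association"


@dataclass
class FittedTable:
    """Expected cell counts under a named log-linear model."""

    mu: np.ndarray
    model: str
    iterations: int = 0
    converged: bool = True
    max_abs_change: float = 0.0


@dataclass
class TestStatistic:
    """A likelihood-ratio statistic with its chi-square reference."""

    stat: float
    df: int
    p_raw: float
    converged: bool = True


def _check_nonempty(t: PairTable) -> np.ndarray:
    c = np.asarray(t.counts, dtype=float)
    if c.sum() <= 0:
        raise InvalidInputError("empty table")
    return c


# ---------------------------------------------------------------------------
# batched kernels: `counts` has shape (..., 3, 3, 2)

def _mu_block(counts: np.ndarray) -> np.ndarray:
    n_ij = counts.sum(axis=-1)
    n_k = counts.sum(axis=(-3, -2))
    n = counts.sum(axis=(-3, -2, -1))
    return n_ij[..., None] * n_k[..., None, None, :] / n[..., None, None, None]


def _mu_partial(counts: np.ndarray, locus: str) -> np.ndarray:
    n_ij = counts.sum(axis=-1)
    if locus == "p":
        n_ik = counts.sum(axis=-2)
        n_i = counts.sum(axis=(-2, -1))
        num = n_ij[..., :, :, None] * n_ik[..., :, None, :]
        den = n_i[..., :, None, None]
    elif locus == "q":
        n_jk = counts.sum(axis=-3)
        n_j = counts.sum(axis=(-3, -1))
        num = n_ij[..., :, :, None] * n_jk[..., None, :, :]
        den = n_j[..., None, :, None]
    else:
        raise ValueError("locus must be 'p' or 'q'")
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape))
    np.divide(num, den, out=out, where=den > 0)
    return out


def _safe_ratio(target: np.ndarray, current: np.ndarray) -> np.ndarray:
    """target/current where both positive; 0 where the target margin is 0.

    A zero target margin forces every cell in its slice to zero, implementing
    the zero-margin remedy; current > 0 wherever target > 0 because IPF
    margins stay consistent with the observed table.
    """
    out = np.zeros_like(target, dtype=float)
    np.divide(target, current, out=out, where=(target > 0) & (current > 0))
    return out


def _ipf_homogeneous(
    counts: np.ndarray,
    tol: float = DEFAULT_IPF_TOL,
    max_iter: int = DEFAULT_IPF_MAX_ITER,
) -> tuple[np.ndarray, int, np.ndarray, np.ndarray]:
    """Cyclic IPF for M_H on a batch of tables.

    Returns (mu, iterations, converged, max_abs_change) where converged and
    max_abs_change are per-table over the leading batch axes.
    """
    counts = np.asarray(counts, dtype=float)
    n_ij = counts.sum(axis=-1)
    n_ik = counts.sum(axis=-2)
    n_jk = counts.sum(axis=-3)
    mu = np.ones_like(counts)
    batch_axes = tuple(range(counts.ndim - 3, counts.ndim))
    delta = np.full(counts.shape[:-3], np.inf)
    it = 0
    for it in range(1, max_iter + 1):
        old = mu.copy()
        mu = mu * _safe_ratio(n_ij, mu.sum(axis=-1))[..., None]
        mu = mu * _safe_ratio(n_ik, mu.sum(axis=-2))[..., :, None, :]
        mu = mu * _safe_ratio(n_jk, mu.sum(axis=-3))[..., None, :, :]
        delta = np.abs(mu - old).max(axis=batch_axes)
        if np.all(delta < tol):
            break
    return mu, it, delta < tol, delta


def _deviance_vs_saturated(counts: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """G^2 = 2 sum n log(n/mu) over occupied cells, batched."""
    ratio = np.ones_like(mu)
    occupied = counts > 0
    np.divide(counts, mu, out=ratio, where=occupied & (mu > 0))
    ratio[occupied & (mu <= 0)] = np.inf
    with np.errstate(divide="ignore"):
        term = np.where(occupied, counts * np.log(ratio), 0.0)
    return 2.0 * term.sum(axis=(-3, -2, -1))


# ---------------------------------------------------------------------------
# single-table public API

def fit_block_independence(t: PairTable) -> FittedTable:
    """Closed-form MLE of the block independence model M_B.

    mu_ijk = n_ij. * n_..k / n.
    """
    c = _check_nonempty(t)
    return FittedTable(_mu_block(c), BLOCK_INDEPENDENCE)


def fit_partial_independence(t: PairTable, locus: str = "p") -> FittedTable:
    """Closed-form MLE of the partial independence model M_P.

    For ``locus='p'``: mu_ijk = n_ij. * n_i.k / n_i.. (phenotype depends on
    X_p only); ``locus='q'`` is the symmetric form over the j margins.
    """
    c = _check_nonempty(t)
    model = PARTIAL_INDEPENDENCE_P if locus == "p" else PARTIAL_INDEPENDENCE_Q
    return FittedTable(_mu_partial(c, locus), model)


def fit_homogeneous_association(
    t: PairTable,
    tol: float = DEFAULT_IPF_TOL,
    max_iter: int = DEFAULT_IPF_MAX_ITER,
) -> FittedTable:
    """MLE of the homogeneous association model M_H by IPF.

    Starting from mu = 1 everywhere, cycles the three margin-scaling updates
    over {n_ij., n_i.k, n_.jk} until the largest absolute cell change in a
    full cycle drops below ``tol`` or ``max_iter`` cycles are reached.
    Non-convergence is flagged, not raised.
    """
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be > 0 and max_iter >= 1")
    c = _check_nonempty(t)
    mu, it, conv, delta = _ipf_homogeneous(c, tol=tol, max_iter=max_iter)
    return FittedTable(mu, HOMOGENEOUS_ASSOCIATION, iterations=it,
                       converged=bool(conv), max_abs_change=float(delta))


def table_loglik(t: PairTable, f: FittedTable) -> float:
    """Poisson-kernel log-likelihood sum n_ijk log mu_ijk - sum mu_ijk.

    Constants (log n_ijk!) are dropped.  Cells with n = 0 contribute -mu;
    a cell with mu = 0 but n > 0 yields -inf.
    """
    n = np.asarray(t.counts, dtype=float)
    mu = np.asarray(f.mu, dtype=float)
    if n.shape != mu.shape:
        raise InvalidInputError("shape mismatch between table and fit")
    if np.any((n > 0) & (mu <= 0)):
        return float("-inf")
    with np.errstate(divide="ignore"):
        term = np.where(n > 0, n * np.log(np.where(mu > 0, mu, 1.0)), 0.0)
    return float(term.sum() - mu.sum())


def chi2_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square probability of the statistic."""
    if stat < 0:
        raise InvalidInputError("statistic must be non-negative")
    if df < 1:
        raise InvalidInputError("df must be >= 1")
    return float(stats.chi2.sf(stat, df))


def joint_test(
    t: PairTable,
    df: int = DEFAULT_JOINT_DF,
    tol: float = DEFAULT_IPF_TOL,
    max_iter: int = DEFAULT_IPF_MAX_ITER,
) -> TestStatistic:
    """Likelihood-ratio test of M_H against M_B (joint association of the pair).

    The statistic 2(L_MH - L_MB) equals the logistic LRT of the two-SNP
    categorical model against the intercept-only model.  ``df`` defaults to 4,
    the (I-1)(K-1) + (J-1)(K-1) parameter-count difference; pass ``df=2`` to
    reproduce the alternative printed convention.
    """
    c = _check_nonempty(t)
    mu_h, _, conv, _ = _ipf_homogeneous(c, tol=tol, max_iter=max_iter)
    stat = _deviance_vs_saturated(c, _mu_block(c)) - _deviance_vs_saturated(c, mu_h)
    stat = float(max(stat, 0.0))
    return TestStatistic(stat, df, chi2_pvalue(stat, df), converged=bool(conv))


def marginal_test(t: PairTable, locus: str = "p") -> TestStatistic:
    """Likelihood-ratio test of M_P against M_B (main effect of one SNP).

    Equals the 2-df single-SNP G^2 test on the table collapsed over the other
    locus.
    """
    c = _check_nonempty(t)
    stat = _deviance_vs_saturated(c, _mu_block(c)) - _deviance_vs_saturated(c, _mu_partial(c, locus))
    stat = float(max(stat, 0.0))
    return TestStatistic(stat, 2, chi2_pvalue(stat, 2))
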