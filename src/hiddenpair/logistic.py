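"""Direct logistic-regression fits for the two-locus association models.

This module fits the logistic models underlying the pair test by iteratively
reweighted least squares (IRLS): the intercept-only null M0, the one-SNP
categorical models M1/M2 (indicator coding I(X=1), I(X=2), major homozygote
as reference), the two-SNP additive-in-factors model M12, and the
allele-count additive codings used to report marginal and bivariate slopes
with z-values.  Doubled log-likelihood differences between these fits equal
the log-linear deviances computed by :mod:`hiddenpair.loglinear`, which makes
this module the independent cross-check of the IPF route.

Collinear (aliased) design columns are detected by pivoted QR and dropped
from the fit; the dropped names are reported on the result rather than
raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import expit

from .tables import MISSING, InvalidInputError, PairTable, as_genotype_vector, as_phenotype_vector

__all__ = [
    "LogisticFit",
    "fit_categorical",
    "fit_categorical_from_table",
    "fit_additive_bivariate",
    "fit_additive_marginal",
    "predict_marginal_from_joint",
]

MAX_ITER = 50
LOGLIK_TOL = 1e-10
RIDGE = 1e-8


@dataclass
class LogisticFit:
    """An IRLS logistic fit: coefficients, standard errors and z-values.

    ``coefficients[0]`` is the intercept.  Aliased (dropped) columns are
    listed in ``aliased`` and do not appear in the coefficient vector.
    """

    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    loglik: float
    model_tag: str
    column_names: list[str] = field(default_factory=list)
    aliased: list[str] = field(default_factory=list)
    converged: bool = True
    iterations: int = 0


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Remove columns that are linearly dependent on earlier ones (pivoted QR)."""
    if X.shape[1] == 0:
        return X, names, []
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [names[i] for i in sorted(piv[rank:])]
    return X[:, keep], [names[i] for i in keep], dropped


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    model_tag: str,
    weights: np.ndarray | None = None,
) -> LogisticFit:
    """Weighted Bernoulli IRLS with a small ridge on the normal equations."""
    w0 = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    X, names, aliased = _drop_aliased(X, names)

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    eye = np.eye(X.shape[1])
    for it in range(1, MAX_ITER + 1):
        eta = X @ beta
        p = expit(eta)
        pc = np.clip(p, 1e-12, 1 - 1e-12)
        ll = float(np.sum(w0 * (y * np.log(pc) + (1 - y) * np.log1p(-pc))))
        if abs(ll - ll_old) < LOGLIK_TOL:
            converged = True
            break
        ll_old = ll
        w = w0 * p * (1 - p)
        info = X.T @ (X * w[:, None]) + RIDGE * eye
        score = X.T @ (w0 * (y - p))
        beta = beta + np.linalg.solve(info, score)
    eta = X @ beta
    p = expit(eta)
    w = w0 * p * (1 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]) + RIDGE * eye)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    return LogisticFit(beta, se, z, ll, model_tag, column_names=names,
                       aliased=aliased, converged=converged, iterations=it)


def _indicator_columns(g: np.ndarray, label: str) -> tuple[np.ndarray, list[str]]:
    cols = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
    return cols, [f"I({label}=1)", f"I({label}=2)"]


def _complete_cases(*vectors: np.ndarray) -> np.ndarray:
    keep = np.ones(vectors[0].shape, dtype=bool)
    for v in vectors:
        keep &= v != MISSING
    if not keep.any():
        raise InvalidInputError("no complete cases")
    return keep


def fit_categorical(gp, gq, y, model_tag: str, weights: np.ndarray | None = None) -> LogisticFit:
    """Fit one of the categorical logistic models M0, M1, M2, M12.

    M0 is intercept-only; M1 (M2) adds indicators for X_p (X_q); M12 adds
    both SNPs' indicators with no product (interaction) term.
    """
    if model_tag not in {"M0", "M1", "M2", "M12"}:
        raise ValueError(f"unknown model_tag {model_tag!r}")
    gp = as_genotype_vector(gp)
    gq = as_genotype_vector(gq)
    yv = as_phenotype_vector(y)
    keep = _complete_cases(gp, gq, yv)
    gp, gq, yv = gp[keep], gq[keep], yv[keep]
    w = None if weights is None else np.asarray(weights, dtype=float)[keep]

    cols = [np.ones(len(yv))]
    names = ["intercept"]
    if model_tag in {"M1", "M12"}:
        c, nm = _indicator_columns(gp, "Xp")
        cols.append(c)
        names += nm
    if model_tag in {"M2", "M12"}:
        c, nm = _indicator_columns(gq, "Xq")
        cols.append(c)
        names += nm
    X = np.column_stack(cols)
    return _irls(X, yv.astype(float), names, model_tag, weights=w)


def fit_categorical_from_table(t: PairTable, model_tag: str) -> LogisticFit:
    """Fit a categorical model to the 18 cells of a pair table (count weights)."""
    i, j, k = np.meshgrid(np.arange(3), np.arange(3), np.arange(2), indexing="ij")
    w = np.asarray(t.counts, dtype=float).ravel()
    nz = w > 0
    return fit_categorical(i.ravel()[nz], j.ravel()[nz], k.ravel()[nz],
                           model_tag, weights=w[nz])


def fit_additive_marginal(g, y) -> LogisticFit:
    """One-SNP additive logistic fit: logit P(Y=1) = b0 + bm * g.

    ``bm`` is the marginal coefficient of the SNP with its z-value; a
    monomorphic SNP leaves the slope aliased.
    """
    g = as_genotype_vector(g)
    yv = as_phenotype_vector(y)
    keep = _complete_cases(g, yv)
    g, yv = g[keep], yv[keep]
    X = np.column_stack([np.ones(len(yv)), g.astype(float)])
    return _irls(X, yv.astype(float), ["intercept", "g"], "additive_marginal")


def fit_additive_bivariate(gp, gq, y) -> LogisticFit:
    """Two-SNP additive logistic fit: logit P(Y=1) = b0 + b1*gp + b2*gq.

    Returns the bivariate regression coefficients (beta_1, beta_2) with
    z-values; a perfectly collinear pair leaves the second slope aliased.
    """
    gp = as_genotype_vector(gp)
    gq = as_genotype_vector(gq)
    yv = as_phenotype_vector(y)
    keep = _complete_cases(gp, gq, yv)
    gp, gq, yv = gp[keep], gq[keep], yv[keep]
    X = np.column_stack([np.ones(len(yv)), gp.astype(float), gq.astype(float)])
    return _irls(X, yv.astype(float), ["intercept", "gp", "gq"], "additive_bivariate")


def predict_marginal_from_joint(betas, rho, p_index: int) -> float:
    """Expected marginal coefficient implied by joint coefficients and correlation.

    For joint slopes beta_q and predictor correlations rho(X_q, X_p) (with
    rho = 1 for the self term), the expectation of the marginal slope of
    X_p is sum_q beta_q * rho(X_q, X_p).  Correlated slopes of opposite sign
    can cancel here, which is the unfaithfulness phenomenon.
    """
    betas = np.asarray(betas, dtype=float)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if np.any(np.abs(rho) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    return float(betas @ rho[:, p_index])
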