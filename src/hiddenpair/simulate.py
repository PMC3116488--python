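"""Two-locus case-control disease simulator with LD-correlated causal SNPs.

The disease model is multiplicative on the odds scale: with i and j the
minor-allele counts at the two causal loci, the odds of disease are

    odds(i, j) = alpha * theta_a**i * theta_b**j,   theta_a = theta,
                                                    theta_b = 1/theta,

so the two loci push disease risk in opposite directions with equal strength
and there is no interaction term on the log-odds scale.  Penetrance is
odds/(1+odds).  The causal pair is in linkage disequilibrium: haplotype
frequencies are built from the two minor-allele frequencies and a target
genotype correlation r^2 (with a chosen sign of D), and individuals are
random unions of two haplotypes (Hardy-Weinberg equilibrium).

(alpha, theta) are not specified directly; they are solved numerically so
that the population disease prevalence p(D) and the variance-ratio
heritability

    h^2 = Var_G[p(D|G)] / (p(D) * (1 - p(D)))

hit requested targets (0.1 and 0.02 by default).  Case-control data sets are
drawn retrospectively (rejection sampling until the requested numbers of
cases and controls are filled), and independent null SNPs in
Hardy-Weinberg equilibrium are appended to form a scan panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .scan import ScanConfig, adjust_pvalues, marginal_pvalues, scan_dataset
from .tables import GenotypeMatrix, InvalidInputError

__all__ = [
    "DiseaseModel",
    "SimConfig",
    "InvalidConfigurationError",
    "penetrance_table",
    "haplotype_freqs",
    "genotype_distribution",
    "analytic_prevalence",
    "analytic_heritability",
    "solve_model_params",
    "simulate_dataset",
    "empirical_model_stats",
    "power_experiment",
]


class InvalidConfigurationError(ValueError):
    """Raised when a requested simulation setting is unachievable."""


def penetrance_table(alpha: float, theta: float) -> np.ndarray:
    """3x3 grid of penetrances p(D | i, j) under the multiplicative-odds model.

    Row index i is the minor-allele count at the risk locus (theta_a = theta),
    column index j at the protective locus (theta_b = 1/theta).  On the
    diagonal the two effects cancel and the odds stay at alpha.
    """
    if alpha <= 0 or theta <= 0:
        raise InvalidConfigurationError("alpha and theta must be positive")
    i = np.arange(3)[:, None]
    j = np.arange(3)[None, :]
    odds = alpha * theta ** i * (1.0 / theta) ** j
    return odds / (1.0 + odds)


def haplotype_freqs(maf_p: float, maf_q: float, ld_r2: float, ld_sign: str = "+") -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) for a target LD level.

    Upper-case letters are major alleles.  D = sign * sqrt(r^2 * p(1-p)q(1-q))
    is added to the coupling haplotypes (AB, ab) and subtracted from the
    repulsion haplotypes (Ab, aB).

    Raises
    ------
    InvalidConfigurationError
        If the requested r^2 is not achievable for these allele frequencies;
        the message reports the achievable maximum.
    """
    if not (0 < maf_p <= 0.5 and 0 < maf_q <= 0.5):
        raise InvalidConfigurationError("minor-allele frequencies must be in (0, 0.5]")
    if not (0 <= ld_r2 <= 1):
        raise InvalidConfigurationError("ld_r2 must be in [0, 1]")
    if ld_sign not in {"+", "-"}:
        raise InvalidConfigurationError("ld_sign must be '+' or '-'")
    sign = 1.0 if ld_sign == "+" else -1.0
    d = sign * np.sqrt(ld_r2 * maf_p * (1 - maf_p) * maf_q * (1 - maf_q))
    if sign > 0:
        d_max = min(maf_p * (1 - maf_q), (1 - maf_p) * maf_q)
    else:
        d_max = min(maf_p * maf_q, (1 - maf_p) * (1 - maf_q))
    if abs(d) > d_max + 1e-12:
        r2_max = d_max ** 2 / (maf_p * (1 - maf_p) * maf_q * (1 - maf_q))
        raise InvalidConfigurationError(
            f"r^2 = {ld_r2} with sign {ld_sign} unachievable for MAFs "
            f"({maf_p}, {maf_q}); maximum achievable r^2 is {r2_max:.4f}")
    f = np.array([
        (1 - maf_p) * (1 - maf_q) + d,  # AB
        (1 - maf_p) * maf_q - d,        # Ab
        maf_p * (1 - maf_q) - d,        # aB
        maf_p * maf_q + d,              # ab
    ])
    f = np.clip(f, 0.0, 1.0)
    return f / f.sum()


# minor-allele counts carried by each haplotype, order (AB, Ab, aB, ab)
_HAP_P = np.array([0, 0, 1, 1])
_HAP_Q = np.array([0, 1, 0, 1])


def genotype_distribution(hap: np.ndarray) -> np.ndarray:
    """3x3 population distribution of two-locus genotypes under HWE.

    Diplotype probabilities are products of haplotype frequencies; entry
    (i, j) sums over haplotype pairs carrying i minor alleles at the first
    locus and j at the second.
    """
    dist = np.zeros((3, 3))
    for a in range(4):
        for b in range(4):
            dist[_HAP_P[a] + _HAP_P[b], _HAP_Q[a] + _HAP_Q[b]] += hap[a] * hap[b]
    return dist


@dataclass
class DiseaseModel:
    """Parameterization of the two-locus disease model.

    ``alpha`` is the baseline odds, ``theta`` the per-minor-allele odds
    multiplier (risk locus theta, protective locus 1/theta).  Prevalence and
    heritability are derived quantities; use :func:`solve_model_params` (or
    :meth:`from_targets`) to choose (alpha, theta) hitting targets.
    """

    alpha: float
    theta: float
    maf_p: float = 0.3
    maf_q: float = 0.3
    ld_r2: float = 0.5
    ld_sign: str = "+"

    def __post_init__(self) -> None:
        self.haplotypes = haplotype_freqs(self.maf_p, self.maf_q, self.ld_r2, self.ld_sign)
        pen = penetrance_table(self.alpha, self.theta)
        if not np.all((pen > 0) & (pen < 1)):
            raise InvalidConfigurationError("penetrances must lie strictly in (0, 1)")

    @property
    def penetrance(self) -> np.ndarray:
        return penetrance_table(self.alpha, self.theta)

    @property
    def genotype_dist(self) -> np.ndarray:
        return genotype_distribution(self.haplotypes)

    @property
    def prevalence(self) -> float:
        return analytic_prevalence(self)

    @property
    def heritability(self) -> float:
        return analytic_heritability(self)

    @classmethod
    def from_targets(cls, prevalence: float = 0.1, h2: float = 0.02,
                     maf_p: float = 0.3, maf_q: float = 0.3,
                     ld_r2: float = 0.5, ld_sign: str = "+") -> "DiseaseModel":
        return solve_model_params(prevalence, h2, maf_p, maf_q, ld_r2, ld_sign)


def analytic_prevalence(m: DiseaseModel) -> float:
    """p(D) = sum_G P(G) p(D|G) over the nine genotype classes."""
    return float((m.genotype_dist * m.penetrance).sum())


def analytic_heritability(m: DiseaseModel) -> float:
    """Variance-ratio heritability Var_G[p(D|G)] / (p(D)(1-p(D)))."""
    pg = m.genotype_dist
    pen = m.penetrance
    prev = float((pg * pen).sum())
    var = float((pg * (pen - prev) ** 2).sum())
    return var / (prev * (1 - prev))


def _solve_alpha(theta: float, target_prev: float, pg: np.ndarray) -> float:
    """Baseline odds hitting the target prevalence at fixed theta (monotone)."""
    def resid(log_alpha: float) -> float:
        pen = penetrance_table(np.exp(log_alpha), theta)
        return float((pg * pen).sum()) - target_prev
    return float(np.exp(optimize.brentq(resid, -40.0, 40.0, xtol=1e-15, rtol=8.9e-16)))


def solve_model_params(target_prevalence: float, target_h2: float,
                       maf_p: float = 0.3, maf_q: float = 0.3,
                       ld_r2: float = 0.5, ld_sign: str = "+") -> DiseaseModel:
    """Numerically solve (alpha, theta >= 1) for prevalence and heritability targets.

    Nested root finding: for each candidate theta the baseline odds alpha is
    solved against the prevalence equation (monotone in alpha), then theta is
    solved against the heritability equation.  Residuals are driven below
    1e-10.

    Raises
    ------
    InvalidConfigurationError
        If the targets are outside the searchable bracket.
    """
    if not (0 < target_prevalence < 1):
        raise InvalidConfigurationError("prevalence must be in (0, 1)")
    if target_h2 < 0:
        raise InvalidConfigurationError("heritability must be >= 0")
    hap = haplotype_freqs(maf_p, maf_q, ld_r2, ld_sign)
    pg = genotype_distribution(hap)
    if target_h2 == 0:
        alpha = target_prevalence / (1 - target_prevalence)
        return DiseaseModel(alpha, 1.0, maf_p, maf_q, ld_r2, ld_sign)

    def h2_resid(theta: float) -> float:
        alpha = _solve_alpha(theta, target_prevalence, pg)
        m = DiseaseModel(alpha, theta, maf_p, maf_q, ld_r2, ld_sign)
        return analytic_heritability(m) - target_h2

    hi = 1.5
    while h2_resid(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise InvalidConfigurationError("heritability target unreachable in bracket")
    theta = float(optimize.brentq(h2_resid, 1.0 + 1e-12, hi, xtol=1e-14, rtol=8.9e-16))
    alpha = _solve_alpha(theta, target_prevalence, pg)
    model = DiseaseModel(alpha, theta, maf_p, maf_q, ld_r2, ld_sign)
    if (abs(analytic_prevalence(model) - target_prevalence) > 1e-10
            or abs(analytic_heritability(model) - target_h2) > 1e-10):
        raise InvalidConfigurationError("root finding failed to reach residual tolerance")
    return model


@dataclass
class SimConfig:
    """Design of one simulated case-control panel.

    Defaults follow the simulation design: 500 cases and 500 controls per
    data set, the causal pair embedded among 98 independent null SNPs
    (100 SNPs total), null minor-allele frequencies uniform on
    ``null_maf_range``.
    """

    model: DiseaseModel
    n_cases: int = 500
    n_controls: int = 500
    n_null_snps: int = 98
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise InvalidConfigurationError("need at least one case and one control")
        lo, hi = self.null_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidConfigurationError("null_maf_range must satisfy 0 < lo <= hi <= 0.5")


def _draw_causal_genotypes(model: DiseaseModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) minor-allele counts at the causal pair: random unions of haplotypes."""
    haps = rng.choice(4, size=(n, 2), p=model.haplotypes)
    gp = _HAP_P[haps].sum(axis=1)
    gq = _HAP_Q[haps].sum(axis=1)
    return np.column_stack([gp, gq]).astype(np.int8)


_MAX_REJECTION_BATCHES = 10_000


def simulate_dataset(cfg: SimConfig, replicate_index: int = 0
                     ) -> tuple[GenotypeMatrix, np.ndarray, dict]:
    """One retrospective case-control panel, deterministic in (seed, replicate).

    Genotypes at the causal pair are drawn from the population model, disease
    status by penetrance, and individuals are accepted until the case and
    control quotas fill.  Null SNPs are independent binomial(2, maf) columns.
    The causal pair occupies the two middle columns; the returned truth
    record names them and the model parameters.
    """
    rng = np.random.default_rng([cfg.seed, replicate_index])
    model = cfg.model
    pen = model.penetrance
    n_needed = cfg.n_cases + cfg.n_controls

    cases: list[np.ndarray] = []
    ctrls: list[np.ndarray] = []
    n_cases = n_ctrls = 0
    batch = max(1000, 4 * n_needed)
    for _ in range(_MAX_REJECTION_BATCHES):
        g = _draw_causal_genotypes(model, batch, rng)
        affected = rng.random(batch) < pen[g[:, 0], g[:, 1]]
        if n_cases < cfg.n_cases:
            cases.append(g[affected])
            n_cases += int(affected.sum())
        if n_ctrls < cfg.n_controls:
            ctrls.append(g[~affected])
            n_ctrls += int((~affected).sum())
        if n_cases >= cfg.n_cases and n_ctrls >= cfg.n_controls:
            break
    else:
        raise InvalidConfigurationError(
            "rejection sampling failed to fill case/control quotas; "
            "penetrances too extreme for the requested design")

    causal = np.vstack([np.concatenate(cases)[:cfg.n_cases],
                        np.concatenate(ctrls)[:cfg.n_controls]])
    y = np.concatenate([np.ones(cfg.n_cases, dtype=np.int8),
                        np.zeros(cfg.n_controls, dtype=np.int8)])

    mafs = rng.uniform(*cfg.null_maf_range, size=cfg.n_null_snps)
    nulls = rng.binomial(2, mafs, size=(n_needed, cfg.n_null_snps)).astype(np.int8)

    L = cfg.n_null_snps + 2
    causal_idx = (L // 2 - 1, L // 2)
    values = np.empty((n_needed, L), dtype=np.int8)
    null_cols = [c for c in range(L) if c not in causal_idx]
    values[:, list(causal_idx)] = causal
    values[:, null_cols] = nulls

    snp_ids = np.array([f"snp{c:04d}" for c in range(L)], dtype=object)
    chrom = np.array(["1"] * L, dtype=object)
    pos = 1 + 10_000 * np.arange(L, dtype=np.int64)
    G = GenotypeMatrix(values, snp_ids, chrom, pos)
    truth = {
        "causal_indices": causal_idx,
        "causal_ids": (str(snp_ids[causal_idx[0]]), str(snp_ids[causal_idx[1]])),
        "alpha": model.alpha,
        "theta": model.theta,
        "maf_p": model.maf_p,
        "maf_q": model.maf_q,
        "ld_r2": model.ld_r2,
        "ld_sign": model.ld_sign,
        "prevalence": model.prevalence,
        "heritability": model.heritability,
        "seed": cfg.seed,
        "replicate": replicate_index,
    }
    return G, y, truth


def empirical_model_stats(model: DiseaseModel, n: int = 1_000_000,
                          rng: np.random.Generator | None = None
                          ) -> tuple[float, float, float]:
    """Prospective cohort check: (prevalence_hat, h2_hat, r2_hat).

    Simulates ``n`` population individuals, assigns disease by penetrance,
    and estimates the disease fraction, the variance-ratio heritability from
    per-genotype-class penetrance estimates, and the squared genotype
    correlation of the causal pair.
    """
    rng = rng or np.random.default_rng()
    g = _draw_causal_genotypes(model, n, rng)
    pen = model.penetrance
    affected = rng.random(n) < pen[g[:, 0], g[:, 1]]
    prev_hat = float(affected.mean())

    cell = g[:, 0] * 3 + g[:, 1]
    n_g = np.bincount(cell, minlength=9).astype(float)
    d_g = np.bincount(cell, weights=affected.astype(float), minlength=9)
    with np.errstate(invalid="ignore"):
        pen_hat = np.where(n_g > 0, d_g / np.maximum(n_g, 1), 0.0)
    var = float((n_g / n * (pen_hat - prev_hat) ** 2).sum())
    h2_hat = var / (prev_hat * (1 - prev_hat))

    r = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
    return prev_hat, h2_hat, float(r ** 2)


def power_experiment(models, cfg: SimConfig, methods=("marginal", "joint_scan"),
                     alpha: float = 0.05, scan_cfg: ScanConfig | None = None
                     ) -> pd.DataFrame:
    """Detection power of the marginal test and/or the joint pair scan.

    For each disease model, ``cfg.replicates`` panels are generated.  The
    marginal test detects when either causal SNP's Bonferroni-adjusted
    single-locus P-value is at or below ``alpha``; the joint scan detects
    when the planted pair appears among the reported pairs of the two-step
    scan run at joint threshold ``alpha``.  Returns a tidy table with one
    row per (model, method).
    """
    rows = []
    for model in models:
        mcfg = replace(cfg, model=model)
        hits = {m: 0 for m in methods}
        for r in range(cfg.replicates):
            G, y, truth = simulate_dataset(mcfg, r)
            ids = set(truth["causal_ids"])
            if "marginal" in methods:
                _, p_raw = marginal_pvalues(G, y)
                p_adj = adjust_pvalues(p_raw, "bonferroni", m=G.n_snps)
                if min(p_adj[list(truth["causal_indices"])]) <= alpha:
                    hits["marginal"] += 1
            if "joint_scan" in methods:
                sc = scan_cfg or ScanConfig(joint_threshold=alpha, correction="bonferroni")
                res = scan_dataset(G, y, sc)
                if any({p.snp_p, p.snp_q} == ids for p in res.pairs):
                    hits["joint_scan"] += 1
        for m in methods:
            rows.append({
                "maf_p": model.maf_p, "maf_q": model.maf_q, "ld_r2": model.ld_r2,
                "theta": model.theta, "alpha_odds": model.alpha,
                "h2": model.heritability, "prevalence": model.prevalence,
                "n_cases": cfg.n_cases, "n_controls": cfg.n_controls,
                "replicates": cfg.replicates, "method": m,
                "n_detected": hits[m], "power": hits[m] / cfg.replicates,
            })
    return pd.DataFrame(rows)
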