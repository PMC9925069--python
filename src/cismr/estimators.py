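"""Core two-sample MR estimators on harmonised instruments.

Notation: per variant j, gamma_j (se s_gamma_j) is the SNP-exposure
association and Gamma_j (se s_Gamma_j) the SNP-outcome association.  The
Wald ratio is beta_j = Gamma_j / gamma_j with first-order standard error
s_Gamma_j / |gamma_j|; the inverse-variance-weighted (IVW) estimate pools
the ratios with weights w_j = gamma_j^2 / s_Gamma_j^2, which is identical
to a zero-intercept weighted least-squares regression of Gamma on gamma.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Z95",
    "CohortEffect",
    "MREstimate",
    "MetaResult",
    "ivw",
    "meta_fixed",
    "mr_egger",
    "or_ci_to_log",
    "read_cohort_effects",
    "unweighted_ivw",
    "wald_ratio",
    "weighted_median",
]

#: 97.5% standard-normal quantile used for every CI/SE conversion
Z95 = 1.959964


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate on the log-odds-per-unit-exposure scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    Q: float | None = None
    Q_df: int | None = None
    tag: str | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def to_dict(self) -> dict:
        return {
            "tag": self.tag,
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "odds_ratio": self.odds_ratio,
            "n_snps": self.n_snps,
            "Q": self.Q,
            "Q_df": self.Q_df,
        }


def _estimate(method, beta, se, n_snps, Q=None, Q_df=None, pvalue=None, tag=None):
    beta = float(beta)
    se = float(se)
    if pvalue is None:
        pvalue = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else math.nan
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=float(pvalue),
        n_snps=int(n_snps),
        Q=None if Q is None else float(Q),
        Q_df=None if Q_df is None else int(Q_df),
        tag=tag,
    )


def _arrays(instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pull (gamma, se_gamma, Gamma, se_Gamma) out of a harmonised frame or set."""
    df = getattr(instruments, "instruments", instruments)
    g = np.asarray(df["gamma"], dtype=float)
    sg = np.asarray(df["se_gamma"], dtype=float)
    G = np.asarray(df["beta_out"], dtype=float)
    sG = np.asarray(df["se_out"], dtype=float)
    if g.size == 0:
        raise ValueError("empty instrument set")
    if np.any(sG <= 0) or np.any(sg < 0):
        raise ValueError("standard errors must be positive")
    return g, sg, G, sG


# ---------------------------------------------------------------------------
# per-variant and pooled estimators


def wald_ratio(
    gamma: float, s_gamma: float, Gamma: float, s_Gamma: float, tag: str | None = None
) -> MREstimate:
    """Single-variant causal estimate Gamma/gamma with first-order SE.

    The first-order SE, s_Gamma / |gamma|, ignores uncertainty in gamma,
    which is adequate for strong (high-F) instruments.
    """
    if gamma == 0:
        raise ZeroDivisionError("wald_ratio undefined for gamma = 0")
    beta = Gamma / gamma
    se = s_Gamma / abs(gamma)
    return _estimate("wald_ratio", beta, se, n_snps=1, tag=tag)


def ivw(instruments, effects_model: str = "fixed", tag: str | None = None) -> MREstimate:
    """Inverse-variance-weighted pooling of per-variant Wald ratios.

    Weights are first-order, w_j = gamma_j^2 / s_Gamma_j^2.  Under the
    ``fixed`` effects model se = (sum w)^-1/2; under ``multiplicative``
    the SE is inflated by max(1, sqrt(Q / (n - 1))) so that heterogeneity
    beyond chance widens the interval without moving the point estimate.
    Cochran's Q (df n - 1) is attached for n >= 2.  A single instrument
    reduces exactly to its Wald ratio.
    """
    if effects_model not in ("fixed", "multiplicative"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    g, sg, G, sG = _arrays(instruments)
    n = g.size
    if np.any(g == 0):
        raise ZeroDivisionError("ivw undefined when any gamma = 0")
    method = "ivw_fixed" if effects_model == "fixed" else "ivw_mre"
    if n == 1:
        if effects_model == "multiplicative":
            logger.info("ivw: single instrument, falling back to fixed effects")
        w = wald_ratio(g[0], sg[0], G[0], sG[0])
        return _estimate(method, w.beta, w.se, 1, tag=tag)
    ratios = G / g
    weights = g**2 / sG**2
    beta = float(np.sum(weights * ratios) / np.sum(weights))
    Q = float(np.sum(weights * (ratios - beta) ** 2))
    se = float(np.sum(weights) ** -0.5)
    if effects_model == "multiplicative":
        se *= max(1.0, math.sqrt(Q / (n - 1)))
    return _estimate(method, beta, se, n, Q=Q, Q_df=n - 1, tag=tag)


def unweighted_ivw(instruments, tag: str | None = None) -> MREstimate:
    """Inverse-variance pooling of the SNP-outcome betas alone.

    Ignores the exposure weighting entirely: pools Gamma_j with weights
    1 / s_Gamma_j^2, so the result is per effect allele rather than per
    unit of exposure.
    """
    _, _, G, sG = _arrays(instruments)
    w = 1.0 / sG**2
    beta = float(np.sum(w * G) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    n = G.size
    Q = float(np.sum(w * (G - beta) ** 2)) if n > 1 else None
    return _estimate(
        "unweighted_ivw", beta, se, n, Q=Q, Q_df=n - 1 if n > 1 else None, tag=tag
    )


def mr_egger(instruments, tag: str | None = None) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: weighted regression of Gamma on gamma with intercept.

    Instruments are first re-oriented so every gamma is positive; weights are
    1 / s_Gamma^2.  Coefficient SEs are inflated by max(1, residual scale)
    — underdispersion never tightens them — and p-values use the t
    distribution with n - 2 df.  The intercept estimates the average
    directional pleiotropic effect; the slope is the pleiotropy-adjusted
    causal estimate.
    """
    g, sg, G, sG = _arrays(instruments)
    n = g.size
    if n < 3:
        raise ValueError(f"mr_egger needs >= 3 instruments, got {n}")
    flip = np.sign(g)
    flip[flip == 0] = 1.0
    g, G = g * flip, G * flip
    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=1.0 / sG**2).fit()
    scale = float(fit.scale)  # weighted residual variance, df = n - 2
    infl = max(1.0, math.sqrt(scale))
    se_unit = np.asarray(fit.bse) / math.sqrt(scale)
    se = se_unit * infl
    df = n - 2
    pvals = 2.0 * stats.t.sf(np.abs(fit.params) / se, df=df)
    intercept = _estimate(
        "egger_intercept", fit.params[0], se[0], n, pvalue=pvals[0], tag=tag
    )
    slope = _estimate("egger_slope", fit.params[1], se[1], n, pvalue=pvals[1], tag=tag)
    return slope, intercept


def weighted_median(
    instruments, n_boot: int = 1000, seed: int | None = None, tag: str | None = None
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Ratio estimates are ordered; with normalised IVW weights w'_j the
    cumulative midpoints p_j = sum_{k<j} w'_k + w'_j / 2 define an empirical
    weighted quantile function, and the estimate is its linear interpolation
    at p = 0.5.  Consistent when under half the total weight comes from
    invalid instruments.  The SE is the SD of the estimate over ``n_boot``
    draws of beta_j ~ Normal(beta_j, se_j^2) (weights held fixed).
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    g, sg, G, sG = _arrays(instruments)
    n = g.size
    if n < 3:
        raise ValueError(f"weighted_median needs >= 3 instruments, got {n}")
    ratios = G / g
    se_ratio = sG / np.abs(g)
    weights = g**2 / sG**2

    beta = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios, se_ratio, size=(int(n_boot), n))
    boots = np.array([_weighted_median_point(row, weights) for row in draws])
    se = float(boots.std(ddof=1))
    return _estimate("weighted_median", beta, se, n, tag=tag)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, r))


# ---------------------------------------------------------------------------
# cross-cohort fixed-effects meta-analysis of odds ratios


@dataclass(frozen=True)
class CohortEffect:
    """One cohort's published OR and 95% CI for one outcome."""

    cohort: str
    outcome: str
    or_point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError(
                f"{self.cohort}/{self.outcome}: OR/CI must satisfy "
                "0 < ci_low <= or <= ci_high"
            )


@dataclass(frozen=True)
class MetaResult:
    """Fixed-effects pooling of per-cohort log-ORs."""

    outcome: str
    pooled_or: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    pvalue: float
    weights: dict[str, float] = field(default_factory=dict)
    Q: float = 0.0
    Q_df: int = 0


def or_ci_to_log(effect: CohortEffect) -> tuple[float, float]:
    """Recover (log-OR, SE) from a printed OR with 95% CI.

    beta = ln(OR); se = (ln(ci_high) - ln(ci_low)) / (2 * 1.959964).  A zero
    CI width gives a degenerate (zero) SE and is rejected.
    """
    beta = math.log(effect.or_point)
    se = (math.log(effect.ci_high) - math.log(effect.ci_low)) / (2 * Z95)
    if se <= 0:
        raise ValueError(
            f"{effect.cohort}/{effect.outcome}: degenerate CI gives se <= 0"
        )
    return beta, se


def meta_fixed(effects: Sequence[CohortEffect], outcome: str | None = None) -> MetaResult:
    """Fixed-effects (inverse-variance) meta-analysis of cohort ORs.

    Log-ORs are pooled with weights 1/se^2; pooled se = (sum w)^-1/2 with a
    Wald 95% CI; Cochran's Q measures cross-cohort heterogeneity.
    """
    if len(effects) < 2:
        raise ValueError("meta_fixed needs >= 2 cohort effects")
    betas, ws, labels = [], [], []
    for eff in effects:
        b, s = or_ci_to_log(eff)
        betas.append(b)
        ws.append(1.0 / s**2)
        labels.append(f"{eff.cohort}:{eff.outcome}")
    betas = np.asarray(betas)
    ws = np.asarray(ws)
    beta = float(np.sum(ws * betas) / np.sum(ws))
    se = float(np.sum(ws) ** -0.5)
    Q = float(np.sum(ws * (betas - beta) ** 2))
    pvalue = float(2.0 * stats.norm.sf(abs(beta) / se))
    return MetaResult(
        outcome=outcome or effects[0].outcome,
        pooled_or=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
        beta=beta,
        se=se,
        pvalue=pvalue,
        weights=dict(zip(labels, ws)),
        Q=Q,
        Q_df=len(effects) - 1,
    )


def read_cohort_effects(path) -> list[CohortEffect]:
    """Read a per-cohort OR table (TSV: cohort, outcome, or, ci_low, ci_high)."""
    df = pd.read_csv(path, sep="\t")
    need = {"cohort", "outcome", "or", "ci_low", "ci_high"}
    if not need.issubset(df.columns):
        raise ValueError(f"cohort table needs columns {sorted(need)}")
    return [
        CohortEffect(
            str(row["cohort"]),
            str(row["outcome"]),
            float(row["or"]),
            float(row["ci_low"]),
            float(row["ci_high"]),
        )
        for _, row in df.iterrows()
    ]
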