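"""Robustness suite: radial outlier detection, leave-one-out, single-SNP
Wald ratios, and re-runs under alternative instrument configurations.

The radial view decomposes Cochran's Q into per-variant contributions
q_j = w_j (beta_j - beta_IVW)^2, each approximately chi-square(1) for a
valid instrument; large contributions flag outlying instruments, which are
removed in a single pass and the IVW estimate recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, ivw, unweighted_ivw, wald_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisState",
    "RadialResult",
    "ScenarioResult",
    "leave_one_out",
    "radial_scan",
    "rerun_with_config",
    "single_snp",
]


@dataclass
class RadialResult:
    """Per-variant Q decomposition and the one-pass outlier-removed re-estimate."""

    per_snp: pd.DataFrame  # variant_id, q_contribution, q_pvalue, outlier
    estimate_all: MREstimate
    estimate_outliers_removed: MREstimate | None
    alpha: float
    correction: str

    @property
    def beta_all(self) -> float:
        return self.estimate_all.beta

    @property
    def beta_outliers_removed(self) -> float | None:
        est = self.estimate_outliers_removed
        return None if est is None else est.beta

    @property
    def outliers(self) -> list[str]:
        return list(self.per_snp.loc[self.per_snp["outlier"], "variant_id"])


def radial_scan(
    instruments,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    effects_model: str = "fixed",
) -> RadialResult:
    """Flag outlying instruments by their contribution to Cochran's Q.

    q_j = w_j (beta_j - beta_IVW)^2 with first-order weights, referred to
    chi-square with 1 df.  Outliers are flagged at ``alpha`` (Bonferroni
    alpha/n by default; ``correction="none"`` uses raw alpha).  If any are
    flagged, IVW is recomputed once on the retained variants.  The q_j sum
    exactly to the IVW Q statistic.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    df = getattr(instruments, "instruments", instruments)
    n = len(df)
    if n < 3:
        raise ValueError(f"radial_scan needs >= 3 instruments, got {n}")
    est_all = ivw(df, effects_model=effects_model)
    g = np.asarray(df["gamma"], dtype=float)
    G = np.asarray(df["beta_out"], dtype=float)
    sG = np.asarray(df["se_out"], dtype=float)
    w = g**2 / sG**2
    q = w * (G / g - est_all.beta) ** 2
    q_p = stats.chi2.sf(q, df=1)
    threshold = alpha / n if correction == "bonferroni" else alpha
    outlier = q_p < threshold
    per_snp = pd.DataFrame(
        {
            "variant_id": df["variant_id"].to_numpy(),
            "q_contribution": q,
            "q_pvalue": q_p,
            "outlier": outlier,
        }
    )
    est_removed = None
    if outlier.any() and not outlier.all():
        est_removed = ivw(df.loc[~outlier], effects_model=effects_model)
    return RadialResult(per_snp, est_all, est_removed, alpha, correction)


def leave_one_out(instruments, effects_model: str = "fixed") -> pd.DataFrame:
    """IVW re-estimated with each instrument left out in turn.

    Returns one row per left-out variant (beta, se, 95% CI, p, n_snps).
    With homogeneous instruments every row's CI overlaps the all-SNP CI.
    """
    df = getattr(instruments, "instruments", instruments)
    if len(df) < 2:
        raise ValueError("leave_one_out needs >= 2 instruments")
    rows = []
    for vid in df["variant_id"]:
        est = ivw(df.loc[df["variant_id"] != vid], effects_model=effects_model)
        rows.append(
            {
                "left_out_variant": vid,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "n_snps": est.n_snps,
            }
        )
    return pd.DataFrame(rows)


def single_snp(instruments) -> pd.DataFrame:
    """Per-variant Wald ratios (one row per instrument)."""
    df = getattr(instruments, "instruments", instruments)
    rows = []
    for rec in df.itertuples(index=False):
        est = wald_ratio(rec.gamma, rec.se_gamma, rec.beta_out, rec.se_out)
        rows.append(
            {
                "variant_id": rec.variant_id,
                "beta": est.beta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario re-runs


@dataclass
class AnalysisState:
    """Inputs needed to re-run instrument selection + estimation for one outcome."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: object  # LDMatrix
    region: object  # GeneRegion
    window_bp: int = 300_000
    r2_threshold: float = 0.1
    effects_model: str = "fixed"
    orientation: str = "per_unit_exposure_decrease"
    palindrome_policy: str = "infer_by_freq"
    freq_window: float = 0.08
    alt_exposures: dict[str, pd.DataFrame] = field(default_factory=dict)
    wm_n_boot: int = 1000
    wm_seed: int | None = None


@dataclass
class ScenarioResult:
    name: str
    estimates: list[MREstimate] = field(default_factory=list)
    failed: bool = False
    error: str | None = None


def rerun_with_config(state: AnalysisState, override: dict, name: str | None = None) -> ScenarioResult:
    """Re-run instrument selection and estimation under a named override.

    Recognised override keys: ``window_bp`` (int), ``weight_source`` (name of
    an alternate exposure panel in ``state.alt_exposures``), ``unweighted``
    (bool — pool SNP-outcome betas directly), ``instrument_subset`` (list of
    variant ids).  An override that leaves zero instruments marks the
    scenario failed without raising, so a run over many scenarios continues.
    """
    from .pipeline import build_harmonised_instruments  # lazy: avoids module cycle

    name = name or "+".join(f"{k}={v}" for k, v in override.items()) or "base"
    unknown = set(override) - {"window_bp", "weight_source", "unweighted", "instrument_subset"}
    if unknown:
        raise ValueError(f"unknown override key(s): {sorted(unknown)}")
    try:
        exposure = state.exposure
        if "weight_source" in override:
            exposure = state.alt_exposures[override["weight_source"]]
        harmonised = build_harmonised_instruments(
            exposure,
            state.outcome,
            ld=state.ld,
            region=state.region,
            window_bp=int(override.get("window_bp", state.window_bp)),
            r2_threshold=state.r2_threshold,
            orientation=state.orientation,
            palindrome_policy=state.palindrome_policy,
            freq_window=state.freq_window,
        )
        df = harmonised.instruments
        if "instrument_subset" in override:
            df = df[df["variant_id"].isin(override["instrument_subset"])]
        if len(df) == 0:
            raise ValueError("override produced 0 instruments")
        if override.get("unweighted"):
            estimates = [unweighted_ivw(df, tag=name)]
        elif len(df) == 1:
            r = df.iloc[0]
            estimates = [
                wald_ratio(r["gamma"], r["se_gamma"], r["beta_out"], r["se_out"], tag=name)
            ]
        else:
            estimates = [ivw(df, effects_model=state.effects_model, tag=name)]
        return ScenarioResult(name=name, estimates=estimates)
    except Exception as err:  # scenario failure must not abort the run
        logger.warning("scenario %s failed: %s", name, err)
        return ScenarioResult(name=name, failed=True, error=str(err))
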