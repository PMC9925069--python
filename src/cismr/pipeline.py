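"""Config-driven orchestration: instruments -> harmonisation -> estimators
-> sensitivity -> clustering -> meta-analysis, with tabular reports.

The run matrix (instrument configurations x cohort outcomes) is described
in a YAML file validated against a strict schema; a failing outcome is
reported and skipped rather than aborting the remaining outcomes, and all
stochastic steps take explicit seeds so re-runs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .clustering import build_trait_matrix, cluster_mr, fit_directional_mixture
from .estimators import (
    CohortEffect,
    MREstimate,
    ivw,
    meta_fixed,
    mr_egger,
    read_cohort_effects,
    unweighted_ivw,
    wald_ratio,
    weighted_median,
)
from .instruments import GeneRegion, InstrumentSet, ld_prune, orient_to_blockade, select_cis_window
from .sensitivity import AnalysisState, leave_one_out, radial_scan, rerun_with_config, single_snp
from .sumstats import harmonise, read_ld_matrix, read_sumstats

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ConfigError",
    "ResultsBundle",
    "build_harmonised_instruments",
    "forest_table",
    "format_or_ci",
    "run",
    "validate_config",
]


class ConfigError(ValueError):
    """Aggregated configuration-validation failure."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ExposureCfg(_Strict):
    path: str
    weight_source: str = "primary"


class OutcomeCfg(_Strict):
    cohort: str
    outcome: str
    path: str


class RegionCfg(_Strict):
    name: str
    chrom: str
    start: int
    end: int


class LDCfg(_Strict):
    matrix: str
    ids: str


class WeightedMedianCfg(_Strict):
    enabled: bool = True
    n_boot: int = 1000
    seed: Optional[int] = None


class ScenarioCfg(_Strict):
    name: str
    window_bp: Optional[int] = None
    weight_source: Optional[str] = None
    unweighted: bool = False
    instrument_subset: Optional[list[str]] = None

    def overrides(self) -> dict:
        out: dict = {}
        if self.window_bp is not None:
            out["window_bp"] = self.window_bp
        if self.weight_source is not None:
            out["weight_source"] = self.weight_source
        if self.unweighted:
            out["unweighted"] = True
        if self.instrument_subset is not None:
            out["instrument_subset"] = self.instrument_subset
        return out


class ClusteringCfg(_Strict):
    enabled: bool = False
    K: int = 10
    n_starts: int = 50
    seed: Optional[int] = None
    assign_threshold: float = 0.8
    min_cluster_size: int = 4


class MetaGroupCfg(_Strict):
    name: str
    members: list[tuple[str, str]] = Field(default_factory=list)  # (cohort, outcome)
    table: Optional[str] = None  # per-cohort OR table, pooled as-is


class AnalysisConfig(_Strict):
    exposure: ExposureCfg
    alt_exposures: dict[str, str] = Field(default_factory=dict)
    outcomes: list[OutcomeCfg]
    region: RegionCfg
    ld: LDCfg
    window_bp: int = 300_000
    r2_threshold: float = 0.1
    effects_model: str = "fixed"
    orientation: str = "per_unit_exposure_decrease"
    palindrome_policy: str = "infer_by_freq"
    freq_window: float = 0.08
    weighted_median: Optional[WeightedMedianCfg] = None
    radial_alpha: float = 0.05
    sensitivity: list[ScenarioCfg] = Field(default_factory=list)
    clustering: ClusteringCfg = Field(default_factory=ClusteringCfg)
    meta: list[MetaGroupCfg] = Field(default_factory=list)
    seed: Optional[int] = None

    def gene_region(self) -> GeneRegion:
        r = self.region
        return GeneRegion(r.name, r.chrom, r.start, r.end)


def validate_config(path: str | Path) -> AnalysisConfig:
    """Parse and validate a YAML analysis configuration.

    All violations — schema errors, unknown keys, missing files, meta
    groupings with fewer than two members, stochastic steps without seeds —
    are aggregated into a single :class:`ConfigError` report.
    """
    base = Path(path).parent
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    problems: list[str] = []
    try:
        cfg = AnalysisConfig.model_validate(raw)
    except ValidationError as err:
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"])
            problems.append(f"{loc}: {e['msg']}")
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    for label, p in [
        ("exposure.path", cfg.exposure.path),
        ("ld.matrix", cfg.ld.matrix),
        ("ld.ids", cfg.ld.ids),
        *[(f"alt_exposures.{k}", v) for k, v in cfg.alt_exposures.items()],
        *[(f"outcomes[{o.cohort}:{o.outcome}]", o.path) for o in cfg.outcomes],
        *[(f"meta[{g.name}].table", g.table) for g in cfg.meta if g.table],
    ]:
        if not resolve(p).exists():
            problems.append(f"{label}: file not found: {p}")
    if not cfg.outcomes:
        problems.append("outcomes: at least one outcome is required")
    for g in cfg.meta:
        if g.table is None and len(g.members) < 2:
            problems.append(f"meta[{g.name}]: needs >= 2 members (or a table)")
    if cfg.weighted_median and cfg.weighted_median.enabled and cfg.weighted_median.seed is None:
        problems.append("weighted_median.seed: required when weighted median is enabled")
    if cfg.clustering.enabled and cfg.clustering.seed is None:
        problems.append("clustering.seed: required when clustering is enabled")
    if cfg.effects_model not in ("fixed", "multiplicative"):
        problems.append(f"effects_model: unknown value {cfg.effects_model!r}")
    if cfg.orientation not in ("per_unit_exposure_increase", "per_unit_exposure_decrease"):
        problems.append(f"orientation: unknown value {cfg.orientation!r}")
    for scen in cfg.sensitivity:
        if scen.weight_source and scen.weight_source not in cfg.alt_exposures:
            problems.append(
                f"sensitivity[{scen.name}]: weight_source {scen.weight_source!r} "
                "not among alt_exposures"
            )
    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    logger.info("validated config: %s", cfg.model_dump())
    return cfg


# ---------------------------------------------------------------------------
# the single-outcome engine


def build_harmonised_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld,
    region: GeneRegion,
    window_bp: int = 300_000,
    r2_threshold: float = 0.1,
    orientation: str = "per_unit_exposure_decrease",
    palindrome_policy: str = "infer_by_freq",
    freq_window: float = 0.08,
) -> InstrumentSet:
    """Window -> LD-prune -> harmonise -> orient; the shared selection path."""
    windowed = select_cis_window(exposure, region, window_bp)
    if len(windowed) == 0:
        raise ValueError(f"no exposure variants within {window_bp} bp of {region.name}")
    pruned = ld_prune(windowed, ld, r2_threshold)
    harmonised, exclusions = harmonise(pruned, outcome, palindrome_policy, freq_window)
    iset = InstrumentSet(
        instruments=harmonised,
        window_bp=window_bp,
        r2_threshold=r2_threshold,
        orientation="per_unit_exposure_increase",
    )
    iset.instruments.attrs["exclusions"] = exclusions
    if orientation == "per_unit_exposure_decrease":
        iset = orient_to_blockade(iset)
    return iset


@dataclass
class ResultsBundle:
    """Tabular outputs of one pipeline run."""

    primary: pd.DataFrame
    sensitivity: pd.DataFrame
    clustering: Optional[pd.DataFrame]
    cluster_estimates: Optional[pd.DataFrame]
    meta: pd.DataFrame
    exclusions: pd.DataFrame
    failures: list[str] = dc_field(default_factory=list)
    log_lines: list[str] = dc_field(default_factory=list)
    outcome_order: list[str] = dc_field(default_factory=list)

    @property
    def all_completed(self) -> bool:
        return not self.failures

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format="%.12g")
        self.primary.to_csv(outdir / "primary.tsv", **kw)
        self.sensitivity.to_csv(outdir / "sensitivity.tsv", **kw)
        self.meta.to_csv(outdir / "meta.tsv", **kw)
        self.exclusions.to_csv(outdir / "exclusions.tsv", **kw)
        if self.clustering is not None:
            self.clustering.to_csv(outdir / "clustering.tsv", **kw)
        if self.cluster_estimates is not None:
            self.cluster_estimates.to_csv(outdir / "cluster_mr.tsv", **kw)
        forest_table(self).to_csv(outdir / "forest.tsv", sep="\t", index=False)
        (outdir / "run.log").write_text("\n".join(self.log_lines) + "\n")


def _estimate_row(tag: str, est: MREstimate, extra: dict | None = None) -> dict:
    row = est.to_dict()
    row["tag"] = tag
    row.update(extra or {})
    return row


def run(config: AnalysisConfig, config_dir: str | Path = ".") -> ResultsBundle:
    """Execute the full analysis described by a validated configuration."""
    base = Path(config_dir)

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    log: list[str] = []
    exposure = read_sumstats(resolve(config.exposure.path))
    alt = {k: read_sumstats(resolve(v)) for k, v in config.alt_exposures.items()}
    ld = read_ld_matrix(resolve(config.ld.matrix), resolve(config.ld.ids))
    region = config.gene_region()
    log.append(f"exposure panel: {len(exposure)} variants ({config.exposure.weight_source})")

    primary_rows: list[dict] = []
    sens_rows: list[dict] = []
    excl_rows: list[pd.DataFrame] = []
    failures: list[str] = []
    ivw_by_key: dict[tuple[str, str], MREstimate] = {}
    harmonised_by_key: dict[tuple[str, str], InstrumentSet] = {}
    panels_by_key: dict[tuple[str, str], pd.DataFrame] = {}

    for ocfg in config.outcomes:
        tag = f"{ocfg.cohort}:{ocfg.outcome}"
        try:
            panel = read_sumstats(resolve(ocfg.path))
            panels_by_key[(ocfg.cohort, ocfg.outcome)] = panel
            iset = build_harmonised_instruments(
                exposure,
                panel,
                ld=ld,
                region=region,
                window_bp=config.window_bp,
                r2_threshold=config.r2_threshold,
                orientation=config.orientation,
                palindrome_policy=config.palindrome_policy,
                freq_window=config.freq_window,
            )
            df = iset.instruments
            excl = df.attrs.get("exclusions")
            if excl is not None and len(excl):
                e = excl.copy()
                e.insert(0, "tag", tag)
                excl_rows.append(e)
            n = len(df)
            log.append(f"{tag}: {n} harmonised instruments")
            if n == 0:
                raise ValueError("no instruments after harmonisation")
            harmonised_by_key[(ocfg.cohort, ocfg.outcome)] = iset

            if n == 1:
                r = df.iloc[0]
                est = wald_ratio(r["gamma"], r["se_gamma"], r["beta_out"], r["se_out"], tag=tag)
            else:
                est = ivw(df, effects_model=config.effects_model, tag=tag)
            ivw_by_key[(ocfg.cohort, ocfg.outcome)] = est
            primary_rows.append(_estimate_row(tag, est))
            primary_rows.append(_estimate_row(tag, unweighted_ivw(df, tag=tag)))
            if n >= 3:
                slope, intercept = mr_egger(df, tag=tag)
                primary_rows.append(_estimate_row(tag, slope))
                primary_rows.append(_estimate_row(tag, intercept))
                if config.weighted_median and config.weighted_median.enabled:
                    primary_rows.append(
                        _estimate_row(
                            tag,
                            weighted_median(
                                df,
                                n_boot=config.weighted_median.n_boot,
                                seed=config.weighted_median.seed,
                                tag=tag,
                            ),
                        )
                    )
                rad = radial_scan(df, alpha=config.radial_alpha, effects_model=config.effects_model)
                sens_rows.append(
                    {
                        "tag": tag,
                        "scenario": "radial",
                        "detail": ";".join(rad.outliers) or "no_outliers",
                        "method": "ivw_outliers_removed",
                        "beta": rad.beta_outliers_removed,
                        "se": None
                        if rad.estimate_outliers_removed is None
                        else rad.estimate_outliers_removed.se,
                        "n_snps": None
                        if rad.estimate_outliers_removed is None
                        else rad.estimate_outliers_removed.n_snps,
                    }
                )
            if n >= 2:
                for loo_row in leave_one_out(df, effects_model=config.effects_model).itertuples(
                    index=False
                ):
                    sens_rows.append(
                        {
                            "tag": tag,
                            "scenario": "leave_one_out",
                            "detail": loo_row.left_out_variant,
                            "method": "ivw",
                            "beta": loo_row.beta,
                            "se": loo_row.se,
                            "n_snps": loo_row.n_snps,
                        }
                    )
            for ss in single_snp(df).itertuples(index=False):
                sens_rows.append(
                    {
                        "tag": tag,
                        "scenario": "single_snp",
                        "detail": ss.variant_id,
                        "method": "wald_ratio",
                        "beta": ss.beta,
                        "se": ss.se,
                        "n_snps": 1,
                    }
                )
            state = AnalysisState(
                exposure=exposure,
                outcome=panel,
                ld=ld,
                region=region,
                window_bp=config.window_bp,
                r2_threshold=config.r2_threshold,
                effects_model=config.effects_model,
                orientation=config.orientation,
                palindrome_policy=config.palindrome_policy,
                freq_window=config.freq_window,
                alt_exposures=alt,
            )
            for scen in config.sensitivity:
                res = rerun_with_config(state, scen.overrides(), name=scen.name)
                if res.failed:
                    sens_rows.append(
                        {
                            "tag": tag,
                            "scenario": scen.name,
                            "detail": f"failed: {res.error}",
                            "method": None,
                            "beta": None,
                            "se": None,
                            "n_snps": None,
                        }
                    )
                else:
                    for est_s in res.estimates:
                        sens_rows.append(
                            {
                                "tag": tag,
                                "scenario": scen.name,
                                "detail": "",
                                "method": est_s.method,
                                "beta": est_s.beta,
                                "se": est_s.se,
                                "n_snps": est_s.n_snps,
                            }
                        )
        except Exception as err:
            failures.append(f"{tag}: {err}")
            log.append(f"{tag}: FAILED ({err})")
            continue

    # meta-analysis groupings
    meta_rows: list[dict] = []
    for group in config.meta:
        try:
            if group.table:
                effects = read_cohort_effects(resolve(group.table))
            else:
                effects = []
                for cohort, outcome in group.members:
                    est = ivw_by_key.get((cohort, outcome))
                    if est is None:
                        raise ValueError(f"member {cohort}:{outcome} has no estimate")
                    lo, hi = est.or_ci
                    effects.append(CohortEffect(cohort, outcome, est.odds_ratio, lo, hi))
            pooled = meta_fixed(effects, outcome=group.name)
            meta_rows.append(
                {
                    "group": group.name,
                    "pooled_or": pooled.pooled_or,
                    "ci_low": pooled.ci_low,
                    "ci_high": pooled.ci_high,
                    "beta": pooled.beta,
                    "se": pooled.se,
                    "pvalue": pooled.pvalue,
                    "Q": pooled.Q,
                    "Q_df": pooled.Q_df,
                    "n_cohorts": len(effects),
                }
            )
        except Exception as err:
            failures.append(f"meta[{group.name}]: {err}")
            log.append(f"meta[{group.name}]: FAILED ({err})")

    # clustering across all complete trait panels
    clustering_df = None
    cluster_est_df = None
    if config.clustering.enabled and panels_by_key:
        try:
            windowed = select_cis_window(exposure, region, config.window_bp)
            pruned = ld_prune(windowed, ld, config.r2_threshold)
            panels = {f"{c}:{o}": p for (c, o), p in panels_by_key.items()}
            matrix, dropped = build_trait_matrix(
                pruned,
                panels,
                palindrome_policy=config.palindrome_policy,
                freq_window=config.freq_window,
            )
            log.append(
                f"clustering: {matrix.z.shape[0]} variants x {matrix.z.shape[1]} traits"
                + (f", dropped traits: {dropped}" if dropped else "")
            )
            assignment = fit_directional_mixture(
                matrix,
                K=config.clustering.K,
                n_starts=config.clustering.n_starts,
                seed=config.clustering.seed,
                assign_threshold=config.clustering.assign_threshold,
                min_cluster_size=config.clustering.min_cluster_size,
            )
            clustering_df = assignment.to_frame()
            rows = []
            for key, iset in harmonised_by_key.items():
                tag = f"{key[0]}:{key[1]}"
                for cid in assignment.cluster_ids:
                    est = cluster_mr(iset, assignment, cid, effects_model=config.effects_model)
                    rows.append(_estimate_row(tag, est, {"cluster": cid}))
            cluster_est_df = pd.DataFrame(rows)
            log.append(f"clustering: K_effective={assignment.K_effective}")
        except Exception as err:
            failures.append(f"clustering: {err}")
            log.append(f"clustering: FAILED ({err})")

    bundle = ResultsBundle(
        primary=pd.DataFrame(primary_rows),
        sensitivity=pd.DataFrame(sens_rows),
        clustering=clustering_df,
        cluster_estimates=cluster_est_df,
        meta=pd.DataFrame(meta_rows),
        exclusions=pd.concat(excl_rows, ignore_index=True)
        if excl_rows
        else pd.DataFrame(columns=["tag", "variant_id", "reason"]),
        failures=failures,
        log_lines=log,
        outcome_order=[f"{o.cohort}:{o.outcome}" for o in config.outcomes],
    )
    return bundle


# ---------------------------------------------------------------------------
# reporting


def format_or_ci(or_point: float, ci_low: float, ci_high: float) -> str:
    """Render "OR (low-high)" at two decimals, half-even, trailing zeros trimmed."""

    def fmt(x: float) -> str:
        return f"{round(x, 2):g}"

    return f"{fmt(or_point)} ({fmt(ci_low)}–{fmt(ci_high)})"


def forest_table(bundle: ResultsBundle) -> pd.DataFrame:
    """One formatted row per outcome (primary IVW), in configured block order."""
    rows = []
    if len(bundle.primary):
        prim = bundle.primary[bundle.primary["method"].isin(["ivw_fixed", "ivw_mre", "wald_ratio"])]
        order = {tag: i for i, tag in enumerate(bundle.outcome_order)}
        prim = prim.sort_values("tag", key=lambda s: s.map(lambda t: order.get(t, len(order))))
        for r in prim.itertuples(index=False):
            rows.append(
                {
                    "outcome": r.tag,
                    "or_ci": format_or_ci(
                        np.exp(r.beta), np.exp(r.ci_low), np.exp(r.ci_high)
                    ),
                    "pvalue": r.pvalue,
                    "n_snps": r.n_snps,
                    "beta_raw": r.beta,
                }
            )
    return pd.DataFrame(rows, columns=["outcome", "or_ci", "pvalue", "n_snps", "beta_raw"])
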