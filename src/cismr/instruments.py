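"""Cis instrument construction: window restriction, greedy LD pruning,
instrument strength, and the target-blockade sign convention.

A cis drug-target instrument is a set of variants lying within a window of
the gene encoding the target (here IL6R, CRP or gp130/IL6ST), mutually
independent at an r-squared threshold, weighted by their effect on a
downstream readout (lnCRP).  Estimates are usually reported on the
"blockade" orientation — per unit *decrease* of the exposure — mimicking a
therapeutic antagonist.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .sumstats import LDMatrix

__all__ = [
    "GeneRegion",
    "InstrumentSet",
    "f_statistic",
    "ld_prune",
    "orient_to_blockade",
    "select_cis_window",
]


@dataclass(frozen=True)
class GeneRegion:
    """1-based inclusive genomic span of a gene."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")


@dataclass
class InstrumentSet:
    """A pruned, windowed instrument panel plus the settings that built it.

    ``instruments`` is a harmonised frame (columns ``gamma, se_gamma,
    beta_out, se_out, ...``) or, before harmonisation, an exposure panel.
    """

    instruments: pd.DataFrame
    window_bp: int = 300_000
    r2_threshold: float = 0.1
    weighting: str = "exposure_weighted"
    orientation: str = "per_unit_exposure_increase"

    def __len__(self) -> int:
        return len(self.instruments)


def select_cis_window(
    records: pd.DataFrame, region: GeneRegion, window_bp: int = 300_000
) -> pd.DataFrame:
    """Records on the region's chromosome within ``window_bp`` of the gene span.

    The interval ``[start - window_bp, end + window_bp]`` is closed on both
    ends.  An empty result is allowed.
    """
    lo, hi = region.start - window_bp, region.end + window_bp
    keep = (
        (records["chrom"].astype(str) == str(region.chrom))
        & (records["pos"] >= lo)
        & (records["pos"] <= hi)
    )
    return records.loc[keep].reset_index(drop=True)


def ld_prune(
    records: pd.DataFrame, ld: LDMatrix, r2_threshold: float = 0.1
) -> pd.DataFrame:
    """Greedy LD pruning at ``r2 >= r2_threshold``.

    Repeatedly keep the remaining variant with the smallest exposure p-value
    (ties broken by smaller position, then variant id) and discard all
    remaining variants correlated with it at ``r2 >= r2_threshold``.  The
    canonical ordering makes the output independent of input row order.
    """
    missing = [v for v in records["variant_id"] if v not in ld]
    if missing:
        raise KeyError(f"variants absent from LD matrix: {missing}")
    pcol = "pvalue" if "pvalue" in records.columns else "pvalue_exposure"
    order = records.sort_values(
        [pcol, "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    kept: list[str] = []
    for rec in order.itertuples(index=False):
        vid = rec.variant_id
        if all(ld.r2(vid, k) < r2_threshold for k in kept):
            kept.append(vid)
    out = records[records["variant_id"].isin(kept)]
    return out.sort_values(["pos", "variant_id"], kind="mergesort").reset_index(drop=True)


def f_statistic(beta: float | np.ndarray, se: float | np.ndarray) -> float | np.ndarray:
    """Single-variant instrument strength, (beta / se)^2.

    Invariant under allele reorientation (sign of beta).  Values below ~10
    conventionally indicate a weak instrument.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def orient_to_blockade(instrument_set: InstrumentSet) -> InstrumentSet:
    """Flip the instrument set to the per-unit-exposure-*decrease* orientation.

    Every instrument's exposure beta is negated and its effect/other alleles
    swapped (EAF complemented), so a positive causal estimate downstream
    means "risk rises as the exposure falls" — the drug-blockade reading.
    Applying the operation twice restores the original set.
    """
    df = instrument_set.instruments.copy()
    df["gamma"] = -df["gamma"]
    df[["effect_allele", "other_allele"]] = df[["other_allele", "effect_allele"]]
    if "eaf" in df:
        df["eaf"] = 1.0 - df["eaf"]
    if "eaf_out" in df:
        df["eaf_out"] = 1.0 - df["eaf_out"]
    new_orientation = (
        "per_unit_exposure_decrease"
        if instrument_set.orientation == "per_unit_exposure_increase"
        else "per_unit_exposure_increase"
    )
    return replace(instrument_set, instruments=df, orientation=new_orientation)
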