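"""GWAS summary-statistic I/O, validation, harmonisation and proxy search.

Summary statistics live in pandas DataFrames with canonical columns
(``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
pvalue, n``).  Harmonisation aligns an outcome panel onto the exposure
panel's effect alleles, resolving strand flips and palindromic (A/T, G/C)
ambiguity from allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CANONICAL_FIELDS",
    "DEFAULT_COLUMN_MAP",
    "LDMatrix",
    "SumstatsError",
    "VariantNotInLD",
    "complement_allele",
    "find_proxy",
    "harmonise",
    "is_palindromic",
    "read_ld_matrix",
    "read_sumstats",
    "write_ld_matrix",
    "write_results",
    "write_sumstats",
]

#: canonical field -> default header name in tab-delimited files
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

CANONICAL_FIELDS = tuple(DEFAULT_COLUMN_MAP)

#: fields that must be present and valid for a row to be kept
MANDATORY_FIELDS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsError(ValueError):
    """Malformed or unusable summary-statistics input."""


class VariantNotInLD(KeyError):
    """Requested variant is absent from the LD matrix (distinct from 'no proxy')."""


def complement_allele(allele: str) -> str:
    return _COMPLEMENT[allele]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be resolved from labels."""
    return _COMPLEMENT.get(effect_allele) == other_allele


# ---------------------------------------------------------------------------
# reading / writing panels


def _validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating record invariants; return (valid rows, n dropped)."""
    ok = pd.Series(True, index=df.index)
    for col in MANDATORY_FIELDS:
        ok &= df[col].notna()
    alleles = set(_COMPLEMENT)
    ok &= df["effect_allele"].isin(alleles) & df["other_allele"].isin(alleles)
    ok &= df["effect_allele"] != df["other_allele"]
    ok &= df["se"] > 0
    ok &= (df["pvalue"] > 0) & (df["pvalue"] <= 1)
    # eaf may be missing, but if present must be an open fraction
    has_eaf = df["eaf"].notna()
    ok &= ~has_eaf | ((df["eaf"] > 0) & (df["eaf"] < 1))
    if "n" in df and df["n"].notna().any():
        ok &= df["n"].isna() | (df["n"] > 0)
    dropped = int((~ok).sum())
    return df.loc[ok].reset_index(drop=True), dropped


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics table into canonical columns.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    column_map
        Mapping from canonical field names to header names; merged over
        :data:`DEFAULT_COLUMN_MAP`.

    Rows violating the record invariants (non-ACGT or identical alleles,
    non-positive SE, p outside (0, 1], EAF outside (0, 1)) are dropped with a
    logged count.  A missing mandatory column or zero valid rows is an error.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep)
    missing = [
        cmap[f] for f in MANDATORY_FIELDS + ("se",) if cmap[f] not in raw.columns
    ]
    if missing:
        raise SumstatsError(
            f"{path}: missing mandatory column(s) {sorted(set(missing))}"
        )
    rename = {header: canon for canon, header in cmap.items() if header in raw.columns}
    df = raw.rename(columns=rename)
    for optional in ("eaf", "n"):
        if optional not in df:
            df[optional] = np.nan
    df = df[[c for c in CANONICAL_FIELDS if c in df.columns]]
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df, dropped = _validate_records(df)
    if dropped:
        logger.info("read_sumstats(%s): dropped %d invalid row(s)", path, dropped)
    if df.empty:
        raise SumstatsError(f"{path}: no valid summary-statistic rows")
    df.attrs["n_dropped"] = dropped
    return df


def write_sumstats(
    df: pd.DataFrame, path: str | Path, column_map: Mapping[str, str] | None = None
) -> None:
    """Write canonical records back to the tab-delimited dialect read_sumstats reads."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = df.rename(columns={canon: header for canon, header in cmap.items()})
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_results(results: Iterable, path: str | Path) -> pd.DataFrame:
    """Write a collection of estimates (``MREstimate`` or dicts) to a results TSV.

    One row per estimate; values survive a write/read round trip to at least
    ten significant digits.  Returns the frame that was written.
    """
    rows = []
    for est in results:
        rows.append(est if isinstance(est, dict) else est.to_dict())
    columns = [
        "tag",
        "method",
        "beta",
        "se",
        "ci_low",
        "ci_high",
        "pvalue",
        "odds_ratio",
        "n_snps",
        "Q",
        "Q_df",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return frame


# ---------------------------------------------------------------------------
# harmonisation

#: exclusion reason codes
REASON_UNMATCHED = "absent_from_outcome"
REASON_INCOMPATIBLE = "incompatible_alleles"
REASON_PALINDROME = "ambiguous_palindrome"
REASON_PALINDROME_NOEAF = "missing_eaf_palindrome"

HARMONISED_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "gamma",
    "se_gamma",
    "pvalue_exposure",
    "beta_out",
    "se_out",
    "eaf_out",
    "palindromic",
    "inferred_by_freq",
]


def harmonise(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: str = "infer_by_freq",
    freq_window: float = 0.08,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome associations onto the exposure panel's effect alleles.

    For each variant shared between the panels the outcome beta is re-signed
    so both refer to the exposure record's effect allele; strand flips
    (A<->T, C<->G relabelling) are resolved through allele matching.
    Palindromic variants are handled per ``palindrome_policy``:

    ``infer_by_freq``
        orientation taken from allele frequency, accepted only when both
        panels' EAF lie outside ``0.5 +/- freq_window``; otherwise dropped.
    ``drop``
        all palindromic variants excluded.

    Returns
    -------
    (harmonised, exclusions)
        ``harmonised`` has one row per retained variant with exposure
        ``gamma``/``se_gamma`` and aligned outcome ``beta_out``/``se_out``;
        ``exclusions`` is a frame of ``variant_id, reason`` covering every
        exposure variant not retained, so that
        ``len(harmonised) + len(exclusions) == len(exposure)``.
    """
    if palindrome_policy not in ("infer_by_freq", "drop"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    merged = exposure.merge(
        outcome, on="variant_id", how="left", suffixes=("_exp", "_out"), validate="1:1"
    )
    exclusions: list[tuple[str, str]] = []
    rows: list[dict] = []

    for rec in merged.itertuples(index=False):
        vid = rec.variant_id
        if pd.isna(rec.beta_out):
            exclusions.append((vid, REASON_UNMATCHED))
            continue
        ea_e, oa_e = rec.effect_allele_exp, rec.other_allele_exp
        ea_o, oa_o = rec.effect_allele_out, rec.other_allele_out
        beta_out, eaf_out = rec.beta_out, rec.eaf_out
        palindromic = is_palindromic(ea_e, oa_e)
        inferred = False

        if palindromic:
            # allele labels cannot resolve strand; the pair must at least be
            # the same palindrome (e.g. exposure A/T vs outcome A/T or T/A)
            if {ea_o, oa_o} != {ea_e, oa_e}:
                exclusions.append((vid, REASON_INCOMPATIBLE))
                continue
            if palindrome_policy == "drop":
                exclusions.append((vid, REASON_PALINDROME))
                continue
            eaf_e = rec.eaf_exp
            if pd.isna(eaf_e) or pd.isna(eaf_out):
                exclusions.append((vid, REASON_PALINDROME_NOEAF))
                continue
            if abs(eaf_e - 0.5) <= freq_window or abs(eaf_out - 0.5) <= freq_window:
                exclusions.append((vid, REASON_PALINDROME))
                continue
            # align outcome EAF to the exposure effect allele by label first
            if ea_o != ea_e:
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
            # frequencies on opposite sides of 0.5 indicate opposite strands
            if (eaf_e < 0.5) != (eaf_out < 0.5):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
            inferred = True
        else:
            comp_ea, comp_oa = _COMPLEMENT[ea_o], _COMPLEMENT[oa_o]
            if (ea_o, oa_o) == (ea_e, oa_e) or (comp_ea, comp_oa) == (ea_e, oa_e):
                pass  # already aligned (possibly after strand relabelling)
            elif (oa_o, ea_o) == (ea_e, oa_e) or (comp_oa, comp_ea) == (ea_e, oa_e):
                beta_out = -beta_out
                if not pd.isna(eaf_out):
                    eaf_out = 1.0 - eaf_out
            else:
                exclusions.append((vid, REASON_INCOMPATIBLE))
                continue

        rows.append(
            {
                "variant_id": vid,
                "chrom": rec.chrom_exp,
                "pos": rec.pos_exp,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "eaf": rec.eaf_exp,
                "gamma": rec.beta_exp,
                "se_gamma": rec.se_exp,
                "pvalue_exposure": rec.pvalue_exp,
                "beta_out": beta_out,
                "se_out": rec.se_out,
                "eaf_out": eaf_out,
                "palindromic": palindromic,
                "inferred_by_freq": inferred,
            }
        )

    harmonised = pd.DataFrame(rows, columns=HARMONISED_COLUMNS)
    excl = pd.DataFrame(exclusions, columns=["variant_id", "reason"])
    if len(excl):
        logger.info(
            "harmonise: retained %d, excluded %d (%s)",
            len(harmonised),
            len(excl),
            excl["reason"].value_counts().to_dict(),
        )
    return harmonised, excl


def harmonised_as_outcome(harmonised: pd.DataFrame) -> pd.DataFrame:
    """Re-express a harmonised frame as an outcome panel (for idempotence checks)."""
    return pd.DataFrame(
        {
            "variant_id": harmonised["variant_id"],
            "chrom": harmonised["chrom"],
            "pos": harmonised["pos"],
            "effect_allele": harmonised["effect_allele"],
            "other_allele": harmonised["other_allele"],
            "eaf": harmonised["eaf_out"],
            "beta": harmonised["beta_out"],
            "se": harmonised["se_out"],
            "pvalue": 1.0,
            "n": np.nan,
        }
    )


# ---------------------------------------------------------------------------
# LD matrix and proxy search


@dataclass
class LDMatrix:
    """Square pairwise-correlation matrix with a matching variant-ID index."""

    variant_ids: list[str]
    r: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if self.r.shape != (n, n):
            raise ValueError(
                f"LD matrix shape {self.r.shape} does not match {n} variant ids"
            )
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2(self, a: str, b: str) -> float:
        """Squared correlation between two variants."""
        try:
            ia, ib = self._index[a], self._index[b]
        except KeyError as err:
            raise VariantNotInLD(str(err)) from None
        return float(self.r[ia, ib] ** 2)

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)])


def read_ld_matrix(matrix_path: str | Path, ids_path: str | Path) -> LDMatrix:
    """Read a plain-text square matrix plus a one-ID-per-line index file."""
    ids = [line.strip() for line in Path(ids_path).read_text().splitlines() if line.strip()]
    r = np.loadtxt(matrix_path, ndmin=2)
    return LDMatrix(ids, r)


def write_ld_matrix(ld: LDMatrix, matrix_path: str | Path, ids_path: str | Path) -> None:
    np.savetxt(matrix_path, ld.r, fmt="%.10g")
    Path(ids_path).write_text("\n".join(ld.variant_ids) + "\n")


def find_proxy(
    target: str,
    candidates: pd.DataFrame,
    ld: LDMatrix,
    r2_min: float = 0.8,
) -> str | None:
    """Best available proxy for ``target`` among candidate records.

    Returns the candidate with maximal r-squared against the target, provided
    it reaches ``r2_min``; ties break to the smaller genomic position.  The
    target itself qualifies (r2 = 1) when present among the candidates.
    ``None`` means no candidate qualifies; a target absent from the LD matrix
    raises :class:`VariantNotInLD` instead.
    """
    if target not in ld:
        raise VariantNotInLD(target)
    best: tuple[float, float, str] | None = None  # (-r2, pos, vid) minimised
    for rec in candidates.itertuples(index=False):
        vid = rec.variant_id
        if vid not in ld:
            continue
        r2 = ld.r2(target, vid)
        if r2 < r2_min:
            continue
        key = (-r2, float(rec.pos), vid)
        if best is None or key < best:
            best = key
    return best[2] if best else None
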