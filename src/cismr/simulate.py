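"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the geometry of a cis drug-target MR analysis: a
panel of 26 strong cis variants measured in a large continuous-exposure
GWAS (lnCRP, n ~ 522,681) and a case-control outcome GWAS of biobank scale
(defaults 11,643 cases / 474,841 controls).  Per-variant exposure SEs use
the standard unit-variance-trait approximation
s_gamma = (2 n p (1 - p))^{-1/2}; binary-outcome SEs use the logistic
score approximation s_Gamma = (2 n p (1 - p) phi (1 - phi))^{-1/2} with
phi the case fraction.  True outcome effects satisfy
Gamma_j = beta_causal * gamma_j + alpha_j exactly, with the pleiotropic
alpha_j drawn from a configurable model (none / balanced / directional /
correlated-with-gamma, the last violating InSIDE-style independence).

A master seed fans out to per-component substreams, so panels are
byte-reproducible and modules can be tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import TraitMatrix
from .sumstats import LDMatrix

__all__ = [
    "Pleiotropy",
    "SimScenario",
    "cis_instrument_fixture",
    "il6r_region",
    "simulate_ld",
    "simulate_trait_matrix",
    "simulate_two_sample",
]

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class Pleiotropy:
    """Pleiotropy model for the direct SNP-outcome effects alpha_j.

    ``none``: alpha = 0.  ``balanced``: alpha ~ N(0, tau^2).
    ``directional``: alpha ~ N(mu, tau^2) *per exposure-increasing allele*
    (the stored alpha_j carries sign(gamma_j), so the Egger intercept on
    positively-oriented instruments targets mu).  ``correlated``:
    alpha = delta * gamma + N(0, tau^2), correlating instrument strength
    with pleiotropy and violating InSIDE-style independence.

    ``frac`` is the fraction of variants carrying the pleiotropic effect
    (the rest stay valid instruments); with frac < 0.5 under equal weights
    the weighted median retains its consistency guarantee.
    """

    kind: str = "none"
    mu: float = 0.0
    tau: float = 0.0
    delta: float = 0.0
    frac: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional", "correlated"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if not (0.0 <= self.frac <= 1.0):
            raise ValueError("frac must lie in [0, 1]")


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one simulated two-sample dataset.

    Defaults mirror the geometry of a biobank-scale sepsis analysis:
    26 cis SNPs, a 522,681-sample exposure GWAS and an outcome GWAS with
    11,643 cases against 474,841 controls.
    """

    n_snps: int = 26
    maf_range: tuple[float, float] = (0.05, 0.45)
    exposure_n: int = 522_681
    outcome_n_cases: int = 11_643
    outcome_n_controls: int = 474_841
    beta_causal: float = 0.0
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    gamma_range: tuple[float, float] = (0.02, 0.08)
    palindromic_fraction: float = 0.15
    strand_flip_fraction: float = 0.3
    allele_swap_fraction: float = 0.3
    ld_blocks: tuple[tuple[int, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high < 0.5")
        if min(self.n_snps, self.exposure_n, self.outcome_n_cases, self.outcome_n_controls) <= 0:
            raise ValueError("counts must be positive")


def _allele_pairs(n: int, palindromic_fraction: float, rng: np.random.Generator):
    pal = rng.random(n) < palindromic_fraction
    eas, oas = [], []
    for is_pal in pal:
        pool = _PALINDROMIC_PAIRS if is_pal else _NONPALINDROMIC_PAIRS
        ea, oa = pool[rng.integers(len(pool))]
        eas.append(ea)
        oas.append(oa)
    return np.array(eas), np.array(oas), pal


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def simulate_two_sample(
    s: SimScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (exposure panel, outcome panel, truth ledger) for a scenario.

    The outcome panel re-expresses a configurable fraction of records on the
    flipped strand and/or with swapped effect/other alleles, so downstream
    harmonisation is exercised; the truth ledger records the per-SNP
    gamma_j, alpha_j and Gamma_j = beta_causal * gamma_j + alpha_j on the
    exposure panel's orientation.
    """
    streams = [
        np.random.default_rng(child)
        for child in np.random.SeedSequence(s.seed).spawn(6)
    ]
    rng_struct, rng_truth, rng_exp, rng_out, rng_alle, rng_plei = streams

    maf = rng_struct.uniform(*s.maf_range, size=s.n_snps)
    pos = np.sort(rng_struct.integers(1_000_000, 1_600_000, size=s.n_snps))
    variant_ids = [f"rs9{i:05d}" for i in range(1, s.n_snps + 1)]

    sign = rng_truth.choice([-1.0, 1.0], size=s.n_snps)
    gamma = sign * rng_truth.uniform(*s.gamma_range, size=s.n_snps)
    carrier = rng_plei.random(s.n_snps) < s.pleiotropy.frac
    if s.pleiotropy.kind == "none":
        alpha = np.zeros(s.n_snps)
    elif s.pleiotropy.kind == "balanced":
        alpha = rng_plei.normal(0.0, s.pleiotropy.tau, size=s.n_snps)
    elif s.pleiotropy.kind == "directional":
        # directional per unit of the exposure-raising allele: carrying the
        # sign of gamma keeps the direction coherent after re-orientation
        alpha = np.sign(gamma) * rng_plei.normal(
            s.pleiotropy.mu, s.pleiotropy.tau, size=s.n_snps
        )
    else:  # correlated
        alpha = s.pleiotropy.delta * gamma + rng_plei.normal(
            0.0, s.pleiotropy.tau, size=s.n_snps
        )
    alpha = np.where(carrier, alpha, 0.0)
    Gamma = s.beta_causal * gamma + alpha

    se_gamma = (2.0 * s.exposure_n * maf * (1.0 - maf)) ** -0.5
    n_eff = s.outcome_n_cases + s.outcome_n_controls
    phi = s.outcome_n_cases / n_eff
    se_Gamma = (2.0 * n_eff * maf * (1.0 - maf) * phi * (1.0 - phi)) ** -0.5

    gamma_hat = gamma + rng_exp.normal(0.0, se_gamma)
    Gamma_hat = Gamma + rng_out.normal(0.0, se_Gamma)

    ea, oa, palindromic = _allele_pairs(s.n_snps, s.palindromic_fraction, rng_alle)

    def panel(beta, se, n, eaf):
        p = 2.0 * stats.norm.sf(np.abs(beta) / se)
        return pd.DataFrame(
            {
                "variant_id": variant_ids,
                "chrom": "1",
                "pos": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pvalue": np.clip(p, 1e-300, 1.0),
                "n": n,
            }
        )

    exposure = panel(gamma_hat, se_gamma, s.exposure_n, maf)
    outcome = panel(Gamma_hat, se_Gamma, n_eff, maf)

    # disguise the outcome panel: strand flips and allele swaps
    flip = rng_alle.random(s.n_snps) < s.strand_flip_fraction
    swap = rng_alle.random(s.n_snps) < s.allele_swap_fraction
    ea_o = outcome["effect_allele"].to_numpy(copy=True)
    oa_o = outcome["other_allele"].to_numpy(copy=True)
    flip_idx = np.where(flip & ~palindromic)[0]  # flipping palindromes is a no-op pair
    ea_o[flip_idx] = [_COMP[a] for a in ea_o[flip_idx]]
    oa_o[flip_idx] = [_COMP[a] for a in oa_o[flip_idx]]
    swap_idx = np.where(swap)[0]
    ea_o[swap_idx], oa_o[swap_idx] = oa_o[swap_idx].copy(), ea_o[swap_idx].copy()
    outcome.loc[swap_idx, "beta"] = -outcome.loc[swap_idx, "beta"]
    outcome.loc[swap_idx, "eaf"] = 1.0 - outcome.loc[swap_idx, "eaf"]
    outcome["effect_allele"] = ea_o
    outcome["other_allele"] = oa_o

    truth = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "gamma_true": gamma,
            "alpha": alpha,
            "Gamma_true": Gamma,
            "maf": maf,
            "se_gamma": se_gamma,
            "se_Gamma": se_Gamma,
        }
    )
    truth.attrs["scenario"] = s
    return exposure, outcome, truth


def simulate_ld(
    blocks: list[tuple[int, float]], variant_ids: list[str] | None = None
) -> LDMatrix:
    """Block-diagonal AR(1)-style LD: within a block, r(i, j) = rho^|i-j|.

    Positive-definite for |rho| < 1; blocks are mutually independent.
    """
    mats = []
    for size, rho in blocks:
        if size < 1:
            raise ValueError("block size must be >= 1")
        if abs(rho) >= 1:
            raise ValueError("|rho| must be < 1")
        idx = np.arange(size)
        mats.append(rho ** np.abs(idx[:, None] - idx[None, :]))
    n = sum(size for size, _ in blocks)
    r = np.zeros((n, n))
    start = 0
    for m in mats:
        k = m.shape[0]
        r[start : start + k, start : start + k] = m
        start += k
    if variant_ids is None:
        variant_ids = [f"v{i + 1}" for i in range(n)]
    if len(variant_ids) != n:
        raise ValueError("variant_ids length must match total block size")
    return LDMatrix(list(variant_ids), r)


def simulate_trait_matrix(
    n_traits: int,
    clusters: list[tuple[int, float]],
    n_noise: int,
    seed: int,
    directions: np.ndarray | None = None,
    scale_range: tuple[float, float] = (1.0, 10.0),
) -> tuple[TraitMatrix, np.ndarray]:
    """Planted-partition trait matrix for clustering recovery tests.

    ``clusters`` is a list of (size, concentration); each cluster's rows are
    von Mises-Fisher draws about a random unit direction, noise rows are
    uniform on the sphere, and every row is rescaled by a random positive
    magnitude (the fit must be invariant to this).  Returns the matrix and
    the true labels (1..K for clusters, 0 for noise).
    """
    rng = np.random.default_rng(seed)
    T = n_traits
    if directions is None:
        directions = rng.normal(size=(len(clusters), T))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    rows, labels = [], []
    for k, (size, kappa) in enumerate(clusters, start=1):
        if np.isinf(kappa):
            draws = np.tile(directions[k - 1], (size, 1))
        else:
            draws = stats.vonmises_fisher(directions[k - 1], kappa).rvs(
                size, random_state=rng
            )
        rows.append(np.atleast_2d(draws))
        labels.extend([k] * size)
    if n_noise:
        noise = rng.normal(size=(n_noise, T))
        noise /= np.linalg.norm(noise, axis=1, keepdims=True)
        rows.append(noise)
        labels.extend([0] * n_noise)
    z = np.vstack(rows)
    z *= rng.uniform(*scale_range, size=(z.shape[0], 1))
    ids = [f"rs8{i:05d}" for i in range(1, z.shape[0] + 1)]
    return TraitMatrix(ids, [f"trait_{t + 1}" for t in range(T)], z), np.array(labels)


# ---------------------------------------------------------------------------
# study-shaped cis instrument fixture


def il6r_region():
    """IL6R gene span (GRCh37 chr1 coordinates)."""
    from .instruments import GeneRegion

    return GeneRegion(name="IL6R", chrom="1", start=154_377_669, end=154_441_926)


def cis_instrument_fixture() -> tuple[pd.DataFrame, LDMatrix]:
    """Deterministic 26-variant cis exposure panel echoing the study geometry.

    Synthetic stand-in for the real instrument list: 26 lnCRP-weighted
    variants within 300 kb of IL6R, of which exactly seven (including
    rs2228145) lie within 10 kb of the gene span; the weakest variant has
    beta -0.0558, se 0.01, i.e. the minimum F statistic of 31.1.  Betas are
    on the exposure-increasing orientation.  Pairwise LD is below r2 = 0.1
    so the panel survives pruning intact.
    """
    region = il6r_region()
    rng = np.random.default_rng(20230130)
    n = 26
    # seven positions inside [start - 10kb, end + 10kb], the rest spread to 300 kb
    near_pos = np.array(
        [
            region.start - 9_500,
            region.start - 1_200,
            region.start + 20_000,
            region.start + 49_301,  # rs2228145 (Asp358Ala)
            region.end - 3_000,
            region.end + 4_200,
            region.end + 9_800,
        ]
    )
    far_left = rng.integers(region.start - 300_000, region.start - 10_001, size=10)
    far_right = rng.integers(region.end + 10_001, region.end + 300_000, size=9)
    pos = np.concatenate([near_pos, np.sort(far_left), np.sort(far_right)])
    ids = ["rs2228145" if p == region.start + 49_301 else f"rs11{i:04d}" for i, p in enumerate(pos)]
    maf = rng.uniform(0.08, 0.45, size=n)
    beta = -rng.uniform(0.06, 0.13, size=n)  # lnCRP per effect allele
    se = np.full(n, 0.01)
    beta[ids.index("rs2228145")] = -0.12  # strongest, canonical functional variant
    weakest = int(np.argmax(beta))  # least-negative effect
    beta[weakest] = -0.0558  # F = 31.1 at se 0.01
    pvalue = 2.0 * stats.norm.sf(np.abs(beta) / se)
    panel = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": region.chrom,
            "pos": pos,
            "effect_allele": "C",
            "other_allele": "A",
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pvalue": np.clip(pvalue, 1e-300, 1.0),
            "n": 522_681,
        }
    )
    panel = panel.sort_values("pos").reset_index(drop=True)
    # mutually independent panel: weak residual correlations, all r2 < 0.1
    r = np.eye(n)
    off = rng.uniform(-0.25, 0.25, size=(n, n))
    off = (off + off.T) / 2
    np.fill_diagonal(off, 0.0)
    r = r + off
    # shrink to guarantee positive-definiteness and the r2 bound
    evals = np.linalg.eigvalsh(r)
    if evals.min() < 0.05:
        shrink = 0.9 * 1.0 / (1.0 - evals.min())
        r = np.eye(n) + shrink * off
    d = np.sqrt(np.diag(r))
    r = r / d[:, None] / d[None, :]
    ld = LDMatrix(list(panel["variant_id"]), r)
    return panel, ld
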