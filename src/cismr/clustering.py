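"""Noise-augmented directional clustering of multi-trait SNP profiles.

Each instrument's standardised associations (z = beta/se) across T traits
form a vector whose *direction* captures its pattern of effects.  Rows are
scaled to unit length and modelled as a mixture of K von Mises-Fisher
components (mean direction mu_k, concentration kappa_k) plus one uniform
"noise" component on the sphere that absorbs variants with no shared
direction.  The mixture is fitted by expectation-maximisation with an exact
M-step for kappa, so the log-likelihood is non-decreasing across
iterations; the best of several seeded restarts (spherical k-means++
initialisation) is kept.

Hard labels use a posterior-probability threshold, and clusters retaining
fewer than ``min_cluster_size`` assigned variants are dissolved into noise
— small chance alignments of unclustered variants are not reported as
structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .estimators import MREstimate, ivw
from .sumstats import harmonise

logger = logging.getLogger(__name__)

__all__ = [
    "NOISE_LABEL",
    "ClusterAssignment",
    "TraitMatrix",
    "build_trait_matrix",
    "cluster_mr",
    "fit_directional_mixture",
]

#: hard label assigned to the noise class
NOISE_LABEL = 0


@dataclass
class TraitMatrix:
    """J x T matrix of standardised SNP-trait associations.

    Rows are oriented to the exposure-increasing allele; no missing cells
    (traits lacking any instrument are dropped upstream).
    """

    variant_ids: list[str]
    trait_names: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.variant_ids), len(self.trait_names)):
            raise ValueError("z shape does not match variant/trait lists")
        if np.isnan(self.z).any():
            raise ValueError("trait matrix must have no missing cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.variant_ids, columns=self.trait_names)


def build_trait_matrix(
    exposure: pd.DataFrame,
    panels: dict[str, pd.DataFrame],
    instrument_ids: list[str] | None = None,
    palindrome_policy: str = "infer_by_freq",
    freq_window: float = 0.08,
) -> tuple[TraitMatrix, list[str]]:
    """Assemble the standardised SNP x trait matrix for clustering.

    Each trait panel is harmonised onto the exposure panel; traits missing
    any instrument are dropped (and returned in the second element).  Rows
    are signed to the exposure-increasing allele, so two variants with
    concordant trait effects per unit of exposure point the same way.
    """
    exp = exposure if instrument_ids is None else exposure[
        exposure["variant_id"].isin(instrument_ids)
    ]
    exp = exp.reset_index(drop=True)
    ids = list(exp["variant_id"])
    orient = np.sign(exp["beta"].to_numpy(dtype=float))
    orient[orient == 0] = 1.0
    columns: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for trait, panel in panels.items():
        harm, _ = harmonise(exp, panel, palindrome_policy, freq_window)
        if len(harm) < len(exp):
            dropped.append(trait)
            logger.info(
                "build_trait_matrix: trait %s dropped (%d/%d instruments)",
                trait,
                len(harm),
                len(exp),
            )
            continue
        harm = harm.set_index("variant_id").loc[ids]
        columns[trait] = (
            harm["beta_out"].to_numpy() / harm["se_out"].to_numpy()
        ) * orient
    if len(columns) < 2:
        raise ValueError(
            f"only {len(columns)} trait(s) have complete instrument coverage; >= 2 required"
        )
    z = np.column_stack([columns[t] for t in columns])
    return TraitMatrix(ids, list(columns), z), dropped


# ---------------------------------------------------------------------------
# von Mises-Fisher mixture with a uniform noise class


def _log_sphere_area(d: int) -> float:
    """log surface area of the unit sphere S^{d-1}."""
    return math.log(2.0) + (d / 2.0) * math.log(math.pi) - special.gammaln(d / 2.0)


def _log_vmf_const(d: int, kappa: float) -> float:
    """log normalising constant of the vMF density on S^{d-1}."""
    if kappa < 1e-10:
        return -_log_sphere_area(d)
    nu = d / 2.0 - 1.0
    log_iv = math.log(special.ive(nu, kappa)) + kappa
    return nu * math.log(kappa) - (d / 2.0) * math.log(2.0 * math.pi) - log_iv


def _mean_resultant(d: int, kappa: float) -> float:
    """A_d(kappa) = I_{d/2}(kappa) / I_{d/2-1}(kappa), the expected resultant length."""
    if kappa < 1e-10:
        return 0.0
    return special.ive(d / 2.0, kappa) / special.ive(d / 2.0 - 1.0, kappa)


def _solve_kappa(rbar: float, d: int, kappa_min: float, kappa_max: float) -> float:
    """Exact ML concentration: solve A_d(kappa) = rbar, clipped to bounds."""
    if rbar <= _mean_resultant(d, kappa_min):
        return kappa_min
    if rbar >= _mean_resultant(d, kappa_max):
        return kappa_max
    return float(
        optimize.brentq(
            lambda k: _mean_resultant(d, k) - rbar, kappa_min, kappa_max, xtol=1e-10
        )
    )


def _log_densities(X: np.ndarray, mus: np.ndarray, kappas: np.ndarray) -> np.ndarray:
    """J x (K+1) log densities: K vMF components then the uniform noise class."""
    J, d = X.shape
    K = mus.shape[0]
    out = np.empty((J, K + 1))
    for k in range(K):
        out[:, k] = _log_vmf_const(d, kappas[k]) + kappas[k] * (X @ mus[k])
    out[:, K] = -_log_sphere_area(d)
    return out


def _mixture_ll(X, mus, kappas, pis) -> float:
    log_dens = _log_densities(X, mus, kappas)
    with np.errstate(divide="ignore"):
        log_joint = log_dens + np.where(pis > 0, np.log(np.where(pis > 0, pis, 1.0)), -np.inf)
    return float(special.logsumexp(log_joint, axis=1).sum())


def _posteriors(X, mus, kappas, pis) -> np.ndarray:
    log_dens = _log_densities(X, mus, kappas)
    with np.errstate(divide="ignore"):
        log_joint = log_dens + np.where(pis > 0, np.log(np.where(pis > 0, pis, 1.0)), -np.inf)
    log_joint -= special.logsumexp(log_joint, axis=1, keepdims=True)
    return np.exp(log_joint)


def _merge_duplicates(X, mus, kappas, pis, kappa_min, kappa_max):
    """Greedy BIC-guided merging of near-duplicate components.

    Maximum likelihood always prefers splitting one concentrated bundle into
    overlapping fragments; merging the most-aligned pair whenever the merge
    costs less likelihood than one component's BIC penalty undoes that.
    """
    J, d = X.shape
    K = mus.shape[0]
    mus, kappas, pis = mus.copy(), kappas.copy(), pis.copy()
    penalty = (d + 1) * math.log(J)
    while True:
        active = np.flatnonzero(pis[:K] > 1e-8)
        if len(active) < 2:
            return mus, kappas, pis
        cos = mus[active] @ mus[active].T
        iu = np.triu_indices(len(active), k=1)
        if iu[0].size == 0:
            return mus, kappas, pis
        best_pair = np.argmax(cos[iu])
        i, j = active[iu[0][best_pair]], active[iu[1][best_pair]]
        ll_cur = _mixture_ll(X, mus, kappas, pis)
        resp = _posteriors(X, mus, kappas, pis)
        r = (resp[:, i] + resp[:, j]) @ X
        Nk = resp[:, i].sum() + resp[:, j].sum()
        mus_new, kappas_new, pis_new = mus.copy(), kappas.copy(), pis.copy()
        rnorm = np.linalg.norm(r)
        if rnorm <= 1e-12 or Nk <= 1e-12:
            return mus, kappas, pis
        mus_new[i] = r / rnorm
        kappas_new[i] = _solve_kappa(
            min(rnorm / Nk, 1.0 - 1e-12), d, kappa_min, kappa_max
        )
        pis_new[i] = pis[i] + pis[j]
        pis_new[j] = 0.0
        ll_new = _mixture_ll(X, mus_new, kappas_new, pis_new)
        if 2.0 * (ll_cur - ll_new) < penalty:
            mus, kappas, pis = mus_new, kappas_new, pis_new
        else:
            return mus, kappas, pis


def _null_concentration_quantile(
    J: int,
    d: int,
    K: int,
    min_size: int,
    rng: np.random.Generator,
    kappa_min: float,
    kappa_max: float,
    n_rep: int = 150,
    q: float = 0.98,
) -> float:
    """Chance-alignment reference for cluster retention.

    For isotropic data of the same shape (J rows on S^{d-1}), run the same
    mixture search (several short EM restarts, keeping the tightest group
    found) and record the largest Rayleigh-type statistic m * d * rbar^2
    over hard-assigned groups of at least ``min_size``; return its ``q``
    quantile.  A reported cluster must beat what pure noise produces under
    the same selection pressure.
    """
    stats = np.zeros(n_rep)
    for rep in range(n_rep):
        Xn = rng.normal(size=(J, d))
        Xn /= np.linalg.norm(Xn, axis=1, keepdims=True)
        best = 0.0
        for _ in range(2):  # restarts explore the data's tightest subsets
            fit = _em_fit(
                Xn, K, rng, max_iter=50, tol=1e-6, kappa_min=kappa_min, kappa_max=kappa_max
            )
            assign = np.argmax(fit["resp"], axis=1)  # K = noise column
            for k in range(K):
                members = Xn[assign == k]
                m = len(members)
                if m < min_size:
                    continue
                rbar = np.linalg.norm(members.sum(axis=0)) / m
                best = max(best, m * d * rbar**2)
        stats[rep] = best
    return float(np.quantile(stats, q))


@dataclass
class ClusterAssignment:
    """Fitted mixture and per-variant assignments.

    ``labels[j]`` is the hard label: 1..K for clusters, 0 for noise
    (:data:`NOISE_LABEL`).  ``probabilities`` is J x (K+1); columns 0..K-1
    are the clusters, column K the noise class; rows sum to one.
    """

    variant_ids: list[str]
    labels: np.ndarray
    probabilities: np.ndarray
    means: np.ndarray  # K x T unit vectors
    kappas: np.ndarray
    weights: np.ndarray  # K+1 mixing proportions (last = noise)
    K_effective: int
    loglik: float
    ll_trace: np.ndarray
    converged: bool
    assign_threshold: float
    min_cluster_size: int

    def members(self, cluster_id: int) -> list[str]:
        return [v for v, lab in zip(self.variant_ids, self.labels) if lab == cluster_id]

    @property
    def cluster_ids(self) -> list[int]:
        return sorted({int(lab) for lab in self.labels if lab != NOISE_LABEL})

    def to_frame(self) -> pd.DataFrame:
        K = self.means.shape[0]
        out = pd.DataFrame({"variant_id": self.variant_ids, "label": self.labels})
        for k in range(K):
            out[f"prob_cluster_{k + 1}"] = self.probabilities[:, k]
        out["prob_noise"] = self.probabilities[:, K]
        return out


def _spherical_kmeanspp(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding + a few Lloyd rounds with cosine distance.

    Returns the centre directions actually supported (possibly fewer than K
    when the data collapse onto fewer distinct directions).
    """
    J = X.shape[0]
    centres = [X[rng.integers(J)]]
    for _ in range(1, K):
        cos = X @ np.array(centres).T
        d2 = np.maximum(0.0, 2.0 - 2.0 * cos.max(axis=1))
        total = d2.sum()
        if total <= 1e-12:
            break
        centres.append(X[rng.choice(J, p=d2 / total)])
    C = np.array(centres)
    for _ in range(10):
        assign = np.argmax(X @ C.T, axis=1)
        newC = []
        for k in range(C.shape[0]):
            members = X[assign == k]
            if len(members) == 0:
                continue
            m = members.sum(axis=0)
            norm = np.linalg.norm(m)
            newC.append(m / norm if norm > 1e-12 else members[0])
        C = np.array(newC)
    return C


def _em_fit(
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    kappa_min: float,
    kappa_max: float,
):
    J, d = X.shape
    C = _spherical_kmeanspp(X, K, rng)
    # a mixture component must be supported by at least two variants:
    # singleton seeds would collapse into degenerate high-concentration
    # spikes on single rows, which the noise class should absorb instead
    assign = np.argmax(X @ C.T, axis=1)
    counts = np.bincount(assign, minlength=C.shape[0])
    keep = counts >= 2
    if not keep.any():
        keep[np.argmax(counts)] = True
    C = C[keep]
    k_init = C.shape[0]
    assign = np.argmax(X @ C.T, axis=1)
    counts = np.bincount(assign, minlength=k_init).astype(float)

    mus = np.zeros((K, d))
    mus[:, 0] = 1.0
    mus[:k_init] = C
    kappas = np.full(K, max(kappa_min, 1.0))
    for k in range(k_init):
        members = X[assign == k]
        if len(members) >= 2:
            rbar = min(np.linalg.norm(members.mean(axis=0)), 1.0 - 1e-9)
            kappas[k] = _solve_kappa(rbar, d, kappa_min, kappa_max)
    pis = np.zeros(K + 1)
    noise_w0 = 0.1
    pis[:k_init] = (1.0 - noise_w0) * counts / counts.sum()
    pis[K] = noise_w0

    log_noise = -_log_sphere_area(d)
    ll_prev = -np.inf
    trace = []
    converged = False
    for _ in range(max_iter):
        # E-step
        log_dens = np.empty((J, K + 1))
        for k in range(K):
            if pis[k] <= 0:
                log_dens[:, k] = -np.inf
                continue
            log_dens[:, k] = _log_vmf_const(d, kappas[k]) + kappas[k] * (X @ mus[k])
        log_dens[:, K] = log_noise
        with np.errstate(divide="ignore"):
            log_joint = log_dens + np.log(np.where(pis > 0, pis, 1.0)) + np.where(
                pis > 0, 0.0, -np.inf
            )
        row_max = log_joint.max(axis=1, keepdims=True)
        resp = np.exp(log_joint - row_max)
        norm = resp.sum(axis=1, keepdims=True)
        resp /= norm
        ll = float(np.sum(row_max.ravel() + np.log(norm.ravel())))
        trace.append(ll)
        if ll - ll_prev < tol * (1.0 + abs(ll)) and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
        # M-step (exact per-component ML, so the likelihood cannot decrease)
        Nk = resp.sum(axis=0)
        pis = Nk / J
        for k in range(K):
            if Nk[k] < 1e-12:
                pis[k] = 0.0
                continue
            r = resp[:, k] @ X
            rnorm = np.linalg.norm(r)
            if rnorm > 1e-12:
                mus[k] = r / rnorm
            rbar = min(rnorm / Nk[k], 1.0 - 1e-12)
            kappas[k] = _solve_kappa(rbar, d, kappa_min, kappa_max)
    n_active = int(np.sum(pis[:K] > 1e-8))
    # BIC over the active components (direction d-1, concentration, weight):
    # used only to rank restarts, where raw likelihood would always prefer
    # the degenerate splitting of one concentrated bundle into near-duplicate
    # high-kappa fragments
    bic = -2.0 * trace[-1] + n_active * (d + 1) * math.log(J)
    return dict(
        mus=mus,
        kappas=kappas,
        pis=pis,
        resp=resp,
        loglik=trace[-1],
        bic=bic,
        n_active=n_active,
        trace=np.asarray(trace),
        converged=converged,
    )


def fit_directional_mixture(
    m: TraitMatrix,
    K: int = 10,
    n_starts: int = 50,
    seed: int | None = None,
    assign_threshold: float = 0.8,
    max_iter: int = 500,
    tol: float = 1e-8,
    kappa_min: float = 1e-3,
    kappa_max: float = 1e4,
    min_cluster_size: int = 4,
) -> ClusterAssignment:
    """Fit the K-component directional mixture plus noise class by EM.

    Rows of ``m.z`` are scaled to unit length (the fit is invariant to
    positive per-row rescaling).  ``n_starts`` seeded restarts are run and
    ranked by BIC over the populated components (raw likelihood always
    prefers degenerate splits of one concentrated bundle into near-duplicate
    fragments; the penalty breaks that tie while K itself stays fixed).  Variants whose top cluster posterior falls
    below ``assign_threshold``, and members of clusters retaining fewer than
    ``min_cluster_size`` variants, are labelled noise.  ``K_effective``
    counts the clusters that keep at least one member.  Non-convergence
    within ``max_iter`` returns the best iterate with ``converged=False``.
    """
    if seed is None:
        raise ValueError("fit_directional_mixture requires an explicit seed")
    if K < 1:
        raise ValueError("K must be >= 1")
    J = m.z.shape[0]
    if J < K:
        raise ValueError(f"need at least K={K} rows, got {J}")
    norms = np.linalg.norm(m.z, axis=1)
    if np.any(norms <= 0):
        raise ValueError("zero-length rows cannot be normalised")
    X = m.z / norms[:, None]
    # canonical content-based row order makes the seeded restarts, and hence
    # the labels, exactly invariant to the input row permutation
    order = np.lexsort(X.T)
    inverse = np.empty_like(order)
    inverse[order] = np.arange(J)
    X = X[order]

    seeds = np.random.SeedSequence(seed).spawn(n_starts + 1)
    best = None
    for child in seeds[:n_starts]:
        fit = _em_fit(
            X, K, np.random.default_rng(child), max_iter, tol, kappa_min, kappa_max
        )
        if best is None or fit["bic"] < best["bic"]:
            best = fit
    if not best["converged"]:
        logger.warning("fit_directional_mixture: best restart did not converge")

    mus, kappas, pis = _merge_duplicates(
        X, best["mus"], best["kappas"], best["pis"], kappa_min, kappa_max
    )
    probs = _posteriors(X, mus, kappas, pis)
    labels = np.argmax(probs, axis=1) + 1  # 1..K clusters, K+1 = noise
    labels[labels == K + 1] = NOISE_LABEL
    top = probs[np.arange(J), np.argmax(probs, axis=1)]
    labels[(labels != NOISE_LABEL) & (top < assign_threshold)] = NOISE_LABEL
    # dissolve clusters too small to count as structure
    for k in range(1, K + 1):
        if 0 < np.sum(labels == k) < min_cluster_size:
            labels[labels == k] = NOISE_LABEL
    # retain only clusters tighter than chance alignments of isotropic rows
    d = X.shape[1]
    null_rng = np.random.default_rng(seeds[n_starts])
    null_stat = _null_concentration_quantile(
        J, d, K, max(2, min_cluster_size), null_rng, kappa_min, kappa_max
    )
    for k in sorted({int(lab) for lab in labels if lab != NOISE_LABEL}):
        members = X[labels == k]
        size = len(members)
        rbar = np.linalg.norm(members.sum(axis=0)) / size
        if size * d * rbar**2 <= null_stat:
            labels[labels == k] = NOISE_LABEL
    K_effective = len({int(lab) for lab in labels if lab != NOISE_LABEL})

    return ClusterAssignment(
        variant_ids=list(m.variant_ids),
        labels=labels[inverse],
        probabilities=probs[inverse],
        means=mus,
        kappas=kappas,
        weights=pis,
        K_effective=K_effective,
        loglik=_mixture_ll(X, mus, kappas, pis),
        ll_trace=best["trace"],
        converged=bool(best["converged"]),
        assign_threshold=assign_threshold,
        min_cluster_size=min_cluster_size,
    )


def cluster_mr(
    instruments,
    assignment: ClusterAssignment,
    cluster_id: int,
    effects_model: str = "fixed",
) -> MREstimate:
    """IVW estimate restricted to one cluster's variants."""
    members = assignment.members(cluster_id)
    if not members:
        raise ValueError(f"cluster {cluster_id} is empty")
    df = getattr(instruments, "instruments", instruments)
    sub = df[df["variant_id"].isin(members)]
    if len(sub) == 0:
        raise ValueError(
            f"cluster {cluster_id} members not present in the instrument set"
        )
    return ivw(sub, effects_model=effects_model, tag=f"cluster_{cluster_id}(n={len(sub)})")
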