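"""Maximum-likelihood ancestry proportions under the admixture model.

Each individual i carries ancestry fractions q_ik over K ancestral
populations with allele frequencies p_kj; its genotype at marker j is
binomial(2, sum_k q_ik p_kj).  The log-likelihood

    sum_ij [ g_ij log f_ij + (2 - g_ij) log (1 - f_ij) ],  f = Q P

is maximised by EM from a seeded random start (monotone by construction).
Initialisation and cross-validation masks are keyed by sample/marker *ids*,
so results are invariant to the storage order of samples.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .dataset import MISSING, GenotypeDataset

_P_CLIP = 1e-6


@dataclass
class AncestryFit:
    K: int
    Q: np.ndarray          # samples x K, rows on the simplex
    P: np.ndarray          # K x markers, entries in [1e-6, 1 - 1e-6]
    loglik: float
    iterations: int
    seed: int
    samples: list[str] = field(default_factory=list)
    loglik_path: np.ndarray | None = None


def _rng(seed: int, *keys) -> np.random.Generator:
    h = zlib.crc32("|".join(map(str, keys)).encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, h])


def _init(ds: GenotypeDataset, K: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    Q = np.vstack(
        [_rng(seed, "q", s).dirichlet(np.ones(K)) for s in ds.samples]
    )
    P = np.vstack(
        [_rng(seed, "p", k).uniform(0.05, 0.95, ds.n_markers) for k in range(K)]
    )
    return Q, P


def _loglik(G, miss, Q, P) -> float:
    F = np.clip(Q @ P, _P_CLIP, 1 - _P_CLIP)
    ll = np.where(miss, 0.0, G * np.log(F) + (2.0 - G) * np.log1p(-F))
    return float(ll.sum())


def _em_once(
    ds: GenotypeDataset, K: int, seed: int, max_iter: int, tol: float
) -> AncestryFit:
    G = ds.genotypes.astype(float)
    miss = ds.genotypes == MISSING
    G[miss] = 0.0
    G2 = np.where(miss, 0.0, 2.0 - G)
    J = (~miss).sum(axis=1).astype(float)  # non-missing markers per sample
    if np.any(J == 0):
        raise ValueError("a sample has no called genotypes")

    Q, P = _init(ds, K, seed)
    ll_prev = -np.inf
    path = []
    for it in range(1, max_iter + 1):
        F = np.clip(Q @ P, _P_CLIP, 1 - _P_CLIP)
        GoF = G / F
        G2oF = G2 / (1.0 - F)
        # E-step sums (all use the current Q, P)
        A = Q * (GoF @ P.T)            # N x K: expected alt copies by ancestry
        B = Q * (G2oF @ (1.0 - P).T)   # N x K: expected ref copies by ancestry
        a_sum = P * (Q.T @ GoF)        # K x M: sum_i a_ijk
        b_sum = (1.0 - P) * (Q.T @ G2oF)
        # M-step
        Q = (A + B) / (2.0 * J)[:, None]
        Q = np.clip(Q, 0.0, None)
        Q /= Q.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = a_sum / np.maximum(a_sum + b_sum, 1e-300)
        P = np.clip(P, _P_CLIP, 1.0 - _P_CLIP)

        ll = _loglik(G, miss, Q, P)
        path.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev):
            ll_prev = ll
            break
        ll_prev = ll
    return AncestryFit(K, Q, P, ll_prev, it, seed, list(ds.samples),
                       np.asarray(path))


def fit_ancestry(
    ds: GenotypeDataset,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    restarts: int = 5,
) -> AncestryFit:
    """Fit ancestry fractions Q and ancestral frequencies P for K ancestries.

    Runs ``restarts`` seeded EM starts and keeps the best log-likelihood
    (local optima are a real hazard of this likelihood).  ``K=1`` has the
    closed form Q = 1, P = sample allele frequencies, which EM reaches in one
    step.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > ds.n_samples:
        raise ValueError(f"K={K} exceeds the sample count {ds.n_samples}")
    best: AncestryFit | None = None
    for r in range(max(1, restarts)):
        fit = _em_once(ds, K, seed + 1000 * r, max_iter, tol)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def _fold_of(seed: int, folds: int, sid: str, mid: str) -> int:
    return zlib.crc32(f"{seed}|{sid}|{mid}".encode()) % folds


def cv_error(
    ds: GenotypeDataset,
    K: int,
    folds: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> float:
    """Cross-validated genotype prediction error for model selection over K.

    Non-missing entries are split into ``folds`` disjoint sets keyed by
    (sample id, marker id); each fold is masked in turn, the model refitted,
    and the mean squared error between held-out dosages and their fitted
    expectation 2 sum_k q_ik p_kj recorded.  Lower is better; the K
    minimising this error is the supported number of ancestries.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    miss = ds.genotypes == MISSING
    fold_mat = np.empty(ds.genotypes.shape, dtype=np.int32)
    for i, sid in enumerate(ds.samples):
        for j, mid in enumerate(ds.markers["id"]):
            fold_mat[i, j] = _fold_of(seed, folds, sid, mid)
    fit_kwargs.setdefault("restarts", 1)

    errors = []
    for f in range(folds):
        held = (~miss) & (fold_mat == f)
        if not held.any():
            raise ValueError(f"fold {f} holds out no entries")
        g_masked = ds.genotypes.copy()
        g_masked[held] = MISSING
        ds_f = GenotypeDataset(list(ds.samples), ds.markers.copy(), g_masked)
        fit = fit_ancestry(ds_f, K, seed=seed + f, **fit_kwargs)
        pred = 2.0 * (fit.Q @ fit.P)
        resid = ds.genotypes[held].astype(float) - pred[held]
        errors.append(float(np.mean(resid**2)))
    return float(np.mean(errors))


def filter_by_ancestry(
    ds: GenotypeDataset,
    fit: AncestryFit,
    component: int,
    max_fraction: float = 0.05,
) -> GenotypeDataset:
    """Drop samples whose fitted ancestry on ``component`` exceeds
    ``max_fraction``.

    Used to clean reference panels before f-statistics: e.g. keeping only
    wild-boar individuals with under 5% of the domestic-side ancestry at
    K=2 so the reference is unadmixed.
    """
    keep = [
        i for i, s in enumerate(fit.samples)
        if fit.Q[i, component] <= max_fraction
    ]
    if not keep:
        raise ValueError("ancestry filter removed every sample")
    kept_ids = [fit.samples[i] for i in keep]
    return ds.select_samples([s for s in ds.samples if s in set(kept_ids)])
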