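"""Drift-normalised principal component analysis of genotypes.

Each marker column is centred at twice its sample allele frequency and
scaled by sqrt(p~ (1 - p~)) with p~ the shrunken frequency
(alt copies + 1) / (2 n + 2) — the normalisation under which each marker's
variance is proportional to its drift, so components reflect population
structure rather than allele-frequency magnitude.  Missing entries are
mean-imputed (zero after centring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import MISSING, GenotypeDataset


@dataclass
class PcaResult:
    coordinates: np.ndarray        # samples x components
    variance_fraction: np.ndarray  # per reported component
    component_count: int
    loadings: np.ndarray           # markers x components, orthonormal columns
    eigenvalues: np.ndarray        # all eigenvalues of the sample covariance


def normalised_matrix(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Return (normalised matrix, polymorphic-column mask)."""
    g = ds.genotypes.astype(float)
    miss = g == MISSING
    g[miss] = np.nan
    n_called = (~miss).sum(axis=0)
    alt = np.nansum(g, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_called)
        p_shrunk = (alt + 1.0) / (2.0 * n_called + 2.0)
    poly = (n_called > 0) & (p > 0) & (p < 1)
    x = g - 2.0 * p
    x[miss] = 0.0
    with np.errstate(invalid="ignore"):
        x /= np.sqrt(p_shrunk * (1.0 - p_shrunk))
    return x[:, poly], poly


def run_pca(ds: GenotypeDataset, n_components: int = 10) -> PcaResult:
    """Top principal components of the drift-normalised genotype matrix.

    Coordinates are the sample projections on the top eigenvectors of the
    sample covariance; ``variance_fraction[i]`` is eigenvalue i over the sum
    of all eigenvalues.  Component sign is fixed by making each component's
    largest-magnitude marker loading positive.
    """
    if ds.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x, poly = normalised_matrix(ds)
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 polymorphic markers")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / x.shape[1]  # eigenvalues of (1/m) X X^T
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = rank

    coords = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(n_components):
        col = loadings[:, k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            loadings[:, k] = -col
            coords[:, k] = -coords[:, k]
    frac = eigvals[:n_components] / eigvals.sum()
    return PcaResult(coords, frac, n_components, loadings, eigvals)
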