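"""Population-structure PCA of genotypes and of normalized CNV depth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnv import CnvRegion, NormalizedDepthMatrix
from .differentiation import _region_values
from .genotypes import MISSING, GenotypeMatrix


@dataclass
class PcaResult:
    """Sample scores, per-component variance fractions, and loadings."""

    samples: list[str]
    scores: np.ndarray             # (n_samples, n_components)
    variance_fraction: np.ndarray  # non-increasing, sums to <= 1
    loadings: np.ndarray           # (n_features, n_components)


def _pca(X: np.ndarray, n_components: int, samples: list[str]) -> PcaResult:
    """PCA of a centered feature matrix with a deterministic sign convention
    (the largest-magnitude loading on each component is positive)."""
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(S))
    total = np.sum(S**2)
    frac = (S[:k] ** 2 / total) if total > 0 else np.zeros(k)
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return PcaResult(
        samples=list(samples),
        scores=scores,
        variance_fraction=frac,
        loadings=loadings,
    )


def genotype_pca(gm: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of per-SNP standardized genotypes.

    Monomorphic sites are dropped; missing genotypes are mean-imputed; each
    SNP is centered and scaled to unit variance (sqrt(p(1-p)) scaling).
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    poly = gm.is_polymorphic()
    if not poly.any():
        raise ValueError("all sites monomorphic")
    g = gm.geno[:, poly].astype(float)
    g[g == MISSING] = np.nan
    mu = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), mu, g)
    p_hat = mu / 2.0
    sd = np.sqrt(p_hat * (1 - p_hat))
    X = (g - mu) / np.where(sd > 0, sd, 1.0)
    return _pca(X, n_components, gm.samples)


def depth_pca(
    ndm: NormalizedDepthMatrix,
    regions: list[CnvRegion],
    n_components: int = 10,
) -> PcaResult:
    """PCA of region-level normalized read depth restricted to CNV loci."""
    if not regions:
        raise ValueError("no CNV regions supplied")
    X = np.column_stack([_region_values(ndm, r) for r in regions])
    return _pca(X, n_components, ndm.samples)
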