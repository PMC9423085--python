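"""CNV-gene intersection and functional-category enrichment.

Enrichment compares observed category counts of an affected gene set with
the genome-wide category composition via a chi-square statistic whose null
distribution is built by Monte-Carlo resampling of equally sized random
gene sets (uniform, without replacement).  Genes may carry several category
labels; both observed and null sets contribute one count per (gene, label),
keeping the two comparable, and unlabeled genes count under "Not assigned".
The one-sided p-value uses the +1 correction, p = (1 + #{null >= obs}) /
(n_simulations + 1), so it can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import NOT_ASSIGNED, GeneAnnotation
from .cnv import CnvRegion
from .genotypes import PopulationMap


def genes_in_cnv_regions(
    regions: list[CnvRegion],
    annotation: GeneAnnotation,
    popmap: PopulationMap,
    min_cluster_freq: float = 0.20,
) -> tuple[dict[str, set[str]], set[str]]:
    """Per-cluster CNV-affected gene sets at a carrier-frequency threshold.

    A gene counts as affected in a cluster iff some CNV region whose
    carrier frequency in that cluster is strictly greater than
    ``min_cluster_freq`` overlaps it (half-open).  The unthresholded global
    affected set (any region, any carrier) is returned alongside.
    """
    clusters = popmap.clusters()
    sizes = popmap.cluster_sizes()
    members = {cl: set(popmap.samples_in(cl)) for cl in clusters}
    per_cluster: dict[str, set[str]] = {cl: set() for cl in clusters}
    global_set: set[str] = set()
    for r in regions:
        genes = annotation.genes_overlapping(r.chrom, r.start, r.end)
        if not genes:
            continue
        if r.carriers:
            global_set.update(genes)
        for cl in clusters:
            freq = len(r.carriers & members[cl]) / sizes[cl]
            if freq > min_cluster_freq:
                per_cluster[cl].update(genes)
    return per_cluster, global_set


@dataclass
class EnrichmentResult:
    observed: pd.DataFrame   # category, observed, expected, residual, direction
    chi2: float
    p_value: float
    n_simulations: int
    seed: int


def _category_matrix(annotation: GeneAnnotation) -> tuple[list[str], np.ndarray]:
    """(categories, genes x categories 0/1 label matrix); unlabeled genes
    get the "Not assigned" column."""
    vocab = annotation.category_vocabulary()
    if NOT_ASSIGNED not in vocab:
        vocab = vocab + [NOT_ASSIGNED]
    col = {c: k for k, c in enumerate(vocab)}
    M = np.zeros((len(annotation), len(vocab)), dtype=np.int8)
    for i, cats in enumerate(annotation.table["categories"]):
        if cats:
            for c in cats:
                M[i, col[c]] = 1
        else:
            M[i, col[NOT_ASSIGNED]] = 1
    return vocab, M


def _chi2_stat(obs: np.ndarray, background_frac: np.ndarray) -> float:
    total = obs.sum()
    exp = background_frac * total
    ok = exp > 0
    return float(np.sum((obs[ok] - exp[ok]) ** 2 / exp[ok]))


def _null_chi2(
    M: np.ndarray,
    background_frac: np.ndarray,
    n_draw: int,
    n_simulations: int,
    rng: np.random.Generator,
    chunk: int = 1000,
) -> np.ndarray:
    """Chi-square statistics of uniformly resampled gene sets (vectorized)."""
    n_genes = M.shape[0]
    Mf = M.astype(np.float64)
    out = np.empty(n_simulations)
    done = 0
    while done < n_simulations:
        m = min(chunk, n_simulations - done)
        keys = rng.random((m, n_genes))
        draws = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
        null_obs = Mf[draws].sum(axis=1)  # (m, n_categories)
        totals = null_obs.sum(axis=1, keepdims=True)
        exp = background_frac[None, :] * totals
        ok = background_frac > 0
        out[done : done + m] = np.sum(
            (null_obs[:, ok] - exp[:, ok]) ** 2 / exp[:, ok], axis=1
        )
        done += m
    return out


def category_enrichment(
    gene_set: set[str],
    annotation: GeneAnnotation,
    n_simulations: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Monte-Carlo chi-square test of category composition of a gene set
    against the genome-wide background."""
    if not gene_set:
        raise ValueError("gene_set is empty")
    if n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    vocab, M = _category_matrix(annotation)
    ids = annotation.gene_ids
    index = {g: i for i, g in enumerate(ids)}
    try:
        rows = np.array([index[g] for g in sorted(gene_set)])
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} not in annotation") from None
    background = M.sum(axis=0).astype(float)
    background_frac = background / background.sum()
    obs = M[rows].sum(axis=0).astype(float)
    stat = _chi2_stat(obs, background_frac)
    rng = np.random.default_rng(seed)
    null = _null_chi2(M, background_frac, len(rows), n_simulations, rng)
    p = (1 + int(np.sum(null >= stat))) / (n_simulations + 1)
    exp = background_frac * obs.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        residual = np.where(exp > 0, (obs - exp) / np.sqrt(exp), 0.0)
    direction = np.where(residual > 2, "over", np.where(residual < -2, "under", "ns"))
    table = pd.DataFrame(
        {
            "category": vocab,
            "observed": obs,
            "expected": exp,
            "residual": residual,
            "direction": direction,
        }
    )
    return EnrichmentResult(
        observed=table, chi2=stat, p_value=p, n_simulations=n_simulations, seed=seed
    )


@dataclass
class OverlapResult:
    observed: int
    expected: float
    p_value: float
    n_simulations: int
    seed: int


def resistance_overlap(
    affected_genes: set[str],
    annotation: GeneAnnotation,
    n_simulations: int = 10_000,
    seed: int = 0,
) -> OverlapResult:
    """One-sided Monte-Carlo test of disease-resistance-gene overlap with a
    CNV-affected gene set (null: uniform gene resampling)."""
    res = annotation.resistance_genes()
    if not res:
        raise ValueError("annotation has no resistance genes")
    ids = annotation.gene_ids
    res_mask = np.array([g in res for g in ids])
    observed = len(affected_genes & res)
    n_draw = len(affected_genes)
    expected = n_draw * res_mask.mean()
    if n_draw == 0:
        return OverlapResult(0, 0.0, 1.0, n_simulations, seed)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_simulations)
    done = 0
    while done < n_simulations:
        m = min(1000, n_simulations - done)
        keys = rng.random((m, len(ids)))
        draws = np.argpartition(keys, n_draw - 1, axis=1)[:, :n_draw]
        counts[done : done + m] = res_mask[draws].sum(axis=1)
        done += m
    p = (1 + int(np.sum(counts >= observed))) / (n_simulations + 1)
    return OverlapResult(observed, float(expected), p, n_simulations, seed)
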