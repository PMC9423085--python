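"""Selection scans: windowed Tajima's D, H12 haplotype homozygosity with
peak finding, a PCA-based outlier SNP scan, and the multi-method gene-level
consensus.

Tajima's D per 100-kb nonoverlapping window uses the standard constants
a1, a2, b1, b2, c1, c2, e1, e2 with D = (pi - theta_W) / sqrt(e1*S +
e2*S*(S-1)).

H12 sums haplotype frequencies with the top two classes pooled,
H12 = (p1 + p2)^2 + sum_{i>2} p_i^2, over sliding windows of a fixed SNP
count.  Because the panel is a highly selfing diploid, samples are reduced
to pseudo-haplotypes from their homozygous calls; heterozygous calls are
treated as missing, haplotypes with too much missingness in a window are
dropped, and remaining gaps are filled with the window's major allele.

The outlier scan regresses standardized genotypes on the top principal
components of the sample covariance, converts each SNP's component-wise
z-statistics to a Mahalanobis distance (robust covariance), rescales by a
genomic inflation factor so the null median matches chi^2 with K degrees of
freedom, and flags SNPs by Benjamini-Hochberg-adjusted p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneAnnotation
from .differentiation import WindowStat, _tile_windows
from .genotypes import MISSING, GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# Tajima's D

def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "e1": e1, "e2": e2}


def tajimas_d(alt_counts: np.ndarray, allele_numbers: np.ndarray) -> float:
    """Tajima's D for one window given per-site alt counts / chromosome
    numbers.  The constants use the rounded mean number of non-missing
    chromosomes; pi handles per-site totals exactly."""
    k = np.asarray(alt_counts, dtype=float)
    m = np.asarray(allele_numbers, dtype=float)
    seg = (k > 0) & (k < m)
    k, m = k[seg], m[seg]
    S = len(k)
    if S < 3:
        return float("nan")
    n = int(round(m.mean()))
    if n < 4:
        return float("nan")
    pi = float(np.sum(2.0 * k * (m - k) / (m * (m - 1))))
    const = _tajima_constants(n)
    theta_w = S / const["a1"]
    var = const["e1"] * S + const["e2"] * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi - theta_w) / float(np.sqrt(var))


def tajimas_d_windows(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    cluster: str,
    window: int = 100_000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Tajima's D in nonoverlapping windows for one cluster's samples.

    Windows with fewer than 3 segregating sites are flagged missing (NaN).
    """
    members = popmap.samples_in(cluster)
    if len(members) < 4:
        raise ValueError("cluster needs >= 4 samples for Tajima's D")
    sub = gm.take_samples(members)
    ac = sub.alt_counts()
    an = sub.allele_numbers()
    chroms = sub.sites["chrom"].to_numpy()
    pos0 = sub.sites["pos"].to_numpy() - 1
    out: list[WindowStat] = []
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        p = pos0[sel]
        end = chrom_sizes[chrom] if chrom_sizes else int(p.max()) + 1
        for ws, we in _tile_windows(end, window, window):
            in_w = (p >= ws) & (p < we)
            k, m = ac[sel][in_w], an[sel][in_w]
            seg = int(np.sum((k > 0) & (k < m)))
            out.append(WindowStat(str(chrom), ws, we, seg, tajimas_d(k, m)))
    return out


# ---------------------------------------------------------------------------
# H12

@dataclass
class H12Window:
    chrom: str
    center_index: int      # index of the window's center SNP on its chromosome
    center_bp: int
    span: tuple[int, int]  # first/last SNP bp in the window
    frequencies: np.ndarray  # haplotype frequency spectrum, descending
    h12: float
    n_haplotypes: int      # haplotypes retained after missingness pruning


def h12_from_frequencies(freqs: np.ndarray) -> float:
    """H12 = (p1 + p2)^2 + sum_{i>2} p_i^2 from a descending spectrum."""
    p = np.sort(np.asarray(freqs, dtype=float))[::-1]
    if len(p) == 0:
        return float("nan")
    top = p[0] + (p[1] if len(p) > 1 else 0.0)
    return float(top**2 + np.sum(p[2:] ** 2))


def _pseudo_haplotypes(
    geno: np.ndarray, max_missing_frac: float = 0.20
) -> list[np.ndarray] | None:
    """Selfing-panel haplotypes from homozygous dosages for one window.

    0 -> ref allele, 2 -> alt allele, 1 (het) and -1 -> missing; samples
    with more than ``max_missing_frac`` missing in the window are dropped,
    the rest have gaps filled with the window's major allele.
    """
    hap = np.full(geno.shape, -1, dtype=np.int8)
    hap[geno == 0] = 0
    hap[geno == 2] = 1
    miss = (hap == -1).mean(axis=1)
    hap = hap[miss <= max_missing_frac]
    if hap.shape[0] == 0:
        return None
    # major allele per SNP among retained haplotypes
    ones = (hap == 1).sum(axis=0)
    zeros = (hap == 0).sum(axis=0)
    major = (ones > zeros).astype(np.int8)
    fill = np.broadcast_to(major, hap.shape)
    hap = np.where(hap == -1, fill, hap)
    return [hap[i] for i in range(hap.shape[0])]


def h12_scan(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    max_missing_frac: float = 0.20,
) -> list[H12Window]:
    """Sliding-window H12 over pseudo-haplotypes (window in SNPs, not bp)."""
    chroms = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    out: list[H12Window] = []
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < window_snps:
            warnings.warn(
                f"chromosome {chrom} has {len(idx)} SNPs < window of "
                f"{window_snps}; skipped",
                stacklevel=2,
            )
            continue
        for w0 in range(0, len(idx) - window_snps + 1, step_snps):
            cols = idx[w0 : w0 + window_snps]
            haps = _pseudo_haplotypes(gm.geno[:, cols], max_missing_frac)
            if haps is None:
                continue
            counts: dict[bytes, int] = {}
            for h in haps:
                key = h.tobytes()
                counts[key] = counts.get(key, 0) + 1
            freqs = np.array(sorted(counts.values(), reverse=True), dtype=float)
            freqs /= freqs.sum()
            center = w0 + window_snps // 2
            out.append(
                H12Window(
                    chrom=str(chrom),
                    center_index=center,
                    center_bp=int(pos[idx[center]]),
                    span=(int(pos[cols[0]]), int(pos[cols[-1]])),
                    frequencies=freqs,
                    h12=h12_from_frequencies(freqs),
                    n_haplotypes=len(haps),
                )
            )
    return out


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    max_h12: float
    rank: int


def find_peaks(
    track: list[H12Window],
    top_k: int = 5,
    min_length_bp: int = 150_000,
    threshold: float | None = None,
) -> list[Peak]:
    """Top-k H12 peaks per chromosome, discarding short ones.

    Contiguous runs of windows with H12 above the threshold (default: track
    median + 2 x MAD) form candidate peaks spanning from the first window's
    first SNP to the last window's last SNP; peaks spanning <=
    ``min_length_bp`` are discarded, the rest ranked by max H12 (ties to
    the leftmost start) and the top_k kept per chromosome.
    """
    if not track:
        return []
    values = np.array([w.h12 for w in track])
    if threshold is None:
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        threshold = med + 2.0 * mad
    out: list[Peak] = []
    chroms = [w.chrom for w in track]
    for chrom in dict.fromkeys(chroms):
        wins = [w for w in track if w.chrom == chrom]
        wins.sort(key=lambda w: w.center_bp)
        candidates: list[Peak] = []
        run: list[H12Window] = []
        for w in wins + [None]:
            if w is not None and w.h12 > threshold:
                run.append(w)
                continue
            if run:
                start = run[0].span[0]
                end = run[-1].span[1]
                if end - start > min_length_bp:
                    candidates.append(
                        Peak(chrom, start, end, max(x.h12 for x in run), rank=0)
                    )
                run = []
        candidates.sort(key=lambda p: (-p.max_h12, p.start))
        for rank, p in enumerate(candidates[:top_k], start=1):
            p.rank = rank
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# PCA outlier scan

@dataclass
class OutlierSet:
    """Flagged items from one selection method."""

    method: str
    table: pd.DataFrame  # chrom, pos, score, p, p_adj, flagged
    alpha: float

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table.loc[self.table["flagged"]]


def pca_outlier_scan(
    gm: GenotypeMatrix,
    n_pcs: int = 5,
    alpha: float = 0.01,
    robust: bool = True,
) -> OutlierSet:
    """Flag SNPs whose loadings on the population-structure PCs are
    Mahalanobis outliers (chi^2 with n_pcs df after genomic-inflation
    rescaling; Benjamini-Hochberg at ``alpha``)."""
    from statsmodels.stats.multitest import multipletests

    if n_pcs < 1 or n_pcs >= gm.n_samples:
        raise ValueError("need 1 <= n_pcs < n_samples")
    g = gm.geno.astype(float)
    g[g == MISSING] = np.nan
    poly = gm.is_polymorphic()
    keep = np.flatnonzero(poly)
    g = g[:, keep]
    sites = gm.sites.iloc[keep].reset_index(drop=True)
    # mean-impute and standardize
    mu = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), mu, g)
    p_hat = mu / 2.0
    sd = np.sqrt(p_hat * (1 - p_hat))
    X = (g - mu) / np.where(sd > 0, sd, 1.0)
    # sample scores: left singular vectors
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_pcs]  # orthonormal columns
    # per-SNP regression of standardized genotype on the PC scores
    beta = scores.T @ X  # (K, n_snps); scores orthonormal => OLS coefficients
    resid = X - scores @ beta
    dof = max(gm.n_samples - n_pcs - 1, 1)
    sigma = np.sqrt(np.sum(resid**2, axis=0) / dof)
    sigma[sigma == 0] = np.inf  # SNP perfectly explained: zero z-statistics
    zstat = beta / sigma  # (K, n_snps)
    Z = zstat.T
    if robust and Z.shape[0] > 10 * n_pcs:
        from sklearn.covariance import MinCovDet

        cov = MinCovDet(random_state=0).fit(Z).covariance_
    elif Z.shape[0] > n_pcs + 1:
        cov = np.atleast_2d(np.cov(Z, rowvar=False))
    else:
        cov = np.eye(n_pcs)  # too few SNPs to estimate a covariance
    center = np.zeros(n_pcs)
    dist = _mahalanobis_sq(Z, center, cov)
    # genomic inflation factor: median distance vs chi2 median
    lam = np.median(dist) / stats.chi2.median(df=n_pcs)
    if lam <= 0 or not np.isfinite(lam):
        lam = 1.0
    pvals = stats.chi2.sf(dist / lam, df=n_pcs)
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    table = sites[["chrom", "pos"]].copy()
    table["score"] = dist / lam
    table["p"] = pvals
    table["p_adj"] = p_adj
    table["flagged"] = p_adj < alpha
    return OutlierSet(method="pca_outlier", table=table, alpha=alpha)


def _mahalanobis_sq(Z: np.ndarray, center: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = Z - center
    cov_inv = np.linalg.pinv(cov)
    return np.einsum("ij,jk,ik->i", d, cov_inv, d)


# ---------------------------------------------------------------------------
# gene mapping and consensus

def regions_to_genes(
    intervals: list[tuple[str, int, int]] | None,
    annotation: GeneAnnotation,
    snp_hits: pd.DataFrame | None = None,
    flank_bp: int = 0,
) -> set[str]:
    """Genes overlapping peak intervals (half-open) or containing flagged
    SNPs; ``flank_bp`` widens intervals/points symmetrically."""
    genes: set[str] = set()
    if intervals:
        for chrom, start, end in intervals:
            genes.update(
                annotation.genes_overlapping(chrom, start - flank_bp, end + flank_bp)
            )
    if snp_hits is not None:
        for _, row in snp_hits.iterrows():
            p0 = int(row["pos"]) - 1
            genes.update(
                annotation.genes_overlapping(row["chrom"], p0 - flank_bp, p0 + 1 + flank_bp)
            )
    return genes


@dataclass
class ConsensusReport:
    candidates: set[str]
    per_method: dict[str, int]
    per_intersection: dict[tuple[str, ...], int]


def consensus_candidates(
    method_gene_sets: dict[str, set[str]], min_methods: int = 2
) -> ConsensusReport:
    """Genes detected by at least ``min_methods`` of the supplied methods
    (one of which may be an externally produced outlier gene list)."""
    if min_methods > len(method_gene_sets):
        raise ValueError("min_methods exceeds number of method sets")
    if len(method_gene_sets) < 2:
        raise ValueError("need >= 2 method sets")
    counts: dict[str, int] = {}
    for genes in method_gene_sets.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    candidates = {g for g, c in counts.items() if c >= min_methods}
    per_method = {m: len(s) for m, s in method_gene_sets.items()}
    names = list(method_gene_sets)
    per_intersection: dict[tuple[str, ...], int] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            key = (names[i], names[j])
            per_intersection[key] = len(
                method_gene_sets[names[i]] & method_gene_sets[names[j]]
            )
    return ConsensusReport(
        candidates=candidates, per_method=per_method, per_intersection=per_intersection
    )
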