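"""Population differentiation: Weir-Cockerham F_ST from SNPs and V_ST from
normalized CNV read depth.

Per-site F_ST uses the Weir & Cockerham (1984) variance components for
diploid data with unequal sample sizes: a (among populations), b (among
individuals within populations), c (within individuals); theta = a/(a+b+c).
Windowed values combine sites as a ratio of sums, sum(a)/sum(a+b+c), the
standard multi-locus estimator.

V_ST is the CNV analog of F_ST: for a set of per-sample values (here the
mean normalized depth over a CNV region's targets), V_T is the pooled
two-population sample variance, V_S the sample-size-weighted mean of the
within-population variances, and V_ST = (V_T - V_S)/V_T.  Sample variances
use the n-1 denominator throughout; V_ST is undefined when V_T = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnv import CnvRegion, NormalizedDepthMatrix
from .genotypes import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class PerSiteFst:
    """Per-site Weir-Cockerham variance components and theta estimates."""

    sites: pd.DataFrame     # chrom, pos of evaluated sites
    a: np.ndarray           # among-population component
    b: np.ndarray           # among-individual-within component
    c: np.ndarray           # within-individual component
    theta: np.ndarray       # a / (a+b+c); NaN where a+b+c == 0

    def mean_theta(self) -> float:
        """Multi-locus ratio-of-sums estimate over all usable sites."""
        denom = np.nansum(self.a + self.b + self.c)
        return float(np.nansum(self.a) / denom) if denom != 0 else float("nan")


def weir_cockerham_fst(
    gm: GenotypeMatrix, samples_a: list[str], samples_b: list[str]
) -> PerSiteFst:
    """Per-site Weir-Cockerham (1984) F_ST between two sample groups."""
    if set(samples_a) & set(samples_b):
        raise ValueError("sample groups overlap")
    ga = gm.take_samples(samples_a).geno.astype(float)
    gb = gm.take_samples(samples_b).geno.astype(float)
    ga[ga == MISSING] = np.nan
    gb[gb == MISSING] = np.nan

    r = 2  # number of populations
    n_i = np.stack([np.sum(~np.isnan(ga), axis=0), np.sum(~np.isnan(gb), axis=0)])
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.nanmean(ga, axis=0) / 2, np.nanmean(gb, axis=0) / 2])
        h_i = np.stack(
            [
                np.nansum(ga == 1, axis=0) / n_i[0],
                np.nansum(gb == 1, axis=0) / n_i[1],
            ]
        )
        n_bar = n_i.mean(axis=0)
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    # sites where either group has < 2 called genotypes are unusable
    bad = (n_i < 2).any(axis=0)
    for arr in (a, b, c, theta):
        arr[bad] = np.nan
    return PerSiteFst(
        sites=gm.sites[["chrom", "pos"]].copy(), a=a, b=b, c=c, theta=theta
    )


@dataclass
class WindowStat:
    """One sliding-window statistic value (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    n_variants: int
    value: float  # NaN flags a window without usable variants


def _tile_windows(chrom_end: int, window: int, step: int):
    if step > window:
        import warnings

        warnings.warn("step > window leaves gaps between windows", stacklevel=3)
    start = 0
    while start < chrom_end:
        yield start, start + window
        start += step


def windowed_fst(
    per_site: PerSiteFst,
    window: int = 100_000,
    step: int = 50_000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Mean F_ST per sliding window as a ratio of sums of the variance
    components; windows tile each chromosome from 0 to its end."""
    out: list[WindowStat] = []
    chroms = per_site.sites["chrom"].to_numpy()
    pos0 = per_site.sites["pos"].to_numpy() - 1  # 0-based point
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        p = pos0[sel]
        a, b, c = per_site.a[sel], per_site.b[sel], per_site.c[sel]
        end = chrom_sizes[chrom] if chrom_sizes else int(p.max()) + 1
        for ws, we in _tile_windows(end, window, step):
            in_w = (p >= ws) & (p < we)
            usable = in_w & ~np.isnan(a)
            n = int(usable.sum())
            if n == 0:
                val = float("nan")
            else:
                denom = np.sum(a[usable] + b[usable] + c[usable])
                val = float(np.sum(a[usable]) / denom) if denom != 0 else float("nan")
            out.append(WindowStat(str(chrom), ws, we, n, val))
    return out


# ---------------------------------------------------------------------------
# V_ST

@dataclass
class VstResult:
    region_id: str
    v_t: float
    v_s: float
    v_st: float  # NaN when v_t == 0


def vst_from_values(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float, float]:
    """Core V_ST for two groups of per-sample values (n-1 variances)."""
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("both populations need >= 2 samples")
    pooled = np.concatenate([va, vb])
    v_t = float(np.var(pooled, ddof=1))
    v_s = float(
        (len(va) * np.var(va, ddof=1) + len(vb) * np.var(vb, ddof=1))
        / (len(va) + len(vb))
    )
    v_st = (v_t - v_s) / v_t if v_t != 0 else float("nan")
    return v_t, v_s, v_st


def _region_values(ndm: NormalizedDepthMatrix, region: CnvRegion) -> np.ndarray:
    """Per-sample mean normalized depth over a region's spanned targets."""
    t = ndm.targets
    mask = (
        (t["chrom"].to_numpy() == region.chrom)
        & (t["start"].to_numpy() < region.end)
        & (t["end"].to_numpy() > region.start)
    )
    if not mask.any():
        raise ValueError(f"region {region.region_id} spans no targets")
    return ndm.z[:, mask].mean(axis=1)


def vst(
    ndm: NormalizedDepthMatrix,
    regions: list[CnvRegion],
    popmap: PopulationMap,
    cluster_a: str,
    cluster_b: str,
) -> list[VstResult]:
    """Per-region V_ST between two clusters from region-mean normalized depth."""
    idx = {s: i for i, s in enumerate(ndm.samples)}
    ia = [idx[s] for s in popmap.samples_in(cluster_a)]
    ib = [idx[s] for s in popmap.samples_in(cluster_b)]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both clusters need >= 2 samples")
    out = []
    for r in regions:
        vals = _region_values(ndm, r)
        v_t, v_s, v_st_ = vst_from_values(vals[ia], vals[ib])
        out.append(VstResult(region_id=r.region_id, v_t=v_t, v_s=v_s, v_st=v_st_))
    return out


def pairwise_mean_vst(
    ndm: NormalizedDepthMatrix,
    regions: list[CnvRegion],
    popmap: PopulationMap,
) -> pd.DataFrame:
    """Mean per-region V_ST for every cluster pair (NaN-aware)."""
    clusters = popmap.clusters()
    mat = pd.DataFrame(np.nan, index=clusters, columns=clusters, dtype=float)
    for i, ca in enumerate(clusters):
        for cb in clusters[i + 1 :]:
            res = vst(ndm, regions, popmap, ca, cb)
            vals = [r.v_st for r in res if np.isfinite(r.v_st)]
            m = float(np.mean(vals)) if vals else float("nan")
            mat.loc[ca, cb] = mat.loc[cb, ca] = m
    return mat


def pairwise_mean_fst(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Multi-locus (ratio-of-sums) F_ST for every cluster pair."""
    clusters = popmap.clusters()
    mat = pd.DataFrame(np.nan, index=clusters, columns=clusters, dtype=float)
    for i, ca in enumerate(clusters):
        for cb in clusters[i + 1 :]:
            ps = weir_cockerham_fst(gm, popmap.samples_in(ca), popmap.samples_in(cb))
            mat.loc[ca, cb] = mat.loc[cb, ca] = ps.mean_theta()
    return mat
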