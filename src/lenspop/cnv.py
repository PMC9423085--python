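"""Copy-number-variant discovery from exome-target read depth.

The caller follows the classic exome-depth recipe: drop unreliable capture
targets, remove the dominant principal components of the sample x target
depth matrix (systematic batch/GC/capture structure), z-score the residual
depth per target, and decode a 3-state hidden Markov model (DEL, DIPLOID,
DUP) along each sample's ordered targets.  Deletions pull the residual
z-score down, duplications push it up; the Viterbi path gives the calls and
the forward-backward posterior gives a per-call quality.

Downstream characterization: union-merged CNV regions across samples,
per-cluster frequencies and private CNVs, per-accession burden with
Kruskal-Wallis / rank-sum comparisons, and Spearman tests of CNV count per
chromosome against chromosome size and gene count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import PopulationMap

DEL, DIPLOID, DUP = 0, 1, 2
STATE_NAMES = {DEL: "DEL", DUP: "DUP"}


# ---------------------------------------------------------------------------
# containers

@dataclass
class DepthMatrix:
    """Samples x exome-targets mean read depth.

    ``targets``: DataFrame with chrom, start, end (0-based half-open),
    sorted and non-overlapping within each chromosome.
    ``depth``: ndarray (n_samples, n_targets), non-negative.
    """

    targets: pd.DataFrame
    samples: list[str]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.targets = self.targets.reset_index(drop=True)
        if self.depth.shape != (len(self.samples), len(self.targets)):
            raise ValueError("depth shape does not match samples x targets")
        if (self.targets["end"] <= self.targets["start"]).any():
            raise ValueError("targets must have end > start")
        for _, sub in self.targets.groupby("chrom", sort=False):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if np.any(np.diff(s) < 0) or np.any(s[1:] < e[:-1]):
                raise ValueError("targets must be sorted and non-overlapping per chromosome")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_targets(self) -> int:
        return len(self.targets)


@dataclass
class NormalizedDepthMatrix:
    """PCA-residual depth z-scores, same shape as the source DepthMatrix."""

    targets: pd.DataFrame
    samples: list[str]
    z: np.ndarray
    n_components_removed: int

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_targets(self) -> int:
        return len(self.targets)


@dataclass
class CnvCall:
    """One per-sample CNV call spanning >= 1 contiguous targets."""

    sample: str
    chrom: str
    start: int   # bp, start of first spanned target
    end: int     # bp, end of last spanned target
    state: str   # "DEL" or "DUP"
    n_targets: int
    mean_z: float
    quality: float  # mean posterior of the call state over spanned targets

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CnvRegion:
    """Union of overlapping per-sample calls; may carry both states."""

    region_id: str
    chrom: str
    start: int
    end: int
    del_carriers: set[str] = field(default_factory=set)
    dup_carriers: set[str] = field(default_factory=set)

    @property
    def carriers(self) -> set[str]:
        return self.del_carriers | self.dup_carriers


@dataclass
class HmmParams:
    """Fixed HMM parameterization (z-score emission space).

    p_cnv is the per-target prior of entering a CNV state from diploid;
    mean_targets_per_cnv sets the geometric expected dwell.  Emission means
    default to -3/+3 z for DEL/DUP with unit sd, the usual convention for
    PCA-normalized exome depth.
    """

    p_cnv: float = 1e-6
    mean_targets_per_cnv: float = 6.0
    del_mean: float = -3.0
    dup_mean: float = 3.0
    emission_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.p_cnv < 0.5:
            raise ValueError("p_cnv must be in (0, 0.5)")
        if self.mean_targets_per_cnv < 1:
            raise ValueError("mean_targets_per_cnv must be >= 1")
        if self.emission_sd <= 0:
            raise ValueError("emission_sd must be positive")

    def transition_matrix(self) -> np.ndarray:
        p, q = self.p_cnv, 1.0 / self.mean_targets_per_cnv
        return np.array(
            [
                [1 - q, q, 0.0],
                [p, 1 - 2 * p, p],
                [0.0, q, 1 - q],
            ]
        )

    def initial_probs(self) -> np.ndarray:
        return np.array([self.p_cnv, 1 - 2 * self.p_cnv, self.p_cnv])

    def emission_means(self) -> np.ndarray:
        return np.array([self.del_mean, 0.0, self.dup_mean])


# ---------------------------------------------------------------------------
# target filtering and normalization

def filter_targets(
    dm: DepthMatrix,
    min_size_bp: int = 100,
    min_mean_depth: float = 3.0,
    max_mean_depth: float = 3000.0,
) -> DepthMatrix:
    """Drop targets shorter than ``min_size_bp`` or with cross-sample mean
    depth outside ``[min_mean_depth, max_mean_depth]``."""
    span = (dm.targets["end"] - dm.targets["start"]).to_numpy()
    mean_depth = dm.depth.mean(axis=0)
    keep = (span >= min_size_bp) & (mean_depth >= min_mean_depth) & (mean_depth <= max_mean_depth)
    if not keep.any():
        raise ValueError("all targets removed by target filtering")
    return DepthMatrix(
        targets=dm.targets.loc[keep].reset_index(drop=True),
        samples=list(dm.samples),
        depth=dm.depth[:, keep],
    )


def normalize_depth(
    dm: DepthMatrix,
    n_components: int | str = "auto",
    log_transform: bool = False,
) -> NormalizedDepthMatrix:
    """PCA-normalize read depth and z-score residuals per target.

    The matrix is centered per target; principal components across samples
    are computed by SVD and the projections onto the top components are
    subtracted.  ``"auto"`` removes every component whose variance exceeds
    0.7 / n_samples of the total (relative-threshold convention).  Residuals
    are z-scored per target with the n-1 variance denominator; targets with
    zero residual variance get z = 0.
    """
    if dm.n_samples < 2 or dm.n_targets < 2:
        raise ValueError("need >= 2 samples and >= 2 targets")
    X = np.log(dm.depth + 1.0) if log_transform else dm.depth.astype(float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    total = var.sum()
    if n_components == "auto":
        if total == 0:
            k = 0
        else:
            k = int(np.sum(var / total > 0.7 / dm.n_samples))
    else:
        k = int(n_components)
        if k >= min(dm.n_samples, dm.n_targets):
            raise ValueError("n_components must be < min(n_samples, n_targets)")
    if k > 0:
        resid = Xc - (U[:, :k] * S[:k]) @ Vt[:k]
    else:
        resid = Xc
    resid = resid - resid.mean(axis=0, keepdims=True)
    sd = resid.std(axis=0, ddof=1)
    # residual variance at float-noise level (e.g. exactly low-rank input)
    # counts as zero, else z-scoring would amplify rounding error
    scale = np.maximum(Xc.std(axis=0, ddof=1), np.finfo(float).tiny)
    z = np.zeros_like(resid)
    ok = sd > 1e-9 * scale
    z[:, ok] = resid[:, ok] / sd[ok]
    return NormalizedDepthMatrix(
        targets=dm.targets.copy(),
        samples=list(dm.samples),
        z=z,
        n_components_removed=k,
    )


# ---------------------------------------------------------------------------
# HMM decoding

def _log_emissions(z: np.ndarray, params: HmmParams) -> np.ndarray:
    """(T, 3) Gaussian log-densities of the observed z under each state."""
    means = params.emission_means()
    sd = params.emission_sd
    zz = np.asarray(z, dtype=float)[:, None]
    return -0.5 * ((zz - means[None, :]) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))


def viterbi_path(z: np.ndarray, params: HmmParams) -> np.ndarray:
    """Most probable state path for one sample's ordered target z-scores."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-scores")
    T = len(z)
    if T == 0:
        return np.empty(0, dtype=int)
    with np.errstate(divide="ignore"):
        log_trans = np.log(params.transition_matrix())
        log_init = np.log(params.initial_probs())
    log_em = _log_emissions(z, params)
    delta = log_init + log_em[0]
    back = np.zeros((T, 3), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_trans  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(3)] + log_em[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def state_posteriors(z: np.ndarray, params: HmmParams) -> np.ndarray:
    """Forward-backward marginal posteriors, shape (T, 3)."""
    z = np.asarray(z, dtype=float)
    T = len(z)
    if T == 0:
        return np.empty((0, 3))
    trans = params.transition_matrix()
    init = params.initial_probs()
    em = np.exp(_log_emissions(z, params))
    alpha = np.zeros((T, 3))
    scale = np.zeros(T)
    alpha[0] = init * em[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ trans) * em[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta = np.ones((T, 3))
    for t in range(T - 2, -1, -1):
        beta[t] = trans @ (em[t + 1] * beta[t + 1])
        beta[t] /= scale[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


def _runs(path: np.ndarray):
    """Yield (state, start_index, end_index_inclusive) for non-diploid runs."""
    start = None
    for i, s in enumerate(path):
        if s != DIPLOID and start is None:
            start = i
        elif start is not None and (s == DIPLOID or s != path[start]):
            yield int(path[start]), start, i - 1
            start = i if s != DIPLOID else None
    if start is not None:
        yield int(path[start]), start, len(path) - 1


def call_cnvs_hmm(
    ndm: NormalizedDepthMatrix, params: HmmParams | None = None
) -> list[CnvCall]:
    """Decode per-sample, per-chromosome CNV calls from normalized depth."""
    params = params or HmmParams()
    if not np.all(np.isfinite(ndm.z)):
        raise ValueError("non-finite values in normalized depth")
    calls: list[CnvCall] = []
    chroms = ndm.targets["chrom"].to_numpy()
    starts = ndm.targets["start"].to_numpy()
    ends = ndm.targets["end"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for si, sample in enumerate(ndm.samples):
            z = ndm.z[si, idx]
            path = viterbi_path(z, params)
            if np.all(path == DIPLOID):
                continue
            post = state_posteriors(z, params)
            for state, a, b in _runs(path):
                span = idx[a : b + 1]
                calls.append(
                    CnvCall(
                        sample=sample,
                        chrom=str(chrom),
                        start=int(starts[span[0]]),
                        end=int(ends[span[-1]]),
                        state=STATE_NAMES[state],
                        n_targets=b - a + 1,
                        mean_z=float(z[a : b + 1].mean()),
                        quality=float(post[a : b + 1, state].mean()),
                    )
                )
    return calls


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.sample, c.state, c.n_targets, c.mean_z, c.quality)
            for c in calls
        ],
        columns=["chrom", "start", "end", "sample", "state", "n_targets", "mean_z", "quality"],
    )


# ---------------------------------------------------------------------------
# region catalog, frequencies, burden

def cnv_regions(calls: list[CnvCall]) -> list[CnvRegion]:
    """Union-merge overlapping calls across samples into CNV regions.

    Calls overlapping in genomic coordinates (half-open) are pooled into one
    region regardless of state, so a region can have both DEL and DUP
    carriers (the same accession may even contribute both).
    """
    regions: list[CnvRegion] = []
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    counter = 0
    for chrom in by_chrom:
        group = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        cur: list[CnvCall] = []
        cur_end = None
        for c in group:
            if cur and c.start >= cur_end:
                regions.append(_make_region(chrom, cur, counter))
                counter += 1
                cur, cur_end = [], None
            cur.append(c)
            cur_end = c.end if cur_end is None else max(cur_end, c.end)
        if cur:
            regions.append(_make_region(chrom, cur, counter))
            counter += 1
    return regions


def _make_region(chrom: str, group: list[CnvCall], counter: int) -> CnvRegion:
    region = CnvRegion(
        region_id=f"cnvr_{counter}",
        chrom=chrom,
        start=min(c.start for c in group),
        end=max(c.end for c in group),
    )
    for c in group:
        (region.del_carriers if c.state == "DEL" else region.dup_carriers).add(c.sample)
    return region


def regions_to_frame(regions: list[CnvRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.chrom, r.start, r.end, r.region_id,
                len(r.del_carriers), len(r.dup_carriers),
                ",".join(sorted(r.del_carriers)), ",".join(sorted(r.dup_carriers)),
            )
            for r in regions
        ],
        columns=[
            "chrom", "start", "end", "region_id",
            "n_del_carriers", "n_dup_carriers", "del_carriers", "dup_carriers",
        ],
    )


def cnv_frequencies(regions: list[CnvRegion], popmap: PopulationMap) -> pd.DataFrame:
    """Per-region, per-cluster carrier frequencies and private flags.

    Frequency = carriers-in-cluster / cluster size, reported per state and
    combined.  A region is private to cluster c iff all its carriers belong
    to c.
    """
    clusters = popmap.clusters()
    sizes = popmap.cluster_sizes()
    rows = []
    for r in regions:
        for s in r.carriers:
            if s not in popmap:
                raise KeyError(f"carrier sample {s!r} not in population map")
        carrier_clusters = {popmap.cluster_of(s) for s in r.carriers}
        private_to = carrier_clusters.pop() if len(carrier_clusters) == 1 else None
        for cl in clusters:
            members = set(popmap.samples_in(cl))
            n = sizes[cl]
            rows.append(
                {
                    "region_id": r.region_id,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "cluster": cl,
                    "freq_del": len(r.del_carriers & members) / n,
                    "freq_dup": len(r.dup_carriers & members) / n,
                    "freq_any": len(r.carriers & members) / n,
                    "private_to": private_to,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BurdenResult:
    per_accession: pd.DataFrame
    kruskal: dict[str, tuple[float, float]]
    pairwise: dict[str, pd.DataFrame]


def cnv_burden(
    calls: list[CnvCall],
    popmap: PopulationMap,
    metrics: tuple[str, ...] = ("n_del", "n_dup", "n_cnv", "median_len"),
) -> BurdenResult:
    """Per-accession CNV counts/lengths and cluster-level comparisons.

    Kruskal-Wallis across clusters and pairwise two-sided rank-sum tests
    with Holm correction, per metric.  Accessions without calls contribute
    zero counts and a missing median length.
    """
    from statsmodels.stats.multitest import multipletests

    per_sample: dict[str, list[CnvCall]] = {s: [] for s in popmap.samples}
    for c in calls:
        if c.sample not in per_sample:
            raise KeyError(f"call sample {c.sample!r} not in population map")
        per_sample[c.sample].append(c)
    rows = []
    for s, cs in per_sample.items():
        lens = [c.length for c in cs]
        rows.append(
            {
                "sample": s,
                "cluster": popmap.cluster_of(s),
                "n_del": sum(c.state == "DEL" for c in cs),
                "n_dup": sum(c.state == "DUP" for c in cs),
                "n_cnv": len(cs),
                "mean_len": float(np.mean(lens)) if lens else np.nan,
                "median_len": float(np.median(lens)) if lens else np.nan,
            }
        )
    per_accession = pd.DataFrame(rows)
    kruskal: dict[str, tuple[float, float]] = {}
    pairwise: dict[str, pd.DataFrame] = {}
    clusters = [c for c in popmap.clusters()]
    usable = []
    for cl in clusters:
        sub = per_accession.loc[per_accession["cluster"] == cl]
        if len(sub) == 0:
            warnings.warn(f"cluster {cl!r} has no accessions; excluded", stacklevel=2)
        else:
            usable.append(cl)
    if len(usable) >= 2:
        for metric in metrics:
            groups = [
                per_accession.loc[per_accession["cluster"] == cl, metric].dropna().to_numpy()
                for cl in usable
            ]
            groups_ok = [(cl, g) for cl, g in zip(usable, groups) if len(g) > 0]
            allvals = (
                np.concatenate([g for _, g in groups_ok]) if groups_ok else np.empty(0)
            )
            if len(groups_ok) >= 2 and np.unique(allvals).size > 1:
                stat, p = stats.kruskal(*[g for _, g in groups_ok])
            else:
                stat, p = np.nan, 1.0
            kruskal[metric] = (float(stat), float(p))
            prs = []
            for i in range(len(groups_ok)):
                for j in range(i + 1, len(groups_ok)):
                    (ca, ga), (cb, gb) = groups_ok[i], groups_ok[j]
                    if len(ga) and len(gb):
                        try:
                            _, pr = stats.mannwhitneyu(ga, gb, alternative="two-sided")
                        except ValueError:
                            pr = 1.0
                    else:
                        pr = np.nan
                    prs.append((ca, cb, float(pr)))
            df = pd.DataFrame(prs, columns=["cluster_a", "cluster_b", "p_raw"])
            if len(df):
                df["p_holm"] = multipletests(df["p_raw"].fillna(1.0), method="holm")[1]
            pairwise[metric] = df
    return BurdenResult(per_accession=per_accession, kruskal=kruskal, pairwise=pairwise)


@dataclass
class ChromosomeCorrelation:
    rho_size: float
    p_size: float
    rho_genes: float
    p_genes: float


def cnv_chromosome_correlation(
    regions: list[CnvRegion],
    chrom_sizes: dict[str, int],
    gene_counts: dict[str, int],
) -> ChromosomeCorrelation:
    """Spearman tests of CNV count per chromosome vs size and gene count."""
    chroms = list(chrom_sizes)
    if len(chroms) < 4:
        raise ValueError("need >= 4 chromosomes for Spearman tests")
    counts = {c: 0 for c in chroms}
    for r in regions:
        if r.chrom in counts:
            counts[r.chrom] += 1
    n = np.array([counts[c] for c in chroms], dtype=float)
    size = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    genes = np.array([gene_counts.get(c, 0) for c in chroms], dtype=float)
    rho_s, p_s = stats.spearmanr(n, size)
    rho_g, p_g = stats.spearmanr(n, genes)
    return ChromosomeCorrelation(float(rho_s), float(p_s), float(rho_g), float(p_g))
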