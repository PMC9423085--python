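"""Synthetic diversity-panel generator.

Emulates the statistical structure of an exome-capture diversity panel of a
highly selfing diploid crop: K clusters whose allele frequencies disperse
around ancestral frequencies under a Balding-Nichols beta model keyed to a
single F_ST parameter, genotypes drawn with the inbreeding coefficient
implied by the selfing rate (F = s / (2 - s)), ancestral frequencies drawn
from a 1/p density so the neutral site-frequency spectrum matches the
Watterson expectation, low-frequency deletions/duplications implanted over
contiguous exome targets, multiplicative read-depth noise with low-rank
batch structure, and optional hard selective sweeps (one locally dominant
haplotype in a designated cluster).

Everything is deterministic given ``SimConfig.seed``; substreams for
genotypes, CNVs, depth and annotation are spawned from one SeedSequence so
stages reproduce independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation
from .cnv import DepthMatrix
from .genotypes import MISSING, GenotypeMatrix, PopulationMap
from . import io as lio

DEFAULT_CATEGORIES = (
    "Enzymes",
    "RNA biosynthesis",
    "Protein modification",
    "Cell Wall Organization",
    "External stimuli response",
    "Nucleotide metabolism",
    "Solute transport",
    "Photosynthesis",
    "Phytohormone action",
    "Protein translocation",
    "Coenzyme metabolism",
    "Lipid metabolism",
)
# genome-wide label weights, decreasing (Enzymes most common)
_CATEGORY_WEIGHTS = np.array([0.22, 0.14, 0.12, 0.08, 0.07, 0.07, 0.07, 0.06,
                              0.05, 0.05, 0.04, 0.03])


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic panel.

    Defaults mirror the real panel's structure at desk scale: 8 clusters of
    a ~95%-selfing diploid, 7 chromosomes, moderate differentiation, rare
    multi-target CNVs whose depth shift is ~3 residual z-units, 2
    batch components in the depth noise, ~20x mean coverage.
    """

    n_clusters: int = 8
    samples_per_cluster: int = 40
    n_chromosomes: int = 7
    chrom_length_bp: int = 5_000_000
    n_snps: int = 7_000
    n_targets: int = 2_000
    selfing_rate: float = 0.95
    fst_between_clusters: float = 0.2
    n_true_cnvs: int = 30
    cnv_z_shift: float = 3.0
    cnv_min_targets: int = 5
    n_batch_components: int = 2
    base_depth: float = 20.0
    sweep_positions: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0
    # secondary knobs (held at realistic values; exposed for testing edge cases)
    missing_rate: float = 0.01
    sweep_cluster: int = 0
    sweep_width_bp: int = 400_000
    sweep_carrier_frac: float = 0.92
    depth_noise_cv: float | None = None      # None -> 0.5 / cnv_z_shift
    sample_effect_sd: float = 0.08
    batch_amplitude: float = 0.15
    cnv_hom_frac: float | None = None   # None -> inbreeding coeff s/(2-s)
    cnv_max_freq: float = 0.08
    cnv_freq_beta: tuple[float, float] = (0.5, 15.0)
    gene_every_bp: int = 50_000
    gene_length_bp: int = 3_000
    resistance_frac: float = 0.02

    def __post_init__(self) -> None:
        for name in ("n_clusters", "samples_per_cluster", "n_chromosomes",
                     "chrom_length_bp", "n_snps", "n_targets", "n_true_cnvs",
                     "cnv_min_targets"):
            if getattr(self, name) < (1 if name != "n_true_cnvs" else 0):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")
        if not 0.0 <= self.fst_between_clusters < 1.0:
            raise ValueError("fst_between_clusters must be in [0, 1)")
        if self.n_snps < 50 * self.n_chromosomes:
            raise ValueError(
                "n_snps < 50 per chromosome: haplotype-homozygosity windows "
                "would be impossible"
            )

    @property
    def noise_cv(self) -> float:
        """Residual depth coefficient of variation.

        Calibrated so that a heterozygous deletion (copy ratio 0.5) in an
        otherwise clean background realizes a residual z-shift of about
        ``cnv_z_shift`` *after* accounting for the carrier's own
        contribution to the per-target spread (per-target z-scores are
        computed across all samples, carriers included).
        """
        return (
            self.depth_noise_cv
            if self.depth_noise_cv is not None
            else 0.36 / self.cnv_z_shift
        )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class TruthCnv:
    """An implanted CNV: contiguous target span plus per-carrier copy ratio."""

    chrom: str
    start: int
    end: int
    state: str                      # "DEL" | "DUP"
    target_indices: np.ndarray      # global indices into the target table
    carriers: dict[str, float]      # sample -> copy ratio (0, 0.5, 1.5, 2)

    @property
    def n_targets(self) -> int:
        return len(self.target_indices)


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    depths: DepthMatrix
    truth_cnvs: list[TruthCnv]
    popmap: PopulationMap
    annotation: GeneAnnotation
    truth_sweep_genes: set[str]
    config: SimConfig


# ---------------------------------------------------------------------------
# pieces

def _gene_grid(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-chromosome gene tiling (starts, ends; 0-based)."""
    starts = np.arange(
        int(cfg.gene_every_bp * 0.3),
        cfg.chrom_length_bp - cfg.gene_length_bp,
        cfg.gene_every_bp,
    )
    return starts, starts + cfg.gene_length_bp


def _snp_positions(
    cfg: SimConfig, rng: np.random.Generator, p_genic: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """(chrom index, 1-based position) for all SNPs, sorted.

    Exome-capture variants concentrate in coding sequence: a fraction
    ``p_genic`` of positions fall inside the gene grid, the rest uniform.
    """
    per = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per[: cfg.n_snps % cfg.n_chromosomes] += 1
    g_start, g_end = _gene_grid(cfg)
    chroms, poss = [], []
    for c, k in enumerate(per):
        chosen: set[int] = set()
        while len(chosen) < k:
            need = k - len(chosen)
            genic = rng.random(need) < p_genic
            gi = rng.integers(0, len(g_start), size=need)
            offset = rng.integers(1, cfg.gene_length_bp + 1, size=need)
            p_in = g_start[gi] + offset
            p_unif = rng.integers(1, cfg.chrom_length_bp + 1, size=need)
            chosen.update(np.where(genic, p_in, p_unif).tolist())
        pos = np.sort(np.fromiter(chosen, dtype=np.int64, count=k))
        chroms.append(np.full(k, c))
        poss.append(pos)
    return np.concatenate(chroms), np.concatenate(poss)


def _ancestral_freqs(n: int, rng: np.random.Generator, eps: float = 1e-3) -> np.ndarray:
    """Frequencies from a density proportional to 1/p on [eps, 1-eps]
    (neutral infinite-sites shape; log-uniform draw)."""
    u = rng.random(n)
    p = eps * (1.0 / eps) ** u
    return np.clip(p, eps, 1 - eps)


def _cluster_drift(cfg: SimConfig) -> np.ndarray:
    """Per-cluster drift parameters spanning [0.5, 1.5] x the nominal F_ST.

    Real panels are unevenly diverged (peripheral clusters drift more than
    those near the center of origin); the spread also makes pairwise
    differentiation genuinely rankable.
    """
    if cfg.n_clusters == 1:
        return np.array([cfg.fst_between_clusters])
    return cfg.fst_between_clusters * np.linspace(0.5, 1.5, cfg.n_clusters)


def _balding_nichols(
    p: np.ndarray, fst_k: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Cluster frequencies dispersed around ancestral p with per-cluster
    drift parameters; (K, n_sites)."""
    p = np.asarray(p, dtype=float)
    out = np.empty((len(fst_k), len(p)))
    for k, fst in enumerate(fst_k):
        if fst == 0:
            out[k] = p
        else:
            scale = (1 - fst) / fst
            a = np.clip(p * scale, 1e-9, None)
            b = np.clip((1 - p) * scale, 1e-9, None)
            out[k] = rng.beta(a, b)
    return out


def _draw_genotypes(
    pk: np.ndarray, n_samples: int, selfing_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Genotypes for one cluster with inbreeding F = s/(2-s); (n, sites)."""
    s = selfing_rate
    F = s / (2.0 - s) if s < 1 else 1.0
    n_sites = len(pk)
    inbred = rng.random((n_samples, n_sites)) < F
    hom = 2 * (rng.random((n_samples, n_sites)) < pk[None, :]).astype(np.int8)
    hw = (
        (rng.random((n_samples, n_sites)) < pk[None, :]).astype(np.int8)
        + (rng.random((n_samples, n_sites)) < pk[None, :]).astype(np.int8)
    )
    return np.where(inbred, hom, hw).astype(np.int8)


def simulate_targets(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping, sorted exome targets (chrom, start, end; 0-based)."""
    per = np.full(cfg.n_chromosomes, cfg.n_targets // cfg.n_chromosomes)
    per[: cfg.n_targets % cfg.n_chromosomes] += 1
    rows = []
    for c, k in enumerate(per):
        slot = cfg.chrom_length_bp // (k + 1)
        max_len = max(min(500, slot - 1), 121)
        for i in range(k):
            length = int(rng.integers(120, max_len))
            offset = int(rng.integers(0, max(slot - length, 1)))
            start = i * slot + offset
            rows.append((cfg.chrom_names[c], start, start + length))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _low_freq(rng: np.random.Generator, shape: tuple[float, float] = (0.5, 15.0)) -> float:
    """Carrier frequency from a monotone-decreasing (low-frequency-skewed)
    distribution; the default mean of ~3% matches a panel where each
    accession carries a few dozen of a few thousand CNV regions."""
    return float(rng.beta(*shape))


def simulate_cnvs(
    cfg: SimConfig,
    targets: pd.DataFrame,
    samples: list[str],
    popmap: PopulationMap,
    rng: np.random.Generator,
) -> list[TruthCnv]:
    """Implant disjoint truth CNVs over contiguous target runs."""
    chrom_arr = targets["chrom"].to_numpy()
    occupied = np.zeros(len(targets), dtype=bool)
    out: list[TruthCnv] = []
    clusters = popmap.clusters()
    attempts = 0
    while len(out) < cfg.n_true_cnvs and attempts < cfg.n_true_cnvs * 60:
        attempts += 1
        span = int(cfg.cnv_min_targets + rng.poisson(3))
        if span >= len(targets):
            continue
        start_idx = int(rng.integers(0, len(targets) - span))
        idx = np.arange(start_idx, start_idx + span)
        if occupied[idx].any() or len(set(chrom_arr[idx])) != 1:
            continue
        occupied[idx] = True
        state = "DEL" if rng.random() < 0.5 else "DUP"
        f_global = max(_low_freq(rng, cfg.cnv_freq_beta), 1.0 / len(samples))
        f_cluster = _balding_nichols(np.array([f_global]), _cluster_drift(cfg), rng)[:, 0]
        # a panel-internal depth reference cannot resolve common CNVs, and
        # the observed per-accession burden implies rare ones; keep carrier
        # frequency bounded while preserving the low-frequency excess
        f_cluster = np.minimum(f_cluster, cfg.cnv_max_freq)
        # in a selfing panel carriers are mostly homozygous for the CNV
        hom_frac = (
            cfg.cnv_hom_frac
            if cfg.cnv_hom_frac is not None
            else cfg.selfing_rate / (2.0 - cfg.selfing_rate)
        )
        carriers: dict[str, float] = {}
        for k, cl in enumerate(clusters):
            for s in popmap.samples_in(cl):
                if rng.random() < f_cluster[k]:
                    hom = rng.random() < hom_frac
                    ratio = (0.0 if hom else 0.5) if state == "DEL" else (2.0 if hom else 1.5)
                    carriers[s] = ratio
        if not carriers:
            s = samples[int(rng.integers(0, len(samples)))]
            carriers[s] = 0.5 if state == "DEL" else 1.5
        out.append(
            TruthCnv(
                chrom=str(chrom_arr[start_idx]),
                start=int(targets["start"].iloc[start_idx]),
                end=int(targets["end"].iloc[start_idx + span - 1]),
                state=state,
                target_indices=idx,
                carriers=carriers,
            )
        )
    return out


def simulate_read_depth(
    truth_cnvs: list[TruthCnv],
    targets: pd.DataFrame,
    samples: list[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> DepthMatrix:
    """Depth = base x gamma target effect x sample effect x low-rank batch
    structure x copy ratio x multiplicative lognormal noise."""
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(4)[2]
    )
    n_s, n_t = len(samples), len(targets)
    starts = targets["start"].to_numpy()
    ends = targets["end"].to_numpy()
    chroms = targets["chrom"].to_numpy()
    for cnv in truth_cnvs:
        idx = np.asarray(cnv.target_indices)
        if np.any(np.diff(idx) != 1):
            raise ValueError("truth CNV targets must be contiguous")
        if len(idx) < 1:
            raise ValueError("truth CNV spans no targets")
        if (
            cnv.start != starts[idx[0]]
            or cnv.end != ends[idx[-1]]
            or not np.all(chroms[idx] == cnv.chrom)
        ):
            raise ValueError("truth CNV not aligned to target boundaries")
    target_effect = rng.gamma(shape=6.0, scale=1.0 / 6.0, size=n_t)
    if config.sample_effect_sd > 0:
        sample_effect = rng.lognormal(0.0, config.sample_effect_sd, size=n_s)
    else:
        sample_effect = np.ones(n_s)
    log_batch = np.zeros((n_s, n_t))
    for _ in range(config.n_batch_components):
        u = rng.standard_normal(n_s)
        v = rng.standard_normal(n_t)
        log_batch += config.batch_amplitude * np.outer(u, v)
    ratio = np.ones((n_s, n_t))
    sample_idx = {s: i for i, s in enumerate(samples)}
    for cnv in truth_cnvs:
        for s, r in cnv.carriers.items():
            ratio[sample_idx[s], cnv.target_indices] = r
    cv = config.noise_cv
    noise = rng.lognormal(0.0, cv, size=(n_s, n_t)) if cv > 0 else np.ones((n_s, n_t))
    depth = (
        config.base_depth
        * target_effect[None, :]
        * sample_effect[:, None]
        * np.exp(log_batch)
        * ratio
        * noise
    )
    return DepthMatrix(targets=targets.copy(), samples=list(samples), depth=depth)


def simulate_annotation(
    cfg: SimConfig,
    rng: np.random.Generator,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
    weights: np.ndarray | None = None,
) -> GeneAnnotation:
    """Genes tiled along chromosomes with MapMan-style category labels and
    a small fraction of disease-resistance genes."""
    weights = _CATEGORY_WEIGHTS if weights is None else np.asarray(weights, float)
    weights = weights / weights.sum()
    g_start, g_end = _gene_grid(cfg)
    rows = []
    gid = 0
    for c in range(cfg.n_chromosomes):
        for start, end in zip(g_start, g_end):
            gid += 1
            cats = [str(rng.choice(categories, p=weights))]
            if rng.random() < 0.15:
                extra = str(rng.choice(categories, p=weights))
                if extra not in cats:
                    cats.append(extra)
            if rng.random() < 0.05:
                cats = []
            rows.append(
                {
                    "gene_id": f"gene{gid:05d}",
                    "chrom": cfg.chrom_names[c],
                    "start": int(start),
                    "end": int(end),
                    "categories": cats,
                    "resistance": bool(rng.random() < cfg.resistance_frac),
                }
            )
    return GeneAnnotation(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# top-level generator

def simulate_populations(config: SimConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset (genotypes, depths, truth CNVs,
    popmap, annotation, truth sweep genes); deterministic given the seed."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_geno, rng_cnv, rng_depth, rng_annot = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    samples = [f"acc{i:03d}" for i in range(cfg.n_clusters * cfg.samples_per_cluster)]
    popmap = PopulationMap.from_pairs(
        (s, str(i // cfg.samples_per_cluster + 1)) for i, s in enumerate(samples)
    )
    clusters = popmap.clusters()

    chrom_idx, pos = _snp_positions(cfg, rng_geno)
    n_sites = len(pos)
    p_anc = _ancestral_freqs(n_sites, rng_geno)
    pk = _balding_nichols(p_anc, _cluster_drift(cfg), rng_geno)
    geno = np.empty((len(samples), n_sites), dtype=np.int8)
    for k, cl in enumerate(clusters):
        rows = [samples.index(s) for s in popmap.samples_in(cl)]
        geno[rows] = _draw_genotypes(pk[k], len(rows), cfg.selfing_rate, rng_geno)

    # sweeps: one locally dominant haplotype in the designated cluster
    for chrom_i, bp in cfg.sweep_positions:
        half = cfg.sweep_width_bp // 2
        in_sweep = (chrom_idx == chrom_i) & (pos >= bp - half) & (pos <= bp + half)
        j = np.flatnonzero(in_sweep)
        if len(j) == 0:
            continue
        hap = (rng_geno.random(len(j)) < pk[cfg.sweep_cluster, j]).astype(np.int8)
        cl = clusters[cfg.sweep_cluster]
        members = [samples.index(s) for s in popmap.samples_in(cl)]
        swept = [m for m in members if rng_geno.random() < cfg.sweep_carrier_frac]
        for m in swept:
            geno[m, j] = 2 * hap

    if cfg.missing_rate > 0:
        miss = rng_geno.random(geno.shape) < cfg.missing_rate
        geno[miss] = MISSING

    bases = np.array(list("ACGT"))
    ref_i = rng_geno.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng_geno.integers(1, 4, size=n_sites)) % 4
    qual = np.round(rng_geno.uniform(30, 300, size=n_sites), 1)
    low_q = rng_geno.random(n_sites) < 0.03
    qual[low_q] = np.round(rng_geno.uniform(5, 30, size=int(low_q.sum())), 1)
    mean_depth = rng_geno.gamma(shape=8.0, scale=cfg.base_depth / 8.0, size=n_sites)
    sites = pd.DataFrame(
        {
            "chrom": [cfg.chrom_names[c] for c in chrom_idx],
            "pos": pos.astype(np.int64),
            "ref": bases[ref_i],
            "alt": bases[alt_i],
            "qual": qual,
            "mean_depth": mean_depth,
            "biallelic": True,
        }
    )
    genotypes = GenotypeMatrix(samples=samples, sites=sites, geno=geno)

    targets = simulate_targets(cfg, rng_cnv)
    truth_cnvs = simulate_cnvs(cfg, targets, samples, popmap, rng_cnv)
    depths = simulate_read_depth(truth_cnvs, targets, samples, cfg, rng_depth)
    annotation = simulate_annotation(cfg, rng_annot)

    # every gene on the swept haplotype is a true positive: within the
    # implanted interval the dominant haplotype is shared, so no method
    # (nor the real data) can single out one causal gene
    sweep_genes: set[str] = set()
    half = cfg.sweep_width_bp // 2
    for chrom_i, bp in cfg.sweep_positions:
        sweep_genes.update(
            annotation.genes_overlapping(cfg.chrom_names[chrom_i], bp - half, bp + half)
        )

    return SyntheticDataset(
        genotypes=genotypes,
        depths=depths,
        truth_cnvs=truth_cnvs,
        popmap=popmap,
        annotation=annotation,
        truth_sweep_genes=sweep_genes,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# writing

def write_dataset(dataset: SyntheticDataset, directory, force: bool = False) -> dict[str, Path]:
    """Write the dataset as VCF + TSV + BED; round-trips through the readers."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": d / "snps.vcf",
        "depth": d / "depth.tsv",
        "popmap": d / "popmap.tsv",
        "targets": d / "targets.bed",
        "truth_cnvs": d / "truth_cnvs.bed",
        "genes": d / "genes.bed",
        "categories": d / "categories.tsv",
    }
    if not force:
        for p in paths.values():
            if p.exists():
                raise FileExistsError(f"{p} exists (pass force=True to overwrite)")
    lio.write_vcf(dataset.genotypes, paths["vcf"], force=force)
    lio.write_depth_tsv(
        dataset.depths.targets, dataset.depths.samples, dataset.depths.depth,
        paths["depth"], force=force,
    )
    dataset.popmap.write_tsv(paths["popmap"])
    lio.write_bed(dataset.depths.targets, paths["targets"], force=force)
    truth = pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.state, len(c.carriers), ",".join(sorted(c.carriers)))
            for c in dataset.truth_cnvs
        ],
        columns=["chrom", "start", "end", "state", "n_carriers", "carriers"],
    )
    lio.write_bed(truth, paths["truth_cnvs"], force=force)
    dataset.annotation.write(paths["genes"], paths["categories"])
    return paths
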