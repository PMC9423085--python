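"""Pipeline orchestration: simulate -> filter -> CNV -> diversity ->
differentiation -> structure -> selection -> enrichment from one config,
with a run manifest recording resolved parameters and output checksums.

Stage substreams are derived deterministically from the single global seed
via SeedSequence spawn keys, so toggling stages on or off never changes the
randomness another stage sees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import io as lio
from .cnv import (
    HmmParams,
    call_cnvs_hmm,
    calls_to_frame,
    cnv_frequencies,
    cnv_regions,
    filter_targets,
    normalize_depth,
    regions_to_frame,
    DepthMatrix,
)
from .differentiation import pairwise_mean_fst, pairwise_mean_vst, weir_cockerham_fst, windowed_fst
from .enrichment import category_enrichment, genes_in_cnv_regions, resistance_overlap
from .filtering import FilterParams, filter_variants, thin_variants
from .genotypes import PopulationMap
from .pca import depth_pca, genotype_pca
from .selection import (
    consensus_candidates,
    find_peaks,
    h12_scan,
    pca_outlier_scan,
    regions_to_genes,
    tajimas_d_windows,
)
from .annotation import GeneAnnotation
from .sim import SimConfig, simulate_populations, write_dataset

STAGES = (
    "simulate", "filter", "cnv", "diversity",
    "differentiation", "structure", "selection", "enrichment",
)


@dataclass
class RunConfig:
    """Resolved parameters for a full run.

    The analysis defaults are the panel-standard values: quality 30, depth
    3x, missingness 0.10, MAC 5; target size 100 bp, mean depth in
    [3x, 3000x]; F_ST windows 100 kb / step 50 kb; Tajima windows 100 kb;
    H12 windows of 50 SNPs stepped by 5; top 5 peaks longer than 150 kb;
    outlier alpha 0.01 (second-pass filter MAC 10, 2 kb thinning, CNV
    exclusion); CNV-gene frequency threshold 0.20; 10,000 Monte-Carlo
    simulations.
    """

    out_dir: str = "lenspop_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # inputs (ignored when the simulate stage is on)
    vcf: str | None = None
    depth_tsv: str | None = None
    popmap_tsv: str | None = None
    genes_bed: str | None = None
    categories_tsv: str | None = None
    # simulate
    sim: dict = field(default_factory=dict)
    # filter (first pass)
    min_quality: float = 30.0
    min_mean_depth: float = 3.0
    max_missingness: float = 0.10
    min_allele_count: int = 5
    # cnv
    min_target_size_bp: int = 100
    min_target_depth: float = 3.0
    max_target_depth: float = 3000.0
    pca_components: int | str = "auto"
    hmm: dict = field(default_factory=dict)
    # windows
    fst_window_bp: int = 100_000
    fst_step_bp: int = 50_000
    tajima_window_bp: int = 100_000
    # selection
    h12_window_snps: int = 50
    h12_step_snps: int = 5
    top_peaks: int = 5
    min_peak_length_bp: int = 150_000
    alpha: float = 0.01
    outlier_mac: int = 10
    thin_bp: int = 2_000
    n_pcs: int = 5
    external_outlier_genes: list[str] = field(default_factory=list)
    # diversity / enrichment
    rarefaction_g: int = 10
    min_cluster_freq: float = 0.20
    n_simulations: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    gm = popmap = dm = annotation = None
    if "simulate" in config.stages:
        sim_cfg = SimConfig(seed=_stage_seed(config.seed, "simulate"), **config.sim)
        dataset = simulate_populations(sim_cfg)
        paths = write_dataset(dataset, out / "synthetic", force=True)
        written.update({f"synthetic/{k}": p for k, p in paths.items()})
        gm, popmap, dm = dataset.genotypes, dataset.popmap, dataset.depths
        annotation = dataset.annotation
        manifest["stages"]["simulate"] = {"n_snps": gm.n_sites, "n_samples": gm.n_samples}
    else:
        missing = [
            name for name, p in (
                ("vcf", config.vcf), ("depth_tsv", config.depth_tsv),
                ("popmap_tsv", config.popmap_tsv),
            ) if p is None
        ]
        if missing:
            raise ValueError(
                f"simulate stage disabled but inputs {missing} not provided "
                "(stage 'simulate' or explicit input paths required)"
            )
        gm = lio.read_vcf(config.vcf)
        popmap = PopulationMap.read_tsv(config.popmap_tsv)
        targets, samples, depth = lio.read_depth_tsv(config.depth_tsv)
        dm = DepthMatrix(targets=targets, samples=samples, depth=depth)
        if config.genes_bed and config.categories_tsv:
            annotation = GeneAnnotation.read(config.genes_bed, config.categories_tsv)

    # --- CNV stage first: its regions feed the SNP filter ---
    regions, ndm, calls = [], None, []
    if "cnv" in config.stages:
        dm_f = filter_targets(
            dm, config.min_target_size_bp, config.min_target_depth, config.max_target_depth
        )
        ndm = normalize_depth(dm_f, config.pca_components)
        calls = call_cnvs_hmm(ndm, HmmParams(**config.hmm))
        regions = cnv_regions(calls)
        calls_to_frame(calls).to_csv(out / "cnv_calls.tsv", sep="\t", index=False)
        regions_to_frame(regions).to_csv(out / "cnv_regions.tsv", sep="\t", index=False)
        if regions:
            cnv_frequencies(regions, popmap).to_csv(
                out / "cnv_frequencies.tsv", sep="\t", index=False
            )
            written["cnv_frequencies"] = out / "cnv_frequencies.tsv"
        written["cnv_calls"] = out / "cnv_calls.tsv"
        written["cnv_regions"] = out / "cnv_regions.tsv"
        manifest["stages"]["cnv"] = {
            "n_calls": len(calls),
            "n_regions": len(regions),
            "pca_components_removed": ndm.n_components_removed,
        }

    gm_f = gm
    if "filter" in config.stages:
        exclude = (
            regions_to_frame(regions)[["chrom", "start", "end"]] if regions else None
        )
        params = FilterParams(
            min_quality=config.min_quality,
            min_mean_depth=config.min_mean_depth,
            max_missingness=config.max_missingness,
            min_allele_count=config.min_allele_count,
            exclude_regions=exclude,
        )
        gm_f, report = filter_variants(gm, params)
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        written["filter_report"] = out / "filter_report.tsv"
        manifest["stages"]["filter"] = {
            "input_sites": report.input_sites,
            "output_sites": report.output_sites,
            "removed_by_rule": report.removed_by_rule,
        }

    chrom_sizes = None
    if "simulate" in config.stages:
        chrom_sizes = {c: sim_cfg.chrom_length_bp for c in sim_cfg.chrom_names}

    if "diversity" in config.stages:
        seg = div.segregating_sites(gm_f, popmap)
        rows = []
        for cl in popmap.clusters():
            spec = div.observed_sfs_snp(gm_f, popmap, cl)
            exp = div.expected_sfs_watterson(spec.n, spec.segregating_sites)
            rows.append(
                {
                    "cluster": cl,
                    "segregating_sites": seg[cl],
                    "sfs_n": spec.n,
                    "observed_sfs": ",".join(f"{x:g}" for x in spec.counts),
                    "expected_sfs": ",".join(f"{x:.3f}" for x in exp.counts),
                }
            )
        pd.DataFrame(rows).to_csv(out / "diversity.tsv", sep="\t", index=False)
        written["diversity"] = out / "diversity.tsv"
        try:
            curves = div.rarefied_richness(gm_f, popmap, config.rarefaction_g)
            pd.DataFrame(
                [
                    {
                        "cluster": cl,
                        "g": int(c.g[0]),
                        "allelic_richness": float(c.allelic_richness[0]),
                        "private_richness": float(c.private_richness[0]),
                        "n_loci_used": c.n_loci_used,
                    }
                    for cl, c in curves.items()
                ]
            ).to_csv(out / "rarefaction.tsv", sep="\t", index=False)
            written["rarefaction"] = out / "rarefaction.tsv"
        except ValueError as exc:
            warnings.warn(f"rarefaction skipped: {exc}", stacklevel=2)
        manifest["stages"]["diversity"] = {"segregating_sites": seg}

    if "differentiation" in config.stages:
        fst_mat = pairwise_mean_fst(gm_f, popmap)
        fst_mat.to_csv(out / "pairwise_fst.tsv", sep="\t")
        written["pairwise_fst"] = out / "pairwise_fst.tsv"
        clusters = popmap.clusters()
        if len(clusters) >= 2:
            ps = weir_cockerham_fst(
                gm_f, popmap.samples_in(clusters[0]), popmap.samples_in(clusters[1])
            )
            wins = windowed_fst(ps, config.fst_window_bp, config.fst_step_bp, chrom_sizes)
            pd.DataFrame(
                [(w.chrom, w.start, w.end, w.n_variants, w.value) for w in wins],
                columns=["chrom", "start", "end", "n", "fst"],
            ).to_csv(out / "windowed_fst.tsv", sep="\t", index=False)
            written["windowed_fst"] = out / "windowed_fst.tsv"
        mean_vst = float("nan")
        if ndm is not None and regions:
            vst_mat = pairwise_mean_vst(ndm, regions, popmap)
            vst_mat.to_csv(out / "pairwise_vst.tsv", sep="\t")
            written["pairwise_vst"] = out / "pairwise_vst.tsv"
            vals = vst_mat.to_numpy()
            mean_vst = float(np.nanmean(vals[np.triu_indices_from(vals, k=1)]))
        vals = fst_mat.to_numpy()
        manifest["stages"]["differentiation"] = {
            "mean_pairwise_fst": float(np.nanmean(vals[np.triu_indices_from(vals, k=1)])),
            "mean_pairwise_vst": mean_vst,
        }

    if "structure" in config.stages:
        pca = genotype_pca(gm_f, n_components=min(10, gm_f.n_samples - 1))
        pd.DataFrame(
            pca.scores, index=pca.samples,
            columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
        ).to_csv(out / "genotype_pca.tsv", sep="\t")
        written["genotype_pca"] = out / "genotype_pca.tsv"
        entry = {"genotype_var_frac": [float(v) for v in pca.variance_fraction[:3]]}
        if ndm is not None and regions:
            dpca = depth_pca(ndm, regions, n_components=min(10, len(regions)))
            pd.DataFrame(
                dpca.scores, index=dpca.samples,
                columns=[f"PC{i+1}" for i in range(dpca.scores.shape[1])],
            ).to_csv(out / "depth_pca.tsv", sep="\t")
            written["depth_pca"] = out / "depth_pca.tsv"
            entry["depth_var_frac"] = [float(v) for v in dpca.variance_fraction[:3]]
        manifest["stages"]["structure"] = entry

    if "selection" in config.stages:
        # Tajima's D per cluster on the first-pass-filtered SNPs
        taj_rows = []
        for cl in popmap.clusters():
            if len(popmap.samples_in(cl)) < 4:
                continue
            for w in tajimas_d_windows(gm_f, popmap, cl, config.tajima_window_bp, chrom_sizes):
                taj_rows.append((cl, w.chrom, w.start, w.end, w.n_variants, w.value))
        pd.DataFrame(
            taj_rows, columns=["cluster", "chrom", "start", "end", "S", "tajimas_d"]
        ).to_csv(out / "tajimas_d.tsv", sep="\t", index=False)
        written["tajimas_d"] = out / "tajimas_d.tsv"

        track = h12_scan(gm_f, config.h12_window_snps, config.h12_step_snps)
        peaks = find_peaks(track, config.top_peaks, config.min_peak_length_bp)
        pd.DataFrame(
            [(p.chrom, p.start, p.end, p.max_h12, p.rank) for p in peaks],
            columns=["chrom", "start", "end", "max_h12", "rank"],
        ).to_csv(out / "h12_peaks.tsv", sep="\t", index=False)
        written["h12_peaks"] = out / "h12_peaks.tsv"

        # second-pass filter before the outlier scan
        gm2, _ = filter_variants(
            gm_f,
            FilterParams(
                min_quality=0.0,
                min_mean_depth=config.min_mean_depth,
                max_missingness=1.0,
                min_allele_count=config.outlier_mac,
                exclude_regions=(
                    regions_to_frame(regions)[["chrom", "start", "end"]]
                    if regions else None
                ),
            ),
        )
        gm2 = thin_variants(gm2, config.thin_bp)
        outliers = pca_outlier_scan(
            gm2, n_pcs=min(config.n_pcs, gm2.n_samples - 1), alpha=config.alpha
        )
        outliers.table.to_csv(out / "pca_outliers.tsv", sep="\t", index=False)
        written["pca_outliers"] = out / "pca_outliers.tsv"

        entry = {
            "n_h12_peaks": len(peaks),
            "n_outlier_snps": int(outliers.table["flagged"].sum()),
        }
        if annotation is not None:
            sweep_genes = regions_to_genes(
                [(p.chrom, p.start, p.end) for p in peaks], annotation
            )
            outlier_genes = regions_to_genes(
                None, annotation, snp_hits=outliers.flagged[["chrom", "pos"]]
            )
            method_sets = {"h12": sweep_genes, "pca_outlier": outlier_genes}
            if config.external_outlier_genes:
                method_sets["external"] = set(config.external_outlier_genes)
            consensus = consensus_candidates(method_sets, min_methods=2)
            pd.DataFrame(
                sorted(consensus.candidates), columns=["gene_id"]
            ).to_csv(out / "consensus_genes.tsv", sep="\t", index=False)
            written["consensus_genes"] = out / "consensus_genes.tsv"
            entry.update(
                {
                    "per_method_genes": consensus.per_method,
                    "n_consensus_genes": len(consensus.candidates),
                }
            )
        manifest["stages"]["selection"] = entry

    if "enrichment" in config.stages and annotation is not None and regions:
        per_cluster, global_set = genes_in_cnv_regions(
            regions, annotation, popmap, config.min_cluster_freq
        )
        entry = {"n_affected_genes": len(global_set)}
        if global_set:
            enr = category_enrichment(
                global_set, annotation, config.n_simulations,
                seed=_stage_seed(config.seed, "enrichment"),
            )
            enr.observed.to_csv(out / "category_enrichment.tsv", sep="\t", index=False)
            written["category_enrichment"] = out / "category_enrichment.tsv"
            entry["enrichment_p"] = enr.p_value
            if annotation.resistance_genes():
                res = resistance_overlap(
                    global_set, annotation, config.n_simulations,
                    seed=_stage_seed(config.seed, "resistance"),
                )
                entry["resistance_overlap"] = {
                    "observed": res.observed,
                    "expected": res.expected,
                    "p": res.p_value,
                }
        manifest["stages"]["enrichment"] = entry

    manifest["outputs"] = {str(k): _sha256(Path(p)) for k, p in written.items()}
    with open(out / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
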