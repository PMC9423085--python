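"""The synthetic-panel generator: determinism, population structure,
frequency structure, depth model and file round-trips."""

import numpy as np
import pytest

from lenspop.cnv import filter_targets, normalize_depth
from lenspop.differentiation import pairwise_mean_fst
from lenspop.sim import (
    SimConfig,
    simulate_populations,
    simulate_read_depth,
    simulate_targets,
    write_dataset,
)


def tiny_cfg(**kw):
    base = dict(
        n_clusters=3, samples_per_cluster=10, n_chromosomes=2,
        chrom_length_bp=1_000_000, n_snps=400, n_targets=200,
        n_true_cnvs=4, seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_h12_impossible_rejected(self):
        with pytest.raises(ValueError):
            tiny_cfg(n_snps=60, n_chromosomes=2)

    def test_fst_bounds(self):
        with pytest.raises(ValueError):
            tiny_cfg(fst_between_clusters=1.0)

    def test_selfing_bounds(self):
        with pytest.raises(ValueError):
            tiny_cfg(selfing_rate=1.5)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self, tmp_path):
        d1 = simulate_populations(tiny_cfg(seed=5))
        d2 = simulate_populations(tiny_cfg(seed=5))
        np.testing.assert_array_equal(d1.genotypes.geno, d2.genotypes.geno)
        np.testing.assert_array_equal(d1.depths.depth, d2.depths.depth)
        p1 = write_dataset(d1, tmp_path / "a")
        p2 = write_dataset(d2, tmp_path / "b")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()

    def test_different_seed_differs(self):
        d1 = simulate_populations(tiny_cfg(seed=5))
        d2 = simulate_populations(tiny_cfg(seed=6))
        assert not np.array_equal(d1.genotypes.geno, d2.genotypes.geno)


class TestPopulationStructure:
    def test_complete_selfing_all_homozygous(self):
        ds = simulate_populations(tiny_cfg(selfing_rate=1.0, missing_rate=0.0))
        assert not np.any(ds.genotypes.geno == 1)

    def test_no_differentiation_when_fst_zero(self):
        ds = simulate_populations(tiny_cfg(fst_between_clusters=0.0, n_snps=1000))
        mat = pairwise_mean_fst(ds.genotypes, ds.popmap)
        vals = mat.to_numpy()[np.triu_indices(3, k=1)]
        assert np.all(np.abs(vals) <= 0.02)

    def test_realized_fst_near_target(self):
        cfg = SimConfig(n_clusters=3, samples_per_cluster=30, n_chromosomes=2,
                        chrom_length_bp=2_000_000, n_snps=1500, n_targets=100,
                        fst_between_clusters=0.3, n_true_cnvs=1, seed=1)
        ds = simulate_populations(cfg)
        mat = pairwise_mean_fst(ds.genotypes, ds.popmap)
        mean_fst = np.nanmean(mat.to_numpy()[np.triu_indices(3, k=1)])
        assert 0.15 <= mean_fst <= 0.45

    def test_fst_monotone_in_parameter(self):
        from scipy import stats

        grid = [0.02, 0.08, 0.15, 0.25, 0.4]
        params, realized = [], []
        for rep in range(10):
            for f in grid:
                ds = simulate_populations(
                    tiny_cfg(fst_between_clusters=f, seed=500 + rep, n_snps=300,
                             n_targets=10, n_true_cnvs=1)
                )
                mat = pairwise_mean_fst(ds.genotypes, ds.popmap)
                params.append(f)
                realized.append(np.nanmean(mat.to_numpy()[np.triu_indices(3, k=1)]))
        rho = stats.spearmanr(params, realized).statistic
        assert rho > 0.9

    def test_positions_strictly_increasing(self, small_dataset):
        sites = small_dataset.genotypes.sites
        for _, sub in sites.groupby("chrom"):
            assert np.all(np.diff(sub["pos"].to_numpy()) > 0)

    def test_popmap_covers_every_sample_once(self, small_dataset):
        gm, pm = small_dataset.genotypes, small_dataset.popmap
        assert sorted(pm.samples) == sorted(gm.samples)


class TestCnvStructure:
    def test_min_contiguous_targets(self, small_dataset):
        cfg = small_dataset.config
        for cnv in small_dataset.truth_cnvs:
            assert cnv.n_targets >= cfg.cnv_min_targets
            assert np.all(np.diff(cnv.target_indices) == 1)

    def test_low_frequency_excess(self):
        """CNV carrier frequencies concentrate below 10%, with essentially
        no mass above 40% (the low-frequency excess of deleterious CNVs)."""
        freqs = []
        for seed in range(10):
            ds = simulate_populations(tiny_cfg(seed=seed, n_true_cnvs=20))
            n = ds.genotypes.n_samples
            freqs += [len(c.carriers) / n for c in ds.truth_cnvs]
        freqs = np.asarray(freqs)
        assert (freqs < 0.1).mean() > (freqs > 0.4).mean()


class TestReadDepth:
    def test_noise_free_rows_equal_target_effect(self):
        cfg = tiny_cfg(n_true_cnvs=0, n_batch_components=0,
                       depth_noise_cv=0.0, sample_effect_sd=0.0)
        rng = np.random.default_rng(0)
        targets = simulate_targets(cfg, rng)
        samples = [f"s{i}" for i in range(4)]
        dm = simulate_read_depth([], targets, samples, cfg, rng)
        for i in range(1, 4):
            np.testing.assert_allclose(dm.depth[i], dm.depth[0], rtol=1e-12)
        assert dm.depth.min() > 0

    def test_homozygous_deletion_zeroes_depth(self):
        cfg = tiny_cfg(n_batch_components=0, depth_noise_cv=0.0, sample_effect_sd=0.0)
        rng = np.random.default_rng(1)
        targets = simulate_targets(cfg, rng)
        from lenspop.sim import TruthCnv

        idx = np.arange(10, 15)
        cnv = TruthCnv(
            chrom=str(targets["chrom"].iloc[10]),
            start=int(targets["start"].iloc[10]),
            end=int(targets["end"].iloc[14]),
            state="DEL", target_indices=idx, carriers={"s0": 0.0},
        )
        dm = simulate_read_depth([cnv], targets, ["s0", "s1"], cfg, rng)
        np.testing.assert_allclose(dm.depth[0, 10:15], 0.0, atol=1e-12)

    def test_misaligned_truth_cnv_rejected(self):
        cfg = tiny_cfg()
        rng = np.random.default_rng(2)
        targets = simulate_targets(cfg, rng)
        from lenspop.sim import TruthCnv

        cnv = TruthCnv(chrom=str(targets["chrom"].iloc[0]),
                       start=int(targets["start"].iloc[0]) + 7,  # off-boundary
                       end=int(targets["end"].iloc[4]),
                       state="DEL", target_indices=np.arange(5), carriers={})
        with pytest.raises(ValueError):
            simulate_read_depth([cnv], targets, ["s0"], cfg, rng)

    def test_batch_components_dominate_log_depth(self):
        cfg = SimConfig(n_clusters=5, samples_per_cluster=10, n_chromosomes=2,
                        chrom_length_bp=3_000_000, n_snps=500, n_targets=1000,
                        n_true_cnvs=0, n_batch_components=2, seed=7)
        ds = simulate_populations(cfg)
        X = np.log(ds.depths.depth + 1)
        Xc = X - X.mean(axis=0, keepdims=True)
        s = np.linalg.svd(Xc, compute_uv=False)
        assert (s[:2] ** 2).sum() / (s**2).sum() > 0.5


class TestWriteDataset:
    def test_refuses_overwrite(self, tmp_path, small_dataset):
        write_dataset(small_dataset, tmp_path)
        with pytest.raises(FileExistsError):
            write_dataset(small_dataset, tmp_path)
        write_dataset(small_dataset, tmp_path, force=True)  # allowed

    def test_truth_bed_record_count(self, tmp_path, small_dataset):
        paths = write_dataset(small_dataset, tmp_path / "d")
        n_lines = len(paths["truth_cnvs"].read_text().strip().splitlines())
        assert n_lines == len(small_dataset.truth_cnvs)

    def test_popmap_roundtrip(self, tmp_path, small_dataset):
        from lenspop.genotypes import PopulationMap

        paths = write_dataset(small_dataset, tmp_path / "d")
        back = PopulationMap.read_tsv(paths["popmap"])
        assert back.assignments == small_dataset.popmap.assignments

    def test_annotation_roundtrip(self, tmp_path, small_dataset):
        from lenspop.annotation import GeneAnnotation

        paths = write_dataset(small_dataset, tmp_path / "d")
        back = GeneAnnotation.read(paths["genes"], paths["categories"])
        orig = small_dataset.annotation
        assert back.gene_ids == orig.gene_ids
        assert back.resistance_genes() == orig.resistance_genes()
        for g in orig.gene_ids[:20]:
            assert sorted(back.categories_of(g)) == sorted(orig.categories_of(g))
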