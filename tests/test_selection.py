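"""Tajima's D, H12 scanning and peak finding, the PCA outlier scan, and the
multi-method consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lenspop.annotation import GeneAnnotation
from lenspop.genotypes import PopulationMap
from lenspop.selection import (
    H12Window,
    consensus_candidates,
    find_peaks,
    h12_from_frequencies,
    h12_scan,
    pca_outlier_scan,
    regions_to_genes,
    tajimas_d,
    tajimas_d_windows,
)

from conftest import make_gm
from oracles import h12_tally, tajimas_d_direct


def haplo_gm(haplotypes, positions=None):
    """GenotypeMatrix of fully homozygous samples from 0/1 haplotypes."""
    hap = np.asarray(haplotypes, dtype=np.int8)
    return make_gm(2 * hap, positions=positions)


class TestTajimasD:
    def test_window_without_segregation_missing(self):
        assert np.isnan(tajimas_d([0, 0], [20, 20]))

    def test_matches_direct_oracle(self):
        rng = np.random.default_rng(0)
        n = 20
        for _ in range(50):
            vectors = []
            for _ in range(100):
                k = rng.integers(0, n + 1)
                v = np.zeros(n, dtype=int)
                v[rng.choice(n, size=k, replace=False)] = 1
                vectors.append(v.tolist())
            expected = tajimas_d_direct(vectors)
            counts = np.array([sum(v) for v in vectors])
            got = tajimas_d(counts, np.full(100, n))
            assert got == pytest.approx(expected, abs=1e-10)

    def test_windows_flag_sparse(self, small_dataset):
        gm, pm = small_dataset.genotypes, small_dataset.popmap
        cl = pm.clusters()[0]
        wins = tajimas_d_windows(gm, pm, cl, window=100_000)
        for w in wins:
            if w.n_variants < 3:
                assert np.isnan(w.value)
            else:
                assert np.isfinite(w.value)

    def test_small_cluster_rejected(self, small_dataset):
        pm = PopulationMap.from_pairs(
            [(s, "solo" if i < 2 else "rest")
             for i, s in enumerate(small_dataset.genotypes.samples)]
        )
        with pytest.raises(ValueError):
            tajimas_d_windows(small_dataset.genotypes, pm, "solo")


class TestH12:
    def test_identical_haplotypes_one(self):
        assert h12_from_frequencies([1.0]) == pytest.approx(1.0)

    def test_five_distinct(self):
        assert h12_from_frequencies([0.2] * 5) == pytest.approx(0.28)

    def test_top_two_pooling(self):
        assert h12_from_frequencies([0.5, 0.3, 0.2]) == pytest.approx(0.68)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_scan_matches_tally_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_samples, n_sites = rng.integers(4, 12), 60
        hap = rng.integers(0, 2, size=(n_samples, n_sites))
        gm = haplo_gm(hap)
        wins = h12_scan(gm, window_snps=50, step_snps=5)
        for w in wins:
            i0 = w.center_index - 25
            cols = slice(i0, i0 + 50)
            expected = h12_tally([tuple(row) for row in hap[:, cols]])
            assert w.h12 == pytest.approx(expected, abs=1e-12)

    def test_short_chromosome_skipped(self):
        gm = haplo_gm(np.zeros((4, 10), dtype=int))
        with pytest.warns(UserWarning):
            assert h12_scan(gm, window_snps=50) == []

    def test_het_sites_reduce_to_major_allele(self):
        hap = np.zeros((6, 60), dtype=np.int8)
        geno = 2 * hap
        geno[0, :5] = 1  # a few heterozygous calls, below the 20% cutoff
        gm = make_gm(geno)
        wins = h12_scan(gm, window_snps=50, step_snps=50)
        assert wins and wins[0].h12 == pytest.approx(1.0)

    def test_high_missing_haplotypes_dropped(self):
        geno = np.zeros((5, 50), dtype=np.int8)
        geno[0, :20] = 1  # 40% het -> dropped
        gm = make_gm(geno)
        wins = h12_scan(gm, window_snps=50, step_snps=50)
        assert wins[0].n_haplotypes == 4


def _window(chrom, center_bp, span, h12):
    return H12Window(chrom=chrom, center_index=0, center_bp=center_bp,
                     span=span, frequencies=np.array([1.0]), h12=h12,
                     n_haplotypes=10)


class TestFindPeaks:
    def _track(self, spans_values, chrom="chr1"):
        return [
            _window(chrom, (s[0] + s[1]) // 2, s, v) for s, v in spans_values
        ]

    def test_long_run_one_peak(self):
        base = [((i * 10_000, i * 10_000 + 50_000), 0.02) for i in range(60)]
        bump = [((600_000 + i * 10_000, 650_000 + i * 10_000 + 150_000), 0.5)
                for i in range(10)]
        peaks = find_peaks(self._track(base + bump))
        assert len(peaks) == 1
        assert peaks[0].end - peaks[0].start > 150_000

    def test_short_run_discarded(self):
        base = [((i * 10_000, i * 10_000 + 40_000), 0.02) for i in range(60)]
        bump = [((700_000, 800_000), 0.5)]  # 100 kb span only
        peaks = find_peaks(self._track(base + bump), min_length_bp=150_000)
        assert peaks == []

    def test_top_k_by_height(self):
        # a long low track with 7 separated qualifying peaks of rising height
        base = [((i * 10_000, i * 10_000 + 40_000), 0.01) for i in range(700)]
        track = self._track(base)
        for j in range(7):
            start = 3_000_000 + j * 400_000
            track.append(_window("chr1", start + 100_000, (start, start + 200_000),
                                 0.3 + 0.05 * j))
        track.sort(key=lambda w: w.center_bp)
        peaks = find_peaks(track, top_k=5, min_length_bp=150_000)
        assert len(peaks) == 5
        heights = [p.max_h12 for p in peaks]
        assert heights == sorted(heights, reverse=True)
        assert min(heights) == pytest.approx(0.4)

    def test_peaks_disjoint_and_ranked(self, small_dataset):
        track = h12_scan(small_dataset.genotypes)
        peaks = find_peaks(track, top_k=5, min_length_bp=50_000)
        by_chrom = {}
        for p in peaks:
            assert p.end - p.start > 50_000
            by_chrom.setdefault(p.chrom, []).append(p)
        for plist in by_chrom.values():
            assert len(plist) <= 5
            plist.sort(key=lambda p: p.start)
            for p1, p2 in zip(plist, plist[1:]):
                assert p1.end <= p2.start

    def test_empty_track(self):
        assert find_peaks([]) == []


class TestPcaOutlierScan:
    def test_alpha_zero_empty(self, small_dataset):
        out = pca_outlier_scan(small_dataset.genotypes, n_pcs=2, alpha=0.0)
        assert len(out.flagged) == 0

    def test_flagged_respect_alpha(self, small_dataset):
        out = pca_outlier_scan(small_dataset.genotypes, n_pcs=2, alpha=0.01)
        assert (out.flagged["p_adj"] < 0.01).all()

    def test_monomorphic_dropped(self):
        geno = np.zeros((10, 30), dtype=np.int8)
        geno[:, 0] = np.arange(10) % 3
        gm = make_gm(geno)
        out = pca_outlier_scan(gm, n_pcs=1, robust=False)
        assert len(out.table) == 1

    def test_invalid_n_pcs(self, small_dataset):
        with pytest.raises(ValueError):
            pca_outlier_scan(small_dataset.genotypes, n_pcs=0)


class TestConsensusAndGeneMapping:
    @pytest.fixture
    def annotation(self):
        table = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [1000, 8000, 1000],
                "end": [4000, 12_000, 4000],
                "categories": [["Enzymes"], [], ["Enzymes"]],
                "resistance": [False, True, False],
            }
        )
        return GeneAnnotation(table=table)

    def test_peak_covering_two_genes(self, annotation):
        genes = regions_to_genes([("chr1", 500, 10_000)], annotation)
        assert genes == {"g1", "g2"}

    def test_snp_inside_gene(self, annotation):
        hits = pd.DataFrame({"chrom": ["chr1"], "pos": [2000]})
        assert regions_to_genes(None, annotation, snp_hits=hits) == {"g1"}

    def test_intergenic_snp_empty(self, annotation):
        hits = pd.DataFrame({"chrom": ["chr1"], "pos": [6000]})
        assert regions_to_genes(None, annotation, snp_hits=hits) == set()

    def test_consensus_two_of_three(self):
        rep = consensus_candidates(
            {"m1": {"g1", "g2"}, "m2": {"g2", "g3"}, "m3": {"g4"}}, min_methods=2
        )
        assert rep.candidates == {"g2"}
        assert rep.per_method == {"m1": 2, "m2": 2, "m3": 1}

    def test_min_methods_one_is_union(self):
        rep = consensus_candidates({"m1": {"g1"}, "m2": {"g2"}}, min_methods=1)
        assert rep.candidates == {"g1", "g2"}

    def test_disjoint_sets_empty(self):
        rep = consensus_candidates({"m1": {"g1"}, "m2": {"g2"}}, min_methods=2)
        assert rep.candidates == set()

    def test_min_methods_exceeding_sets_rejected(self):
        with pytest.raises(ValueError):
            consensus_candidates({"m1": set(), "m2": set()}, min_methods=3)
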