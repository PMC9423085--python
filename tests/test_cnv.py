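"""Exome-depth CNV discovery: target filtering, PCA normalization, HMM
decoding, region merging, frequencies, burden and chromosome correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lenspop.cnv import (
    DEL, DIPLOID, DUP,
    CnvCall, DepthMatrix, HmmParams, NormalizedDepthMatrix,
    call_cnvs_hmm, cnv_burden, cnv_chromosome_correlation, cnv_frequencies,
    cnv_regions, filter_targets, normalize_depth, state_posteriors, viterbi_path,
)
from lenspop.genotypes import PopulationMap

from oracles import viterbi_brute


def make_dm(depth, chrom=None, starts=None, length=200):
    depth = np.asarray(depth, dtype=float)
    n_s, n_t = depth.shape
    starts = np.arange(n_t) * 1000 if starts is None else np.asarray(starts)
    targets = pd.DataFrame(
        {
            "chrom": chrom or ["chr1"] * n_t,
            "start": starts,
            "end": starts + length,
        }
    )
    return DepthMatrix(targets=targets, samples=[f"s{i}" for i in range(n_s)], depth=depth)


def make_ndm(z, chrom=None):
    z = np.asarray(z, dtype=float)
    n_s, n_t = z.shape
    starts = np.arange(n_t) * 1000
    targets = pd.DataFrame(
        {"chrom": chrom or ["chr1"] * n_t, "start": starts, "end": starts + 200}
    )
    return NormalizedDepthMatrix(
        targets=targets, samples=[f"s{i}" for i in range(n_s)], z=z,
        n_components_removed=0,
    )


class TestFilterTargets:
    def test_short_target_dropped(self):
        dm = make_dm(np.full((3, 2), 10.0), length=200)
        dm.targets.loc[0, "end"] = dm.targets.loc[0, "start"] + 80
        out = filter_targets(dm)
        assert out.n_targets == 1

    def test_extreme_depth_dropped(self):
        depth = np.full((3, 3), 10.0)
        depth[:, 1] = 3500.0  # too high
        depth[:, 2] = 1.0     # too low
        out = filter_targets(make_dm(depth))
        assert out.n_targets == 1

    def test_six_target_fixture(self):
        depth = np.full((4, 6), 10.0)
        depth[:, 2] = 4000.0
        dm = make_dm(depth)
        dm.targets.loc[4, "end"] = dm.targets.loc[4, "start"] + 50
        out = filter_targets(dm)
        assert out.n_targets == 4

    def test_all_dropped_is_error(self):
        with pytest.raises(ValueError):
            filter_targets(make_dm(np.full((2, 2), 1.0)))


class TestNormalizeDepth:
    def test_constant_matrix_all_zero(self):
        ndm = normalize_depth(make_dm(np.full((5, 6), 7.0)), n_components=1)
        np.testing.assert_array_equal(ndm.z, 0.0)

    def test_rank_one_exactly_removed(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(0.5, 2.0, size=8)
        v = rng.uniform(5, 50, size=12)
        ndm = normalize_depth(make_dm(np.outer(u, v)), n_components=1)
        assert np.max(np.abs(ndm.z)) < 1e-8

    def test_auto_removes_batch_components(self, small_dataset):
        ndm = normalize_depth(small_dataset.depths, "auto")
        assert ndm.n_components_removed >= 2

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            normalize_depth(make_dm(np.random.default_rng(1).uniform(1, 2, (4, 6))), 4)


class TestHmm:
    def test_all_zero_no_calls(self):
        assert call_cnvs_hmm(make_ndm(np.zeros((3, 10)))) == []

    def test_strong_deletion_called(self):
        z = np.zeros((2, 9))
        z[0, 2:7] = -4.0
        calls = call_cnvs_hmm(make_ndm(z))
        assert len(calls) == 1
        c = calls[0]
        assert (c.sample, c.state, c.n_targets) == ("s0", "DEL", 5)
        assert c.mean_z < 0 and 0 < c.quality <= 1

    def test_duplication_sign(self):
        z = np.zeros((1, 8))
        z[0, 1:7] = 4.0
        (c,) = call_cnvs_hmm(make_ndm(z))
        assert c.state == "DUP" and c.mean_z > 0

    def test_nonfinite_rejected(self):
        z = np.zeros((1, 4))
        z[0, 1] = np.nan
        with pytest.raises(ValueError):
            call_cnvs_hmm(make_ndm(z))

    @given(st.integers(min_value=1, max_value=6), st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_viterbi_matches_enumeration(self, T, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 2.5, size=T)
        params = HmmParams()
        with np.errstate(divide="ignore"):
            log_trans = np.log(params.transition_matrix())
            log_init = np.log(params.initial_probs())
        expected = viterbi_brute(z, log_init, log_trans,
                                 params.emission_means(), params.emission_sd)
        np.testing.assert_array_equal(viterbi_path(z, params), expected)

    def test_posteriors_normalized(self):
        rng = np.random.default_rng(3)
        post = state_posteriors(rng.normal(0, 2, 20), HmmParams())
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_merging_conserves_state_assignments(self):
        rng = np.random.default_rng(7)
        z = rng.normal(0, 2.5, size=(6, 40))
        ndm = make_ndm(z)
        params = HmmParams()
        calls = call_cnvs_hmm(ndm, params)
        n_from_calls = sum(c.n_targets for c in calls)
        n_from_paths = sum(
            int(np.sum(viterbi_path(z[i], params) != DIPLOID)) for i in range(6)
        )
        assert n_from_calls == n_from_paths


class TestRegions:
    def _call(self, sample, start, end, state="DEL", chrom="chr1"):
        return CnvCall(sample=sample, chrom=chrom, start=start, end=end,
                       state=state, n_targets=3, mean_z=-3.0 if state == "DEL" else 3.0,
                       quality=0.99)

    def test_identical_calls_merge(self):
        regions = cnv_regions([self._call("a", 0, 5000), self._call("b", 0, 5000)])
        assert len(regions) == 1
        assert regions[0].del_carriers == {"a", "b"}

    def test_del_dup_overlap_one_region_both_states(self):
        regions = cnv_regions(
            [self._call("a", 0, 5000, "DEL"), self._call("b", 3000, 9000, "DUP")]
        )
        assert len(regions) == 1
        assert regions[0].del_carriers == {"a"} and regions[0].dup_carriers == {"b"}

    def test_disjoint_calls_distinct_regions(self):
        calls = [self._call("a", i * 10_000, i * 10_000 + 2000) for i in range(4)]
        assert len(cnv_regions(calls)) == 4

    def test_frequencies_and_private(self):
        popmap = PopulationMap.from_pairs(
            [(f"s{i}", "c1" if i < 4 else "c2") for i in range(8)]
        )
        regions = cnv_regions([self._call("s0", 0, 5000)])
        freqs = cnv_frequencies(regions, popmap)
        row = freqs.loc[freqs["cluster"] == "c1"].iloc[0]
        assert row["freq_del"] == 0.25 and row["freq_any"] == 0.25
        assert row["private_to"] == "c1"

    def test_not_private_when_shared(self):
        popmap = PopulationMap.from_pairs(
            [(f"s{i}", "c1" if i < 2 else "c2") for i in range(4)]
        )
        regions = cnv_regions([self._call("s0", 0, 5000), self._call("s2", 0, 5000)])
        freqs = cnv_frequencies(regions, popmap)
        assert freqs["private_to"].isna().all() or (freqs["private_to"] is None)

    def test_unknown_sample_rejected(self):
        popmap = PopulationMap.from_pairs([("s0", "c1"), ("s1", "c1")])
        with pytest.raises(KeyError):
            cnv_frequencies(cnv_regions([self._call("ghost", 0, 1000)]), popmap)


class TestBurden:
    def _calls_for(self, sample, lengths, state="DEL"):
        return [
            CnvCall(sample=sample, chrom="chr1", start=i * 100_000,
                    end=i * 100_000 + L, state=state, n_targets=5,
                    mean_z=-3.0, quality=0.99)
            for i, L in enumerate(lengths)
        ]

    def test_median_length(self):
        popmap = PopulationMap.from_pairs([("a", "c1"), ("b", "c1"), ("c", "c2"), ("d", "c2")])
        calls = self._calls_for("a", [10_000, 30_000])
        res = cnv_burden(calls, popmap)
        row = res.per_accession.set_index("sample").loc["a"]
        assert row["median_len"] == 20_000
        assert row["n_del"] == 2 and row["n_dup"] == 0

    def test_null_kruskal_rarely_significant(self):
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 100
        for _ in range(reps):
            popmap = PopulationMap.from_pairs(
                [(f"s{i}", str(i % 3)) for i in range(30)]
            )
            calls = []
            for i in range(30):
                n = rng.poisson(4)
                calls += self._calls_for(f"s{i}", rng.integers(5_000, 50_000, size=n))
            res = cnv_burden(calls, popmap, metrics=("n_cnv",))
            if res.kruskal["n_cnv"][1] < 0.01:
                rejections += 1
        assert rejections <= 5  # >= 95% of reps non-significant

    def test_shifted_cluster_detected(self):
        rng = np.random.default_rng(1)
        popmap = PopulationMap.from_pairs(
            [(f"s{i}", str(i // 30)) for i in range(90)]
        )
        calls = []
        for i in range(90):
            shift = 50_000 if i < 30 else 0
            lengths = rng.integers(10_000, 40_000, size=5) + shift
            calls += self._calls_for(f"s{i}", lengths)
        res = cnv_burden(calls, popmap, metrics=("median_len",))
        pw = res.pairwise["median_len"]
        involving0 = pw[(pw["cluster_a"] == "0") | (pw["cluster_b"] == "0")]
        assert (involving0["p_holm"] < 0.01).all()


class TestChromosomeCorrelation:
    def _regions(self, counts):
        from lenspop.cnv import CnvRegion

        out = []
        for c, n in counts.items():
            for i in range(n):
                out.append(CnvRegion(region_id=f"{c}_{i}", chrom=c,
                                     start=i * 1000, end=i * 1000 + 500))
        return out

    def test_proportional_counts_rho_one(self):
        sizes = {f"chr{i}": (i + 1) * 1_000_000 for i in range(5)}
        counts = {c: (i + 1) * 2 for i, c in enumerate(sizes)}
        res = cnv_chromosome_correlation(self._regions(counts), sizes, counts)
        assert res.rho_size == pytest.approx(1.0)

    def test_reversed_counts_rho_minus_one(self):
        sizes = {f"chr{i}": (i + 1) * 1_000_000 for i in range(5)}
        counts = {c: (5 - i) * 2 for i, c in enumerate(sizes)}
        res = cnv_chromosome_correlation(self._regions(counts), sizes, {c: 1 for c in sizes})
        assert res.rho_size == pytest.approx(-1.0)

    def test_too_few_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            cnv_chromosome_correlation([], {"chr1": 1, "chr2": 2, "chr3": 3}, {})
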