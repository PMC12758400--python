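"""Bayes factors, differential regions, Fisher tests, Z-scores, UPGMA."""

import numpy as np
import pandas as pd
import pytest

from replichrom import diffrt
from replichrom.diffrt import (DifferentialRegion, RTZscores,
                               WindowComparison, bayes_factor_windows,
                               call_differential_regions, cluster_cell_types,
                               domain_summary, domain_profile_correlations,
                               earlier_totals, rms_distance_matrix,
                               zscore_tracks)
from replichrom.repli import TimingTrack

# frozen fine-grid oracle (step 1e-4, range [-15, 15], prior sd 2):
# A with s=90, f=10 per bin (x3 bins) vs B reversed
BF_270_30_VS_30_270 = 94.73684158448397


class TestBayesFactor:
    def test_both_empty_windows_null_equivalent(self):
        bf = bayes_factor_windows([0], [0], [0], [0])
        assert abs(bf[0]) < 1e-5   # grid-truncation residual only

    def test_identical_populated_windows_favor_null(self):
        bf = bayes_factor_windows([600], [600], [600], [600])
        assert bf[0] < 0           # Occam penalty of the extra parameter

    def test_matches_frozen_fine_grid_oracle(self):
        bf = bayes_factor_windows([270], [30], [30], [270])
        assert bf[0] > 2
        assert bf[0] == pytest.approx(BF_270_30_VS_30_270, abs=1e-6)

    def test_label_swap_symmetric(self):
        rng = np.random.default_rng(4)
        S1, F1 = rng.integers(0, 400, 20), rng.integers(0, 400, 20)
        S2, F2 = rng.integers(0, 400, 20), rng.integers(0, 400, 20)
        np.testing.assert_allclose(
            bayes_factor_windows(S1, F1, S2, F2),
            bayes_factor_windows(S2, F2, S1, F1), atol=1e-10)


def _comparison(centers, bf, dirs, delta=None, chrom="c"):
    centers = np.asarray(centers)
    bf = np.asarray(bf, float)
    dirs = np.asarray(dirs, object)
    if delta is None:
        delta = np.where(dirs == "A_earlier", 0.3,
                         np.where(dirs == "B_earlier", -0.3, 0.0))
    return WindowComparison("A", "B", 1000, {chrom: centers},
                            {chrom: delta}, {chrom: np.zeros(len(centers))},
                            {chrom: bf}, {chrom: dirs})


def _oracle_regions(centers, bf, dirs, seed_bf=1.0, extend_bf=0.5,
                    max_gap=3000, min_len=20_000, step=1000):
    """Brute-force interval-merge oracle, independent of the implementation:
    expand each qualifying window to its bp extent, union per direction,
    merge nearby intervals, keep those containing a seed and long enough."""
    out = []
    for want in ("A_earlier", "B_earlier"):
        # runs of consecutive centers with extend-level support
        runs = []
        cur = None
        for c, b, d in zip(centers, bf, dirs):
            ok = b >= extend_bf and d == want
            if ok and cur is not None and c == cur[-1][-1] + 1:
                cur.append((b, c))
            elif ok:
                cur = [(b, c)]
                runs.append(cur)
            else:
                cur = None
        runs = [r for r in runs if any(b >= seed_bf for b, _ in r)]
        ivs = [((r[0][1] - 1) * step, (r[-1][1] + 2) * step) for r in runs]
        merged = []
        for s, e in sorted(ivs):
            if merged and s - merged[-1][1] <= max_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        out += [(s, e, want) for s, e in merged if e - s >= min_len]
    return sorted(out)


class TestRegionCalling:
    def test_long_seed_run_yields_one_region(self):
        centers = np.arange(10, 35)   # 25 consecutive windows
        comp = _comparison(centers, [2.0] * 25, ["A_earlier"] * 25)
        regions = call_differential_regions(comp)
        assert len(regions) == 1
        assert regions[0].length >= 25_000
        assert regions[0].direction == "A_earlier"

    def test_short_run_below_20kb_discarded(self):
        centers = np.arange(10, 20)   # 10 windows -> 12 kb span
        comp = _comparison(centers, [5.0] * 10, ["A_earlier"] * 10)
        assert call_differential_regions(comp) == []

    def test_subthreshold_gap_merged(self):
        # two seed runs split by a 2-window sub-threshold gap merge into one
        centers = np.arange(0, 30)
        bf = np.full(30, 2.0)
        bf[13:15] = 0.1
        dirs = np.array(["A_earlier"] * 30, dtype=object)
        comp = _comparison(centers, bf, dirs)
        regions = call_differential_regions(comp)
        oracle = _oracle_regions(centers, bf, dirs)
        assert [(r.start, r.end, r.direction) for r in regions] == oracle
        assert len(regions) == 1

    def test_randomized_vectors_match_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(25):
            n = 300
            centers = np.arange(1, n + 1)
            bf = rng.choice([0.0, 0.6, 1.5], size=n,
                            p=[0.55, 0.25, 0.2])
            dirs = rng.choice(["A_earlier", "B_earlier", "none"], size=n,
                              p=[0.45, 0.45, 0.1]).astype(object)
            comp = _comparison(centers, bf, dirs)
            got = [(r.start, r.end, r.direction)
                   for r in call_differential_regions(comp)]
            assert sorted(got) == _oracle_regions(centers, bf, dirs), trial

    def test_every_region_satisfies_contract(self):
        rng = np.random.default_rng(12)
        n = 500
        comp = _comparison(np.arange(1, n + 1),
                           rng.uniform(0, 2, n),
                           rng.choice(["A_earlier", "B_earlier"],
                                      n).astype(object))
        for r in call_differential_regions(comp):
            assert r.length >= 20_000
            assert r.direction in ("A_earlier", "B_earlier")

    def test_unsorted_input_rejected(self):
        comp = _comparison([5, 3, 4], [2.0] * 3, ["A_earlier"] * 3)
        with pytest.raises(ValueError, match="not sorted"):
            call_differential_regions(comp)


class TestEarlierTotals:
    def test_kb_and_fraction_single_region(self, layout):
        # one 25 kb A-earlier region on the 800 kb 2L arm
        regions = [DifferentialRegion("chr2", 100_000, 125_000,
                                      "A_earlier", 3.0, 0.4)]
        df = earlier_totals(regions, layout).set_index("unit")
        row = df.loc["2L_arm"]
        assert row["a_earlier_kb"] == 25
        assert row["a_fraction"] == pytest.approx(25_000 / 800_000)

    def test_symmetric_fisher_table_p_one(self):
        from replichrom.stats import fisher_2x2
        assert fisher_2x2([[10, 10], [10, 10]]).p_value == pytest.approx(1.0)

    def test_region_outside_layout_rejected(self, layout):
        bad = [DifferentialRegion("chr4", 0, 999_000, "A_earlier", 1, 0.1)]
        with pytest.raises(ValueError, match="outside layout"):
            earlier_totals(bad, layout)


def _toy_timing(cell, rt_by_chrom):
    centers = {c: np.arange(1, len(v) + 1) for c, v in rt_by_chrom.items()}
    sds = {c: np.zeros(len(v)) for c, v in rt_by_chrom.items()}
    return TimingTrack(cell, 1000, centers,
                       {c: np.asarray(v, float)
                        for c, v in rt_by_chrom.items()}, sds)


class TestZscores:
    def test_columns_standardized(self, timing_tracks):
        _, timings = timing_tracks
        zs = zscore_tracks(timings)
        for ct in zs.cell_types:
            assert abs(zs.z[ct].mean()) < 1e-12
            assert zs.z[ct].std() == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_zscores(self):
        x = np.array([0.2, 0.4, 0.9])
        mu, sd = x.mean(), x.std()
        tracks = {"A": _toy_timing("A", {"c": x}),
                  "B": _toy_timing("B", {"c": x[::-1]})}
        zs = zscore_tracks(tracks)
        np.testing.assert_allclose(zs.z["A"], (x - mu) / sd, atol=1e-12)

    def test_identical_cell_types_correlate_perfectly(self, layout):
        rng = np.random.default_rng(5)
        n = layout.n_bins("chr2", 1000) - 2
        vals = rng.uniform(-0.5, 0.5, n)
        tracks = {"A": _toy_timing("A", {"chr2": vals}),
                  "B": _toy_timing("B", {"chr2": vals})}
        zs = zscore_tracks(tracks)
        summary = domain_summary(zs, layout)
        corr = domain_profile_correlations(summary, zs.cell_types)
        assert corr["pearson_r"][0] == pytest.approx(1.0)

    def test_zero_variance_track_rejected(self):
        tracks = {"A": _toy_timing("A", {"c": np.full(20, 0.5)}),
                  "B": _toy_timing("B", {"c": np.arange(20) / 20})}
        with pytest.raises(ValueError, match="zero-variance"):
            zscore_tracks(tracks)


def _zs_from_matrix(mat, names):
    """RTZscores straight from a windows x cells matrix (pre-standardized
    columns not required for distance tests)."""
    return RTZscores(list(names), np.array(["c"] * mat.shape[0], dtype=object),
                     np.arange(mat.shape[0]) * 1000 + 500,
                     {n: mat[:, i] for i, n in enumerate(names)},
                     {n: mat[:, i] for i, n in enumerate(names)})


def _manual_upgma(D):
    """Hand-executed UPGMA: returns merge order as frozensets with heights."""
    clusters = {i: frozenset([i]) for i in range(len(D))}
    dist = {(i, j): D[i, j] for i in range(len(D)) for j in range(len(D))
            if i < j}
    merges = []
    nxt = len(D)
    while len(clusters) > 1:
        (i, j), d = min(dist.items(), key=lambda kv: kv[1])
        merged = clusters[i] | clusters[j]
        merges.append((clusters[i], clusters[j], d))
        del clusters[i], clusters[j]
        new = {}
        for (a, b), v in dist.items():
            if len({a, b} & {i, j}) == 0:
                new[(a, b)] = v
        for k, ck in clusters.items():
            # average linkage: mean over all cross pairs
            num = sum(D[x, y] for x in merged for y in ck)
            new[(min(k, nxt), max(k, nxt))] = num / (len(merged) * len(ck))
        clusters[nxt] = merged
        # rebuild distances involving the new cluster id against D indices
        dist = new
        nxt += 1
    return merges


class TestClustering:
    def test_distance_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(6)
        zs = _zs_from_matrix(rng.normal(size=(100, 3)), ["a", "b", "c"])
        D = rms_distance_matrix(zs)
        np.testing.assert_array_equal(D, D.T)
        np.testing.assert_array_equal(np.diag(D), 0)

    def test_identical_profiles_merge_first(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=200)
        mat = np.stack([base, base, rng.normal(size=200)], axis=1)
        tree = cluster_cell_types(_zs_from_matrix(mat, ["a", "b", "out"]))
        assert tree.distance[0, 1] == 0.0
        # first linkage row merges leaves 0 and 1 at height 0
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}
        assert tree.linkage[0, 2] == 0.0

    def test_four_profiles_match_manual_upgma(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(50, 4))
        names = ["w", "x", "y", "z"]
        zs = _zs_from_matrix(mat, names)
        D = rms_distance_matrix(zs)
        merges = _manual_upgma(D)
        tree = cluster_cell_types(zs)
        # merge heights agree with the hand-executed algorithm
        got_heights = sorted(tree.linkage[:, 2])
        exp_heights = sorted(m[2] for m in merges)
        np.testing.assert_allclose(got_heights, exp_heights, atol=1e-12)
        for name in names:
            assert name in tree.newick

    def test_planted_outlier_isolated_at_top_split(self):
        rng = np.random.default_rng(9)
        shared = rng.normal(size=400)
        mat = np.stack([shared + 0.3 * rng.normal(size=400)
                        for _ in range(3)] +
                       [rng.normal(size=400)], axis=1)
        mat = (mat - mat.mean(0)) / mat.std(0)
        names = ["a", "b", "c", "outlier"]
        tree = cluster_cell_types(_zs_from_matrix(mat, names))
        # the root merge joins the outlier singleton with the rest
        last = tree.linkage[-1, :2].astype(int)
        # cluster ids < n are leaves; the singleton side must be leaf 3
        assert 3 in last
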