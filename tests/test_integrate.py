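"""Expression categories, DE sets, meta-profiles, integration statistics.

The classical tests (Welch t, paired t, Fisher exact, Pearson/Spearman)
are checked against from-scratch formula / enumeration oracles.
"""

import numpy as np
import pandas as pd
import pytest

from replichrom import integrate as I
from replichrom import stats as S
from replichrom.diffrt import DifferentialRegion
from replichrom.genome import BinnedTrack, Domain, GenomeLayout
from replichrom.repli import TimingTrack


# ---------------------------------------------------------------------------
# independent statistical oracles
# ---------------------------------------------------------------------------

def welch_oracle(x, y):
    """Welch's t from the textbook formulas (two-sided p via scipy's
    survival function of the t distribution only)."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def paired_oracle(x, y):
    from scipy.stats import t as tdist

    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    p = 2 * tdist.sf(abs(t), n - 1)
    return t, p


def fisher_oracle(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins."""
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.dot(xc, yc) /
                 np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def spearman_oracle(x, y):
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    return pearson_oracle(rx, ry)


class TestStatOracles:
    def test_welch_matches_formula(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1, 1, 200)
        y = rng.normal(0, 1, 200)
        got = S.welch_t(x, y)
        t, df, p = welch_oracle(x, y)
        assert got.statistic == pytest.approx(t, abs=1e-9)
        assert got.df == pytest.approx(df, abs=1e-9)
        assert got.p_value == pytest.approx(p, abs=1e-9)

    def test_paired_matches_formula(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 1, 60)
        y = x + rng.normal(0, 0.3, 60)
        got = S.paired_t(x, y)
        t, p = paired_oracle(x, y)
        assert got.statistic == pytest.approx(t, abs=1e-9)
        assert got.p_value == pytest.approx(p, abs=1e-9)

    def test_paired_exact_offset_flagged(self):
        x = np.arange(10.0)
        got = S.paired_t(x + 0.5, x)
        assert got.flag == "exact_offset"
        assert got.statistic == np.inf and got.p_value == 0.0

    @pytest.mark.parametrize("table", [
        [[10, 10], [10, 10]],
        [[100, 50], [300, 300]],
        [[3, 9], [14, 2]],
        [[0, 5], [8, 1]],
    ])
    def test_fisher_matches_enumeration(self, table):
        got = S.fisher_2x2(table)
        assert got.p_value == pytest.approx(fisher_oracle(table), abs=1e-9)

    def test_symmetric_fisher_table_is_one(self):
        assert S.fisher_2x2([[10, 10], [10, 10]]).p_value == \
            pytest.approx(1.0, abs=1e-12)

    def test_correlations_match_formula(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        y = 0.5 * x + rng.normal(size=80)
        assert S.pearson(x, y).statistic == \
            pytest.approx(pearson_oracle(x, y), abs=1e-9)
        assert S.spearman(x, y).statistic == \
            pytest.approx(spearman_oracle(x, y), abs=1e-9)


class TestClassifyExpression:
    def test_printed_marker_cpms_classify_on_off(self):
        # germline marker ~700 CPM on in one cell type, ~2 CPM off in the
        # other; adhesion marker 256.04 vs 0.17 likewise
        cpm = pd.Series({"ago3_A": 697.21, "ago3_B": 2.11,
                         "cadN_B": 256.04, "cadN_A": 0.17,
                         "g1": 10, "g2": 20, "g3": 30, "g4": 40})
        cat = I.classify_expression(cpm)
        assert cat["ago3_A"] != "off" and cat["ago3_B"] == "off"
        assert cat["cadN_B"] != "off" and cat["cadN_A"] == "off"

    def test_threshold_is_strictly_above_five(self):
        cat = I.classify_expression(pd.Series({"a": 5.0, "b": 5.01,
                                               "c": 6, "d": 7}))
        assert cat["a"] == "off" and cat["b"] == "low"

    def test_nine_on_genes_make_equal_tertiles(self):
        cpm = pd.Series({f"g{i}": 10.0 + i for i in range(9)})
        cat = I.classify_expression(cpm)
        assert cat.value_counts()[["low", "medium", "high"]].tolist() == \
            [3, 3, 3]
        assert cat["g0"] == "low" and cat["g8"] == "high"

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        cpm = pd.Series(rng.lognormal(1.5, 2, 500),
                        index=[f"g{i}" for i in range(500)])
        cat = I.classify_expression(cpm)
        counts = cat.value_counts()
        assert counts.sum() == 500
        on = counts.reindex(["low", "medium", "high"]).fillna(0)
        assert on.max() - on.min() <= 1


class TestPhaseReweight:
    def test_balanced_phases_unit_weights(self):
        w = I.phase_reweight({"G1": 100, "S": 100, "G2M": 100})
        assert all(v == pytest.approx(1.0) for v in w.values())

    def test_hand_computed_weights(self):
        w = I.phase_reweight({"G1": 200, "S": 100, "G2M": 100})
        assert w["G1"] == pytest.approx(2 / 3)
        assert w["S"] == pytest.approx(4 / 3)
        assert w["G2M"] == pytest.approx(4 / 3)

    def test_weights_average_one_over_cells(self):
        counts = {"G1": 137, "S": 41, "G2M": 88}
        w = I.phase_reweight(counts)
        total = sum(counts.values())
        mean_w = sum(n * w[p] for p, n in counts.items()) / total
        assert mean_w == pytest.approx(1.0, abs=1e-12)

    def test_empty_phase_rejected(self):
        with pytest.raises(ValueError, match="G2M"):
            I.phase_reweight({"G1": 5, "S": 5, "G2M": 0})


class TestDEFilter:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "s_value"],
                            index=[f"g{i}" for i in range(len(rows))])

    def test_printed_marker_effects_land_in_sets(self):
        # log2FC 3.91 s 0 -> A-enriched; log2FC -6.01 s 0 -> B-enriched
        t = self._table([(3.91, 0.0), (-6.01, 0.0)])
        a, b = I.de_filter(t)
        assert "g0" in a and "g1" in b

    def test_large_s_value_excluded(self):
        t = self._table([(2.0, 1e-3)])
        a, b = I.de_filter(t)
        assert len(a) == len(b) == 0

    def test_small_fold_change_excluded(self):
        t = self._table([(0.3, 0.0)])
        a, b = I.de_filter(t)
        assert len(a) == len(b) == 0

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(4)
        t = self._table(list(zip(rng.normal(0, 2, 300),
                                 rng.uniform(0, 1e-3, 300))))
        sizes = []
        for fc in (1.2, 1.5, 2.0, 3.0):
            a, b = I.de_filter(t, fc_min=fc)
            sizes.append(len(a) + len(b))
        assert sizes == sorted(sizes, reverse=True)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="s_value"):
            I.de_filter(pd.DataFrame({"log2fc": [1.0]}))


def _flat_layout(n_steps=5000, chrom="chrA"):
    return GenomeLayout({chrom: n_steps * 20},
                        [Domain("a", chrom, 0, n_steps * 20,
                                "autosome_arm")], (chrom,))


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss",
                                       "start", "end", "biotype"])


class TestMetaprofiles:
    def test_minus_strand_sampling_is_reversed(self):
        n = 500
        v = np.arange(n, dtype=float)
        track = BinnedTrack(20, {"chrA": v})
        genes = _genes([("plus", "chrA", "+", 5000, 5000, 7000,
                         "protein_coding"),
                        ("minus", "chrA", "-", 5000, 3001, 5001,
                         "protein_coding")])
        cats = pd.Series({"plus": "high", "minus": "high"})
        prof = I.tss_metaprofile(track, genes, cats, flank=400)
        curves = prof.curves["high"]
        # mean of a ramp and its reverse is constant
        np.testing.assert_allclose(curves, curves[::-1], atol=1e-9)

    def test_uniform_track_flat_profile(self):
        track = BinnedTrack(20, {"chrA": np.full(2000, 2.0)})
        genes = _genes([(f"g{i}", "chrA", "+", 4000 + 200 * i,
                         4000 + 200 * i, 6000 + 200 * i, "protein_coding")
                        for i in range(40)])
        cats = pd.Series({f"g{i}": ("off" if i % 2 else "high")
                          for i in range(40)})
        prof = I.tss_metaprofile(track, genes, cats)
        np.testing.assert_allclose(prof.curves["high"], 2.0)
        assert prof.tests["high"].p_value == pytest.approx(1.0) or \
            np.isnan(prof.tests["high"].p_value)

    def test_welch_at_profile_max_matches_oracle(self):
        rng = np.random.default_rng(5)
        n = 200
        track_vals = np.full(6000, 1.0)
        genes, cats = [], {}
        # plant per-gene offsets by giving each gene its own step value
        for i in range(n):
            pos = 1000 + 25 * i
            track_vals[pos] = 1.0 + rng.normal(1.0, 1.0)
            genes.append((f"hi{i}", "chrA", "+", pos * 20, pos * 20,
                          pos * 20 + 2000, "protein_coding"))
            cats[f"hi{i}"] = "high"
        for i in range(n):
            pos = 1000 + 25 * i + 12
            track_vals[pos] = 1.0 + rng.normal(0.0, 1.0)
            genes.append((f"off{i}", "chrA", "+", pos * 20, pos * 20,
                          pos * 20 + 2000, "protein_coding"))
            cats[f"off{i}"] = "off"
        track = BinnedTrack(20, {"chrA": track_vals})
        prof = I.tss_metaprofile(track, _genes(genes), pd.Series(cats),
                                 flank=0)
        t, df, p = welch_oracle(prof.per_gene["high"],
                                np.array([track_vals[1000 + 25 * i + 12]
                                          for i in range(n)]))
        assert prof.tests["high"].statistic == pytest.approx(t, abs=1e-9)
        assert prof.tests["high"].p_value == pytest.approx(p, abs=1e-9)

    def test_genebody_constant_track(self):
        track = BinnedTrack(20, {"chrA": np.full(5000, 1.7)})
        genes = _genes([("g", "chrA", "+", 20_000, 20_000, 24_000,
                         "protein_coding")])
        prof, means = I.genebody_profile(track, genes)
        assert means["g"] == pytest.approx(1.7)
        np.testing.assert_allclose(prof.curves["all"], 1.7)

    def test_genebody_identical_cells_null_test(self):
        rng = np.random.default_rng(6)
        v = rng.uniform(0, 2, 5000)
        track = BinnedTrack(20, {"chrA": v})
        genes = _genes([(f"g{i}", "chrA", "+", 10_000 + 3000 * i,
                         10_000 + 3000 * i, 12_500 + 3000 * i,
                         "protein_coding") for i in range(20)])
        _, means = I.genebody_profile(track, genes)
        res = I.genebody_between_cells(means, means.copy())
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_genebody_no_eligible_genes(self):
        track = BinnedTrack(20, {"chrA": np.zeros(100)})
        genes = _genes([("g", "chrA", "+", 100, 100, 300, "protein_coding")])
        with pytest.raises(ValueError, match="no eligible"):
            I.genebody_profile(track, genes)


class TestCellSpecific:
    def test_label_rules(self):
        lay = _flat_layout(3)
        fe_a = BinnedTrack(20, {"chrA": np.array([0.3, 0.2, -0.3])})
        fe_b = BinnedTrack(20, {"chrA": np.array([-0.3, -0.3, 0.3])})
        labels, pct = I.cellspec_enrichment_domains(fe_a, fe_b, lay)
        assert list(labels["chrA"]) == ["A_specific", "none", "B_specific"]
        assert pct.iloc[0]["pct_A_specific"] == pytest.approx(100 / 3)

    def test_grid_mismatch_rejected(self):
        a = BinnedTrack(20, {"chrA": np.zeros(5)})
        b = BinnedTrack(20, {"chrA": np.zeros(6)})
        with pytest.raises(ValueError, match="match"):
            I.cellspec_enrichment_domains(a, b, _flat_layout(5))

    def test_region_paired_test_matches_oracle(self):
        rng = np.random.default_rng(7)
        n_steps = 5000
        va = rng.normal(0.3, 0.2, n_steps)
        vb = va - 0.5 + rng.normal(0, 0.05, n_steps)
        fe_a = BinnedTrack(20, {"chrA": va})
        fe_b = BinnedTrack(20, {"chrA": vb})
        regions = [DifferentialRegion("chrA", i * 10_000, i * 10_000 + 4000,
                                      "A_earlier", 2.0, 0.4)
                   for i in range(10)]
        got = I.region_paired_fe_test(fe_a, fe_b, regions)
        step = 20
        ma = [va[r.start // step: r.end // step].mean() for r in regions]
        mb = [vb[r.start // step: r.end // step].mean() for r in regions]
        t, p = paired_oracle(ma, mb)
        assert got.statistic == pytest.approx(t, abs=1e-9)
        assert got.p_value == pytest.approx(p, abs=1e-9)

    def test_exact_offset_regions_flagged(self):
        va = np.full(3000, 0.5)
        fe_a = BinnedTrack(20, {"chrA": va})
        fe_b = BinnedTrack(20, {"chrA": va - 0.5})
        regions = [DifferentialRegion("chrA", i * 6000, i * 6000 + 3000,
                                      "A_earlier", 2.0, 0.4)
                   for i in range(10)]
        got = I.region_paired_fe_test(fe_a, fe_b, regions)
        assert got.flag == "exact_offset"


class TestRTIntegration:
    def _timing(self, rt, chrom="chrA"):
        n = len(rt)
        return TimingTrack("A", 1000, {chrom: np.arange(1, n + 1)},
                           {chrom: np.asarray(rt, float)},
                           {chrom: np.zeros(n)})

    def test_rows_ordered_early_to_late(self):
        tt = self._timing([0.8, -0.8, 0.1])
        marks = {"m": BinnedTrack(20, {"chrA": np.zeros(5000)})}
        mat = I.rt_chromatin_matrix(tt, marks)
        assert mat["rt"].tolist() == sorted(mat["rt"], reverse=True)

    def test_constant_mark_column(self):
        tt = self._timing(np.linspace(-0.5, 0.5, 30))
        marks = {"m": BinnedTrack(20, {"chrA": np.full(5000, 0.7)})}
        mat = I.rt_chromatin_matrix(tt, marks)
        np.testing.assert_allclose(mat["fe_m"], 0.7)

    def test_mark_tracking_rt_gives_high_rank_correlation(self):
        rng = np.random.default_rng(8)
        n = 200
        rt = rng.uniform(-1, 1, n)
        fe_steps = np.zeros((n + 2) * 50)
        for i, r in enumerate(rt):
            fe_steps[(i + 1) * 50: (i + 2) * 50] = r + \
                rng.normal(0, 0.05, 50)
        tt = self._timing(rt)
        marks = {"k4": BinnedTrack(20, {"chrA": fe_steps})}
        mat = I.rt_chromatin_matrix(tt, marks)
        rho = spearman_oracle(-np.arange(len(mat)), mat["fe_k4"])
        assert rho > 0.9
        assert S.spearman(-np.arange(len(mat)), mat["fe_k4"]).statistic == \
            pytest.approx(rho, abs=1e-9)

    def test_gene_classification_matches_overlap_oracle(self):
        rt = np.linspace(0.5, -0.5, 60)
        tracks = {"A": self._timing(rt), "B": self._timing(-rt)}
        regions = [DifferentialRegion("chrA", 5000, 26_000, "A_earlier",
                                      2.0, 0.4),
                   DifferentialRegion("chrA", 40_000, 61_000, "B_earlier",
                                      2.0, -0.4)]
        rng = np.random.default_rng(9)
        rows = []
        for i in range(10):
            start = int(rng.integers(2000, 55_000))
            end = start + int(rng.integers(1000, 8000))
            rows.append((f"g{i}", "chrA", "+", start, start, end,
                         "protein_coding"))
        genes = _genes(rows)
        table = I.gene_rt_classification(tracks, regions, genes).set_index(
            "gene_id")
        for _, g in genes.iterrows():
            span = g["end"] - g["start"]
            expected = "neither"
            for r in regions:
                ov = max(0, min(r.end, g["end"]) - max(r.start, g["start"]))
                if ov > span / 2:
                    expected = r.direction
            assert table.loc[g["gene_id"], "rt_class"] == expected

    def test_fully_contained_gene_inherits_region_class(self):
        tracks = {"A": self._timing(np.full(60, 0.3)),
                  "B": self._timing(np.full(60, -0.3))}
        regions = [DifferentialRegion("chrA", 5000, 30_000, "A_earlier",
                                      2.0, 0.6)]
        genes = _genes([("in", "chrA", "+", 10_000, 10_000, 20_000,
                         "protein_coding"),
                        ("out", "chrA", "+", 40_000, 40_000, 50_000,
                         "lncRNA")])
        table = I.gene_rt_classification(tracks, regions,
                                         genes).set_index("gene_id")
        assert table.loc["in", "rt_class"] == "A_earlier"
        assert table.loc["out", "rt_class"] == "neither"


class TestXARatio:
    def _layout(self):
        return GenomeLayout(
            {"chrA": 100_000, "chrX": 100_000},
            [Domain("a", "chrA", 0, 100_000, "autosome_arm"),
             Domain("x", "chrX", 0, 100_000, "chrX")], ("chrA",))

    def _inputs(self, x_cpms, a_cpms):
        genes = _genes(
            [(f"x{i}", "chrX", "+", 10, 10, 1000, "protein_coding")
             for i in range(len(x_cpms))] +
            [(f"a{i}", "chrA", "+", 10, 10, 1000, "protein_coding")
             for i in range(len(a_cpms))])
        table = pd.DataFrame({
            "gene_id": [f"x{i}" for i in range(len(x_cpms))] +
                       [f"a{i}" for i in range(len(a_cpms))],
            "cpm": list(x_cpms) + list(a_cpms)})
        return genes, table

    def test_matched_distributions_give_unity(self):
        genes, table = self._inputs([10, 20, 30], [10, 20, 30])
        assert I.xa_ratio(table, genes, self._layout(), "cpm") == \
            pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        genes, table = self._inputs([8, 10, 12], [18, 20, 22])
        assert I.xa_ratio(table, genes, self._layout(), "cpm") == \
            pytest.approx(0.5)

    def test_no_expressed_x_genes_warns_nan(self):
        genes, table = self._inputs([1, 2], [10, 20, 30])
        with pytest.warns(UserWarning, match="X-linked"):
            assert np.isnan(I.xa_ratio(table, genes, self._layout(), "cpm"))
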