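"""Transcriptome / chromatin / replication-timing integration.

Expression categories follow the CPM rule: a gene is "on" when CPM > 5
(strict), and on-genes split into equal-count tertiles (low / medium /
high) by CPM rank, ties broken by gene id.  Differential expression uses
externally supplied posterior log2 fold changes with s-values (estimated
false sign rates): enriched means |fold change| > 1.5 and s < 1e-4.

Meta-profiles sample chromatin tracks on the 20 bp grid around TSSs
(strand-oriented) or along length-rescaled gene bodies, with Welch tests
against the "off" category at each on-category's profile maximum.
Cell-specific chromatin is the +-0.2 log2FE rule; replication-timing
integration assigns each gene the mean score of its overlapping windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffrt import DifferentialRegion
from .genome import BinnedTrack, GenomeLayout
from .repli import TimingTrack
from .stats import TestResult, paired_t, welch_t

logger = logging.getLogger(__name__)

CATEGORIES = ("off", "low", "medium", "high")
CPM_ON_THRESHOLD = 5.0


# ---------------------------------------------------------------------------
# expression categories and DE sets
# ---------------------------------------------------------------------------

def classify_expression(cpm: pd.Series, threshold: float = CPM_ON_THRESHOLD
                        ) -> pd.Series:
    """off if CPM <= threshold; on-genes ranked into equal tertiles.

    ``cpm`` is indexed by gene id; ties in CPM break by gene id so the
    partition is deterministic.  Tertile sizes differ by at most one
    (lower tertiles take the extra genes).
    """
    if (cpm < 0).any():
        raise ValueError("negative CPM")
    cat = pd.Series("off", index=cpm.index, dtype=object)
    on = cpm[cpm > threshold]
    # rank by (CPM, gene id): sort by id first, then a stable sort by value
    on_sorted = on.sort_index().sort_values(kind="stable")
    parts = np.array_split(on_sorted.index.to_numpy(), 3)
    for label, idx in zip(("low", "medium", "high"), parts):
        cat.loc[idx] = label
    return cat


def phase_reweight(phase_counts: dict[str, int],
                   target: dict[str, float] | None = None) -> dict[str, float]:
    """Per-cell weight per cell-cycle phase equalizing phase composition.

    Weight for a cell in phase phi = target_fraction / observed_fraction
    (target defaults to 1/3 each for G1, S, G2M).  The weighted mean over
    cells is exactly 1.
    """
    if target is None:
        target = {p: 1.0 / 3.0 for p in phase_counts}
    total = sum(phase_counts.values())
    weights: dict[str, float] = {}
    for phase, n in phase_counts.items():
        if n <= 0:
            raise ValueError(f"phase {phase!r} has no cells")
        weights[phase] = target[phase] / (n / total)
    return weights


def reweighted_cpm(counts: pd.DataFrame, phase_labels: pd.Series) -> pd.Series:
    """Weighted pseudobulk CPM from a genes x cells count matrix and
    per-cell phase labels."""
    w = phase_reweight(phase_labels.value_counts().to_dict())
    cell_w = phase_labels.map(w)
    pooled = counts.mul(cell_w, axis=1).sum(axis=1)
    return pooled / pooled.sum() * 1e6


def de_filter(table: pd.DataFrame, fc_min: float = 1.5, s_max: float = 1e-4,
              lfc_col: str = "log2fc", s_col: str = "s_value"
              ) -> tuple[pd.Index, pd.Index]:
    """Split genes into (A-enriched, B-enriched) index sets.

    A-enriched: log2fc > log2(fc_min) and s < s_max; B symmetric.
    """
    for col in (lfc_col, s_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    cut = np.log2(fc_min)
    sig = table[s_col] < s_max
    a = table.index[(table[lfc_col] > cut) & sig]
    b = table.index[(table[lfc_col] < -cut) & sig]
    logger.info("de_filter: %d A-enriched, %d B-enriched", len(a), len(b))
    return a, b


# ---------------------------------------------------------------------------
# meta-profiles
# ---------------------------------------------------------------------------

@dataclass
class MetaProfile:
    positions: np.ndarray                # bp from TSS, or scaled-body bins
    curves: dict[str, np.ndarray]        # category -> mean signal
    per_gene: dict[str, np.ndarray]      # category -> per-gene values at max
    tests: dict[str, TestResult]         # category -> Welch vs "off"


def _sample_track(track: BinnedTrack, chrom: str, positions: np.ndarray
                  ) -> np.ndarray:
    v = track.data[chrom]
    idx = (positions // track.step).astype(int)
    idx = np.clip(idx, 0, len(v) - 1)
    return v[idx]


def tss_metaprofile(track: BinnedTrack, genes: pd.DataFrame,
                    categories: pd.Series, flank: int = 1000
                    ) -> MetaProfile:
    """Mean signal around TSSs per expression category, plus Welch tests.

    The signal is sampled on the track's 20 bp grid over TSS +- flank and
    reversed for minus-strand genes.  At the position of each on-category's
    maximum mean, the per-gene values are compared with the "off"
    category's values at that same position (two-sided Welch t).
    """
    step = track.step
    rel = np.arange(-flank, flank + 1, step)
    mats: dict[str, list[np.ndarray]] = {c: [] for c in CATEGORIES}
    for _, g in genes.iterrows():
        cat = categories.get(g["gene_id"], None)
        if cat is None:
            continue
        chrom = g["chrom"]
        if chrom not in track.data:
            continue
        pos = g["tss"] + (rel if g["strand"] == "+" else -rel)
        if pos.min() < 0 or pos.max() >= len(track.data[chrom]) * step:
            continue
        mats[cat].append(_sample_track(track, chrom, pos))
    curves: dict[str, np.ndarray] = {}
    stacks: dict[str, np.ndarray] = {}
    for cat, rowlist in mats.items():
        if rowlist:
            stacks[cat] = np.vstack(rowlist)
            curves[cat] = stacks[cat].mean(axis=0)
    tests: dict[str, TestResult] = {}
    per_gene: dict[str, np.ndarray] = {}
    off = stacks.get("off")
    for cat in ("low", "medium", "high"):
        if cat not in stacks:
            continue
        imax = int(np.argmax(curves[cat]))
        per_gene[cat] = stacks[cat][:, imax]
        if off is None or len(off) < 2 or len(per_gene[cat]) < 2:
            warnings.warn(f"category {cat!r}: too few genes for Welch test")
            continue
        tests[cat] = welch_t(per_gene[cat], off[:, imax])
    return MetaProfile(rel, curves, per_gene, tests)


def genebody_profile(track: BinnedTrack, genes: pd.DataFrame,
                     categories: pd.Series | None = None,
                     body_bins: int = 100, flank_bins: int = 25
                     ) -> tuple[MetaProfile, pd.Series]:
    """Scaled gene-body profile plus per-gene mean body signal.

    Bodies are rescaled to ``body_bins`` positions by linear
    interpolation; flanks stay in fixed 20 bp steps.  Genes shorter than
    ``body_bins * step`` are skipped (count logged).  Returns the profile
    and a per-gene Series of mean body signal (for between-cell Welch
    tests).
    """
    step = track.step
    min_span = body_bins * step
    rows = []
    means = {}
    skipped = 0
    for _, g in genes.iterrows():
        chrom = g["chrom"]
        span = g["end"] - g["start"]
        if chrom not in track.data or span < min_span:
            skipped += 1
            continue
        L = len(track.data[chrom]) * step
        if g["start"] - flank_bins * step < 0 or \
                g["end"] + flank_bins * step >= L:
            skipped += 1
            continue
        body_pos = np.linspace(g["start"], g["end"] - 1, body_bins)
        up = g["start"] - np.arange(flank_bins, 0, -1) * step
        down = g["end"] + np.arange(flank_bins) * step
        pos = np.concatenate([up, body_pos, down])
        vals = _sample_track(track, chrom, pos.astype(int))
        if g["strand"] == "-":
            vals = vals[::-1]
        rows.append(vals)
        means[g["gene_id"]] = float(
            vals[flank_bins:flank_bins + body_bins].mean())
    if not rows:
        raise ValueError("no eligible genes for gene-body profile")
    if skipped:
        logger.info("genebody_profile: skipped %d short/edge genes", skipped)
    mat = np.vstack(rows)
    positions = np.arange(-flank_bins, body_bins + flank_bins)
    curves = {"all": mat.mean(axis=0)}
    if categories is not None:
        ids = list(means)
        cats = categories.reindex(ids)
        for cat in CATEGORIES:
            sel = (cats == cat).to_numpy()
            if sel.any():
                curves[cat] = mat[sel].mean(axis=0)
    return (MetaProfile(positions, curves, {}, {}),
            pd.Series(means, name="body_mean"))


def genebody_between_cells(body_a: pd.Series, body_b: pd.Series) -> TestResult:
    """Welch's t on matched gene sets' mean body signals (A vs B)."""
    shared = body_a.index.intersection(body_b.index)
    return welch_t(body_a.loc[shared], body_b.loc[shared])


# ---------------------------------------------------------------------------
# cell-specific enrichment domains
# ---------------------------------------------------------------------------

def cellspec_enrichment_domains(fe_a: BinnedTrack, fe_b: BinnedTrack,
                                layout: GenomeLayout, hi: float = 0.2,
                                lo: float = -0.2
                                ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Label steps A-specific (FE_A > hi and FE_B < lo) / B-specific
    (symmetric), and tabulate the labeled percentage per domain."""
    if fe_a.step != fe_b.step or set(fe_a.data) != set(fe_b.data):
        raise ValueError("log2FE grids do not match")
    labels: dict[str, np.ndarray] = {}
    for c in fe_a.data:
        if len(fe_a.data[c]) != len(fe_b.data[c]):
            raise ValueError("log2FE grids do not match")
        lab = np.full(len(fe_a.data[c]), "none", dtype=object)
        lab[(fe_a.data[c] > hi) & (fe_b.data[c] < lo)] = "A_specific"
        lab[(fe_b.data[c] > hi) & (fe_a.data[c] < lo)] = "B_specific"
        labels[c] = lab
    rows = []
    step = fe_a.step
    for d in layout.domains:
        lo_i = -(-d.start // step)
        hi_i = -(-d.end // step)
        seg = labels[d.chrom][lo_i:hi_i]
        n = len(seg)
        if n == 0:
            continue
        rows.append({
            "domain": d.name, "class": d.cls, "n_steps": n,
            "pct_A_specific": 100.0 * float((seg == "A_specific").sum()) / n,
            "pct_B_specific": 100.0 * float((seg == "B_specific").sum()) / n,
        })
    return labels, pd.DataFrame(rows)


def region_paired_fe_test(fe_a: BinnedTrack, fe_b: BinnedTrack,
                          regions: list[DifferentialRegion]) -> TestResult:
    """Paired t-test of per-region mean log2FE, A vs B, paired by region."""
    if len(regions) < 2:
        raise ValueError("need >= 2 regions for the paired test")
    step = fe_a.step
    ma, mb = [], []
    for r in regions:
        sl = slice(r.start // step, -(-r.end // step))
        ma.append(float(fe_a.data[r.chrom][sl].mean()))
        mb.append(float(fe_b.data[r.chrom][sl].mean()))
    return paired_t(ma, mb)


# ---------------------------------------------------------------------------
# replication-timing integration
# ---------------------------------------------------------------------------

def rt_chromatin_matrix(timing: TimingTrack, marks: dict[str, BinnedTrack],
                        genes: pd.DataFrame | None = None,
                        categories: pd.Series | None = None) -> pd.DataFrame:
    """Windows ordered early -> late with per-mark mean FE (20 bp steps
    averaged into each 1 kb window) and TSS counts per expression
    category."""
    rows = []
    for chrom in timing.chroms():
        centers = timing.centers[chrom]
        if len(centers) == 0:
            continue
        df = pd.DataFrame({
            "chrom": chrom,
            "start": centers * timing.step,
            "end": (centers + 1) * timing.step,
            "rt": timing.rt[chrom],
        })
        for mark, fe in marks.items():
            ratio = timing.step // fe.step
            vals = fe.data[chrom]
            n_full = len(vals) // ratio
            means = vals[:n_full * ratio].reshape(n_full, ratio).mean(axis=1)
            idx = np.clip(centers, 0, n_full - 1)
            df[f"fe_{mark}"] = means[idx]
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    if genes is not None and categories is not None:
        for cat in CATEGORIES:
            out[f"n_tss_{cat}"] = 0
        gi = genes.set_index("gene_id")
        for gene_id, cat in categories.items():
            if gene_id not in gi.index:
                continue
            g = gi.loc[gene_id]
            hit = (out["chrom"] == g["chrom"]) & \
                  (out["start"] <= g["tss"]) & (g["tss"] < out["end"])
            out.loc[hit, f"n_tss_{cat}"] += 1
    out = out.sort_values(["rt", "chrom", "start"],
                          ascending=[False, True, True],
                          kind="stable").reset_index(drop=True)
    return out


def gene_rt_classification(tracks: dict[str, TimingTrack],
                           regions: list[DifferentialRegion],
                           genes: pd.DataFrame,
                           de_sets: tuple[pd.Index, pd.Index] | None = None
                           ) -> pd.DataFrame:
    """Per-gene timing and differential-region membership.

    Gene RT per cell type = mean RT of overlapping 3 kb windows; region
    class (A_earlier / B_earlier / neither) by majority span overlap.
    Genes on contigs lacking timing are skipped with a log line.
    """
    names = list(tracks)
    rows = []
    skipped = 0
    for _, g in genes.iterrows():
        chrom = g["chrom"]
        tr0 = tracks[names[0]]
        if chrom not in tr0.centers or len(tr0.centers[chrom]) == 0:
            skipped += 1
            continue
        row = {"gene_id": g["gene_id"], "chrom": chrom,
               "biotype": g.get("biotype", "other")}
        step = tr0.step
        ok = True
        for ct in names:
            tr = tracks[ct]
            centers = tr.centers[chrom]
            w_start = (centers - 1) * step
            w_end = (centers + 2) * step
            hit = (w_start < g["end"]) & (g["start"] < w_end)
            if not hit.any():
                ok = False
                break
            row[f"rt_{ct}"] = float(tr.rt[chrom][hit].mean())
        if not ok:
            skipped += 1
            continue
        span = g["end"] - g["start"]
        best = "neither"
        for want in ("A_earlier", "B_earlier"):
            ov = sum(max(0, min(r.end, g["end"]) - max(r.start, g["start"]))
                     for r in regions
                     if r.chrom == chrom and r.direction == want)
            if ov > span / 2:
                best = want
        row["rt_class"] = best
        if de_sets is not None:
            a_set, b_set = de_sets
            row["de_status"] = ("A" if g["gene_id"] in a_set else
                                "B" if g["gene_id"] in b_set else "none")
        rows.append(row)
    if skipped:
        logger.info("gene_rt_classification: skipped %d genes without timing",
                    skipped)
    return pd.DataFrame(rows)


def biotype_proportions(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Proportion of biotypes within each replication-timing class."""
    out = (gene_table.groupby(["rt_class", "biotype"]).size()
           .rename("n").reset_index())
    totals = out.groupby("rt_class")["n"].transform("sum")
    out["proportion"] = out["n"] / totals
    return out


def xa_ratio(table: pd.DataFrame, genes: pd.DataFrame, layout: GenomeLayout,
             cpm_col: str, threshold: float = CPM_ON_THRESHOLD) -> float:
    """X-to-autosome median CPM ratio over expressed ("on") genes."""
    merged = genes.merge(table, on="gene_id")
    on = merged[merged[cpm_col] > threshold]
    x_chroms = {d.chrom for d in layout.domains if d.cls == "chrX"}
    x = on[on["chrom"].isin(x_chroms)][cpm_col]
    a = on[on["chrom"].isin(layout.autosome_names)][cpm_col]
    if len(x) == 0:
        warnings.warn("no expressed X-linked genes; X:A ratio undefined")
        return float("nan")
    if len(a) == 0:
        warnings.warn("no expressed autosomal genes; X:A ratio undefined")
        return float("nan")
    return float(np.median(x) / np.median(a))
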