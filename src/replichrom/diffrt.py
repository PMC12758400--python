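"""Cross-cell-type replication timing comparison.

Per 3 kb window the shared-timing null (one logit parameter for both cell
types) is compared with the cell-specific full model (independent
parameters) through the marginal-likelihood ratio

    BF10 = log10( [int L_A pi dtheta * int L_B pi dtheta]
                  / int L_A L_B pi dtheta )

computed by trapezoid quadrature on the same theta grid as the timing
score, with log-sum-exp guarding underflow.  Windows with strong evidence
for different timing are merged by two-tier nested peak calling into
differential regions of at least 20 kb, which feed the per-domain totals,
Fisher tests, genome-wide RT Z-scores, domain summaries and average-linkage
(UPGMA) clustering of cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import fisher_exact, pearsonr

from .genome import GenomeLayout
from .repli import (DEFAULT_GRID, DEFAULT_PRIOR_SD, TimingTrack, WindowTable,
                    _log_binom_kernel, posterior_timing_score, theta_grid)
from .trackio import Region

LOG10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def bayes_factor_windows(SA, FA, SB, FB, prior_sd: float = DEFAULT_PRIOR_SD,
                         grid: tuple[float, float, int] = DEFAULT_GRID
                         ) -> np.ndarray:
    """log10 Bayes factor (full vs shared timing) per window, vectorized.

    Symmetric in the two cell types; both-empty windows give exactly 0
    (all three marginals coincide).
    """
    SA = np.atleast_1d(np.asarray(SA, float))
    FA = np.atleast_1d(np.asarray(FA, float))
    SB = np.atleast_1d(np.asarray(SB, float))
    FB = np.atleast_1d(np.asarray(FB, float))
    theta = theta_grid(grid)
    h = theta[1] - theta[0]
    log_tw = np.log(np.full(len(theta), h))
    log_tw[0] -= np.log(2.0)
    log_tw[-1] -= np.log(2.0)
    log_prior = (-0.5 * (theta / prior_sd) ** 2
                 - 0.5 * np.log(2 * np.pi) - np.log(prior_sd))
    llA = _log_binom_kernel(SA, FA, theta)
    llB = _log_binom_kernel(SB, FB, theta)
    log_mA = logsumexp(llA + log_prior + log_tw, axis=1)
    log_mB = logsumexp(llB + log_prior + log_tw, axis=1)
    log_m0 = logsumexp(llA + llB + log_prior + log_tw, axis=1)
    return (log_mA + log_mB - log_m0) / LOG10


@dataclass
class WindowComparison:
    """Per-window Bayes factors and directions for a cell-type pair."""

    cell_a: str
    cell_b: str
    step: int
    centers: dict[str, np.ndarray]
    rt_a: dict[str, np.ndarray]
    rt_b: dict[str, np.ndarray]
    bf10: dict[str, np.ndarray]
    direction: dict[str, np.ndarray]   # "A_earlier" | "B_earlier" | "none"

    def chroms(self) -> list[str]:
        return list(self.centers)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms():
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "center_bp": self.centers[chrom] * self.step + self.step // 2,
                f"rt_{self.cell_a}": self.rt_a[chrom],
                f"rt_{self.cell_b}": self.rt_b[chrom],
                "log10_bf": self.bf10[chrom],
                "direction": self.direction[chrom],
            }))
        return pd.concat(rows, ignore_index=True)


def compare_windows(wa: WindowTable, wb: WindowTable,
                    prior_sd: float = DEFAULT_PRIOR_SD,
                    grid: tuple[float, float, int] = DEFAULT_GRID,
                    min_delta: float = 1e-3) -> WindowComparison:
    """Bayes-factor comparison of two cell types over shared windows.

    Direction is the sign of the RT difference; windows with
    ``|RT_A - RT_B| < min_delta`` are "none" even when the Bayes factor
    passes, preventing zero-effect regions.
    """
    centers: dict[str, np.ndarray] = {}
    rt_a: dict[str, np.ndarray] = {}
    rt_b: dict[str, np.ndarray] = {}
    bf: dict[str, np.ndarray] = {}
    direction: dict[str, np.ndarray] = {}
    for chrom in wa.chroms():
        if chrom not in wb.centers:
            continue
        ca, cb = wa.centers[chrom], wb.centers[chrom]
        shared, ia, ib = np.intersect1d(ca, cb, return_indices=True)
        if len(shared) == 0:
            continue
        SA, FA = wa.S[chrom][ia], wa.F[chrom][ia]
        SB, FB = wb.S[chrom][ib], wb.F[chrom][ib]
        ra, _ = posterior_timing_score(SA, FA, prior_sd, grid)
        rb, _ = posterior_timing_score(SB, FB, prior_sd, grid)
        b = bayes_factor_windows(SA, FA, SB, FB, prior_sd, grid)
        d = np.where(np.abs(ra - rb) < min_delta, "none",
                     np.where(ra > rb, "A_earlier", "B_earlier"))
        centers[chrom] = shared
        rt_a[chrom], rt_b[chrom] = ra, rb
        bf[chrom] = b
        direction[chrom] = d
    return WindowComparison(wa.cell_type, wb.cell_type, wa.step, centers,
                            rt_a, rt_b, bf, direction)


# ---------------------------------------------------------------------------
# nested differential-region calling
# ---------------------------------------------------------------------------

@dataclass
class DifferentialRegion:
    chrom: str
    start: int
    end: int
    direction: str        # "A_earlier" or "B_earlier"
    peak_bf: float
    mean_delta_rt: float

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_region(self, label_a: str, label_b: str) -> Region:
        name = (f"{label_a}_earlier" if self.direction == "A_earlier"
                else f"{label_b}_earlier")
        return Region(self.chrom, self.start, self.end, name, self.peak_bf)


def call_differential_regions(comp: WindowComparison, seed_bf: float = 1.0,
                              extend_bf: float = 0.5, max_gap_bp: int = 3000,
                              min_len_bp: int = 20_000
                              ) -> list[DifferentialRegion]:
    """Two-tier nested peak calling of differential-timing regions.

    Seeds are windows with BF10 >= ``seed_bf``; seeds extend through
    contiguous same-direction windows with BF10 >= ``extend_bf``;
    same-direction regions separated by <= ``max_gap_bp`` merge; regions
    shorter than ``min_len_bp`` are discarded.  A region's span is the
    union of its member windows' 3 kb extents.
    """
    out: list[DifferentialRegion] = []
    step = comp.step
    for chrom in comp.chroms():
        centers = comp.centers[chrom]
        if len(centers) == 0:
            continue
        if np.any(np.diff(centers) <= 0):
            raise ValueError(f"{chrom}: windows not sorted")
        bf = comp.bf10[chrom]
        dirs = comp.direction[chrom]
        delta = comp.rt_a[chrom] - comp.rt_b[chrom]
        for want in ("A_earlier", "B_earlier"):
            ext = (bf >= extend_bf) & (dirs == want)
            seed = (bf >= seed_bf) & (dirs == want)
            # maximal runs of extendable windows at consecutive centers
            regions: list[tuple[int, int]] = []  # index ranges [i, j]
            i = 0
            n = len(centers)
            while i < n:
                if not ext[i]:
                    i += 1
                    continue
                j = i
                while (j + 1 < n and ext[j + 1]
                       and centers[j + 1] == centers[j] + 1):
                    j += 1
                if seed[i:j + 1].any():
                    regions.append((i, j))
                i = j + 1
            # bp spans (union of member window extents)
            spans = [((centers[i] - 1) * step, (centers[j] + 2) * step, i, j)
                     for i, j in regions]
            # merge same-direction spans with gap <= max_gap_bp
            merged: list[list[int]] = []
            for s, e, i, j in spans:
                if merged and s - merged[-1][1] <= max_gap_bp:
                    merged[-1][1] = e
                    merged[-1][3] = j
                else:
                    merged.append([s, e, i, j])
            for s, e, i, j in merged:
                if e - s < min_len_bp:
                    continue
                members = slice(i, j + 1)
                mask = (dirs[members] == want) & (bf[members] >= extend_bf)
                out.append(DifferentialRegion(
                    chrom, int(s), int(e), want,
                    float(bf[members][mask].max()),
                    float(delta[members][mask].mean())))
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


# ---------------------------------------------------------------------------
# earlier-replicating totals + Fisher tests
# ---------------------------------------------------------------------------

def _overlap_bp(region: DifferentialRegion, start: int, end: int) -> int:
    return max(0, min(region.end, end) - max(region.start, start))


def earlier_totals(regions: list[DifferentialRegion], layout: GenomeLayout,
                   by: str = "domain") -> pd.DataFrame:
    """Per-domain (or per-chromosome) earlier-replicating totals.

    Columns: unit, kb earlier per direction, fraction of the unit, and a
    two-sided Fisher exact p comparing the unit's (A-earlier, B-earlier)
    1 kb-unit counts against the aggregate over all other units.  rDNA
    units are summarized but excluded from the Fisher aggregation.
    """
    for r in regions:
        if r.chrom not in layout.chromosomes or r.end > layout.length(r.chrom):
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} outside layout")
    if by == "domain":
        units = [(d.name, d.chrom, d.start, d.end, d.cls) for d in layout.domains]
    else:
        units = [(c, c, 0, layout.length(c), "") for c in layout.chromosomes]
    rows = []
    for name, chrom, start, end, cls in units:
        a_bp = sum(_overlap_bp(r, start, end) for r in regions
                   if r.chrom == chrom and r.direction == "A_earlier")
        b_bp = sum(_overlap_bp(r, start, end) for r in regions
                   if r.chrom == chrom and r.direction == "B_earlier")
        rows.append({"unit": name, "chrom": chrom, "length_bp": end - start,
                     "class": cls,
                     "a_earlier_kb": a_bp / 1000, "b_earlier_kb": b_bp / 1000,
                     "a_fraction": a_bp / (end - start),
                     "b_fraction": b_bp / (end - start)})
    df = pd.DataFrame(rows)
    # Fisher per unit: 1 kb units in-unit vs aggregated others
    in_fisher = df["class"] != "rDNA_unit" if by == "domain" else \
        ~df["chrom"].isin(layout.rdna_chroms())
    a_units = np.round(df["a_earlier_kb"]).astype(int)
    b_units = np.round(df["b_earlier_kb"]).astype(int)
    tot_a = int(a_units[in_fisher].sum())
    tot_b = int(b_units[in_fisher].sum())
    ps = []
    for i in df.index:
        if not in_fisher[i]:
            ps.append(np.nan)
            continue
        table = [[int(a_units[i]), int(b_units[i])],
                 [tot_a - int(a_units[i]), tot_b - int(b_units[i])]]
        ps.append(fisher_exact(table, alternative="two-sided")[1])
    df["fisher_p"] = ps
    return df


# ---------------------------------------------------------------------------
# Z-scores, domain summaries, clustering
# ---------------------------------------------------------------------------

@dataclass
class RTZscores:
    """Standardized timing over windows shared by all cell types."""

    cell_types: list[str]
    chrom: np.ndarray          # per shared window
    center_bp: np.ndarray
    z: dict[str, np.ndarray]   # cell type -> standardized scores
    rt: dict[str, np.ndarray]

    def n_windows(self) -> int:
        return len(self.chrom)


def zscore_tracks(tracks: dict[str, TimingTrack]) -> RTZscores:
    """Z-score each cell type's RT over the windows shared by all."""
    if len(tracks) < 2:
        raise ValueError("need at least two cell types")
    names = list(tracks)
    first = tracks[names[0]]
    chroms, centers = [], []
    idx = {ct: [] for ct in names}
    for chrom in first.chroms():
        shared = first.centers[chrom]
        for ct in names[1:]:
            other = tracks[ct].centers.get(chrom, np.array([], dtype=int))
            shared = np.intersect1d(shared, other)
        if len(shared) == 0:
            continue
        for ct in names:
            pos = np.searchsorted(tracks[ct].centers[chrom], shared)
            idx[ct].append((chrom, pos))
        chroms.append(np.full(len(shared), chrom, dtype=object))
        centers.append(shared * first.step + first.step // 2)
    chrom_arr = np.concatenate(chroms)
    center_arr = np.concatenate(centers)
    rt: dict[str, np.ndarray] = {}
    z: dict[str, np.ndarray] = {}
    for ct in names:
        vals = np.concatenate([tracks[ct].rt[chrom][pos]
                               for chrom, pos in idx[ct]])
        sd = vals.std()
        if sd == 0:
            raise ValueError(f"zero-variance timing track for {ct}")
        rt[ct] = vals
        z[ct] = (vals - vals.mean()) / sd
    return RTZscores(names, chrom_arr, center_arr, z, rt)


def domain_summary(zs: RTZscores, layout: GenomeLayout) -> pd.DataFrame:
    """Arithmetic-mean Z per domain per cell type (12 domains incl. rDNA),
    plus pairwise Pearson correlations of the domain profiles."""
    dom = np.array([layout.domain_at(c, int(p)) for c, p in
                    zip(zs.chrom, zs.center_bp)], dtype=object)
    rows = []
    for d in layout.domains:
        mask = dom == d.name
        if not mask.any():
            continue
        row = {"domain": d.name, "class": d.cls, "n_windows": int(mask.sum())}
        for ct in zs.cell_types:
            row[f"mean_z_{ct}"] = float(zs.z[ct][mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def domain_profile_correlations(summary: pd.DataFrame,
                                cell_types: list[str]) -> pd.DataFrame:
    rows = []
    for i, a in enumerate(cell_types):
        for b in cell_types[i + 1:]:
            r, p = pearsonr(summary[f"mean_z_{a}"], summary[f"mean_z_{b}"])
            rows.append({"cell_a": a, "cell_b": b, "pearson_r": float(r),
                         "p_value": float(p)})
    return pd.DataFrame(rows)


@dataclass
class CellTree:
    cell_types: list[str]
    distance: np.ndarray       # square matrix
    linkage: np.ndarray        # scipy linkage matrix (average method)
    newick: str


def rms_distance_matrix(zs: RTZscores, layout: GenomeLayout | None = None
                        ) -> np.ndarray:
    """Root-mean-square Z difference between cell types over shared windows
    (Euclidean distance per window count); rDNA windows excluded."""
    mask = np.ones(zs.n_windows(), dtype=bool)
    if layout is not None:
        rdna = layout.rdna_chroms()
        mask = ~np.isin(zs.chrom, list(rdna))
    n = len(zs.cell_types)
    D = np.zeros((n, n))
    for i, a in enumerate(zs.cell_types):
        for j in range(i + 1, n):
            b = zs.cell_types[j]
            diff = zs.z[a][mask] - zs.z[b][mask]
            D[i, j] = D[j, i] = float(np.sqrt(np.mean(diff ** 2)))
    return D


def _newick(node, labels, branch_len: float | None) -> str:
    if node.is_leaf():
        return f"{labels[node.id]}:{branch_len:.6g}"
    left = _newick(node.left, labels, node.dist - node.left.dist)
    right = _newick(node.right, labels, node.dist - node.right.dist)
    inner = f"({left},{right})"
    return inner if branch_len is None else f"{inner}:{branch_len:.6g}"


def cluster_cell_types(zs: RTZscores, layout: GenomeLayout | None = None
                       ) -> CellTree:
    """Average-linkage (UPGMA) tree on the RMS Z-score distance matrix."""
    from scipy.cluster.hierarchy import linkage, to_tree
    from scipy.spatial.distance import squareform

    for ct in zs.cell_types:
        if not np.all(np.isfinite(zs.z[ct])):
            raise ValueError(f"missing values in Z profile for {ct}")
    D = rms_distance_matrix(zs, layout)
    Z = linkage(squareform(D, checks=False), method="average")
    tree = to_tree(Z)
    newick = _newick(tree, zs.cell_types, None) + ";"
    return CellTree(list(zs.cell_types), D, Z, newick)
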