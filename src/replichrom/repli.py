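"""Per-cell-type replication timing inference.

The timing model is a one-parameter Bayesian logistic regression per 3 kb
sliding window (1 kb step): the four S-phase fractions are collapsed to an
early half (E + EM, "successes") and a late half (LM + L, "failures"), and
the window's logit timing score theta has the binomial log-likelihood

    l(theta) = S log sigma(theta) + F log(1 - sigma(theta))

with S, F the depth-normalized (rounded) early/late totals pooled over the
window's three 1 kb bins and all replicates, and sigma the logistic
function.  The prior is Normal(0, tau^2), near-uniform on the probability
scale at the default tau = 2.  The replication timing score is the
posterior mean of 2*sigma(theta) - 1, in (-1, 1), computed by trapezoid
quadrature on a symmetric theta grid; the grid is fine enough that
doubling its density changes the score below 1e-8 (the integrand is
bell-shaped, where trapezoid quadrature converges spectrally).

Scores are canonicalized so that the model's exact symmetries hold in
floating point: a window with S == F scores exactly 0, and swapping S and
F exactly negates the score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .genome import BinnedTrack, GenomeLayout
from .simulate import FRACTIONS, FractionCounts

logger = logging.getLogger(__name__)

DEFAULT_PRIOR_SD = 2.0
DEFAULT_GRID = (-10.0, 10.0, 801)


# ---------------------------------------------------------------------------
# depth normalization
# ---------------------------------------------------------------------------

def normalize_fractions(fc: FractionCounts, layout: GenomeLayout
                        ) -> FractionCounts:
    """Scale each (replicate, fraction) track to the replicate's mean depth.

    Depths exclude reads on rDNA-unit contigs.  After scaling, the four
    fractions of one replicate have equal totals, so neither sequencing
    depth nor fraction-specific recovery biases the early/late collapse.
    """
    excl = layout.rdna_chroms()
    scaled: dict = {}
    for rep in fc.replicates():
        depths = {f: fc.depth(rep, f, exclude_chroms=excl) for f in FRACTIONS}
        for f, d in depths.items():
            if d <= 0:
                raise ValueError(f"zero-depth fraction ({rep}, {f})")
        mean_depth = sum(depths.values()) / len(depths)
        scaled[rep] = {}
        for f in FRACTIONS:
            factor = mean_depth / depths[f]
            tr = fc.counts[rep][f]
            scaled[rep][f] = BinnedTrack(
                tr.step, {c: v * factor for c, v in tr.data.items()}, "count")
    return FractionCounts(fc.cell_type, scaled, fc.step)


# ---------------------------------------------------------------------------
# window assembly
# ---------------------------------------------------------------------------

@dataclass
class WindowTable:
    """Sliding-window early/late observations for one cell type.

    Per chromosome: window centers (bin index; windows span bins
    center-1 .. center+1) and pooled successes S / failures F (already
    summed over the three bins and all replicates; the binomial likelihood
    depends on the per-replicate-bin observations only through these
    totals).  ``autocorr`` holds the lag-1 autocorrelation of per-bin
    totals per chromosome, a diagnostic of whether consecutive bins are
    independent enough to pool.
    """

    cell_type: str
    step: int
    centers: dict[str, np.ndarray]
    S: dict[str, np.ndarray]
    F: dict[str, np.ndarray]
    n_replicates: int
    autocorr: dict[str, float]

    def chroms(self) -> list[str]:
        return list(self.centers)

    def n_windows(self) -> int:
        return int(sum(len(v) for v in self.centers.values()))

    def window_span(self, chrom: str, i: int) -> tuple[int, int]:
        c = int(self.centers[chrom][i])
        return ((c - 1) * self.step, (c + 2) * self.step)


def _lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 3 or np.std(x) == 0:
        return 0.0  # degenerate rule: constant/short series -> 0
    x = x - x.mean()
    return float(np.dot(x[:-1], x[1:]) / np.dot(x, x))


def window_observations(scaled: FractionCounts, window_bins: int = 3
                        ) -> WindowTable:
    """Assemble 3 kb sliding windows (1 kb step) of early/late counts.

    Per bin, successes = round(E + EM) and failures = round(LM + L) after
    depth normalization; windows pool three consecutive bins over all
    replicates.  Edge windows with fewer than ``window_bins`` bins are
    dropped.
    """
    step = scaled.step
    reps = scaled.replicates()
    centers: dict[str, np.ndarray] = {}
    S: dict[str, np.ndarray] = {}
    F: dict[str, np.ndarray] = {}
    ac: dict[str, float] = {}
    some = scaled.counts[reps[0]][FRACTIONS[0]]
    half = window_bins // 2
    kernel = np.ones(window_bins)
    for chrom, v in some.data.items():
        n = len(v)
        s_bins = np.zeros(n)
        f_bins = np.zeros(n)
        for rep in reps:
            e = scaled.counts[rep]["E"].data[chrom] + \
                scaled.counts[rep]["EM"].data[chrom]
            l = scaled.counts[rep]["LM"].data[chrom] + \
                scaled.counts[rep]["L"].data[chrom]
            s_bins += np.round(e)
            f_bins += np.round(l)
        ac[chrom] = _lag1_autocorr(s_bins + f_bins)
        if n < window_bins:
            centers[chrom] = np.array([], dtype=int)
            S[chrom] = np.array([])
            F[chrom] = np.array([])
            continue
        sw = np.convolve(s_bins, kernel, mode="valid")
        fw = np.convolve(f_bins, kernel, mode="valid")
        centers[chrom] = np.arange(half, n - half)
        S[chrom] = sw
        F[chrom] = fw
    return WindowTable(scaled.cell_type, step, centers, S, F, len(reps), ac)


# ---------------------------------------------------------------------------
# posterior timing score
# ---------------------------------------------------------------------------

def theta_grid(spec: tuple[float, float, int] = DEFAULT_GRID) -> np.ndarray:
    lo, hi, n = spec
    if not np.isclose(lo, -hi):
        raise ValueError("theta grid must be symmetric about 0")
    return np.linspace(lo, hi, int(n))


def _log_binom_kernel(S: np.ndarray, F: np.ndarray, theta: np.ndarray
                      ) -> np.ndarray:
    """(n_windows, n_grid) binomial log-likelihood S log s + F log(1-s)."""
    # log sigma(t) = -log1p(exp(-t)); log(1 - sigma(t)) = -log1p(exp(t))
    log_sig = -np.log1p(np.exp(-theta))
    log_1m = -np.log1p(np.exp(theta))
    return np.outer(S, log_sig) + np.outer(F, log_1m)


def posterior_timing_score(S, F, prior_sd: float = DEFAULT_PRIOR_SD,
                           grid: tuple[float, float, int] = DEFAULT_GRID
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and sd of the timing score 2*sigma(theta)-1.

    Vectorized over windows; S and F are arrays of pooled early/late
    totals.  Returns ``(rt, sd)``.  Scores are canonicalized so the
    S <-> F symmetry is exact (see module docstring).
    """
    S = np.atleast_1d(np.asarray(S, dtype=float))
    F = np.atleast_1d(np.asarray(F, dtype=float))
    if S.shape != F.shape:
        raise ValueError("S and F must have matching shapes")
    theta = theta_grid(grid)
    # canonical ordering: compute with successes >= failures, then restore
    flip = F > S
    Sc = np.where(flip, F, S)
    Fc = np.where(flip, S, F)
    ll = _log_binom_kernel(Sc, Fc, theta)
    if not np.all(np.isfinite(ll)):
        raise FloatingPointError("non-finite log-likelihood")
    lp = ll - 0.5 * (theta / prior_sd) ** 2
    lp -= lp.max(axis=1, keepdims=True)
    w = np.exp(lp)
    # trapezoid weights on the uniform grid
    tw = np.ones_like(theta)
    tw[0] = tw[-1] = 0.5
    g = 2.0 / (1.0 + np.exp(-theta)) - 1.0  # score transform
    z = w @ tw
    m1 = (w * g) @ tw / z
    m2 = (w * g * g) @ tw / z
    sd = np.sqrt(np.maximum(m2 - m1 * m1, 0.0))
    rt = np.where(Sc == Fc, 0.0, m1)          # exact zero by symmetry
    rt = np.where(flip, -rt, rt)
    return rt, sd


@dataclass
class TimingTrack:
    """Per-window replication timing for one cell type (1 kb step)."""

    cell_type: str
    step: int
    centers: dict[str, np.ndarray]
    rt: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]

    def chroms(self) -> list[str]:
        return list(self.centers)

    def as_binned(self, layout: GenomeLayout, smooth: bool = False
                  ) -> BinnedTrack:
        """Dense 1 kb track of per-window scores (NaN where no window)."""
        tr = BinnedTrack.zeros(layout, self.step, semantics="score")
        for chrom in tr.data:
            tr.data[chrom][:] = np.nan
            if chrom in self.centers and len(self.centers[chrom]):
                tr.data[chrom][self.centers[chrom]] = self.rt[chrom]
        return tr


def timing_track(windows: WindowTable, prior_sd: float = DEFAULT_PRIOR_SD,
                 grid: tuple[float, float, int] = DEFAULT_GRID) -> TimingTrack:
    """Score every window of a :class:`WindowTable`."""
    rt: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    for chrom in windows.chroms():
        if len(windows.S[chrom]) == 0:
            rt[chrom] = np.array([])
            sd[chrom] = np.array([])
            continue
        rt[chrom], sd[chrom] = posterior_timing_score(
            windows.S[chrom], windows.F[chrom], prior_sd, grid)
    return TimingTrack(windows.cell_type, windows.step, dict(windows.centers),
                       rt, sd)


# ---------------------------------------------------------------------------
# LOESS display track
# ---------------------------------------------------------------------------

def loess_track(track: TimingTrack, span_bp: float = 100_000.0,
                degree: int = 1) -> TimingTrack:
    """LOESS-smoothed copy for display (local linear, tricube weights).

    The span is converted per chromosome to a fraction of its window
    count.  Chromosomes with fewer than 10 windows are returned unsmoothed
    with a warning.  Output clamped to [-1, 1].
    """
    if degree != 1:
        raise NotImplementedError("only locally linear (degree 1) smoothing")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    rt: dict[str, np.ndarray] = {}
    for chrom in track.chroms():
        y = track.rt[chrom]
        x = track.centers[chrom].astype(float)
        if len(y) < 10:
            warnings.warn(f"{chrom}: fewer than 10 windows, not smoothed")
            rt[chrom] = y.copy()
            continue
        frac = min(1.0, (span_bp / track.step) / len(y))
        sm = lowess(y, x, frac=frac, it=0, return_sorted=False)
        rt[chrom] = np.clip(sm, -1.0, 1.0)
    return TimingTrack(track.cell_type, track.step, dict(track.centers), rt,
                       {c: v.copy() for c, v in track.sd.items()})


# ---------------------------------------------------------------------------
# convenience: fragments -> timing track
# ---------------------------------------------------------------------------

def fraction_counts_from_fragments(cell_type: str, frag_tables: dict,
                                   layout: GenomeLayout, step: int = 1000,
                                   max_width: int = 500) -> FractionCounts:
    """Build :class:`FractionCounts` from per-(replicate, fraction)
    fragment DataFrames, applying the <= 500 bp paired-fragment cap."""
    from .genome import bin_midpoints

    counts: dict = {}
    for rep, fractions in frag_tables.items():
        counts[rep] = {}
        for frac, frags in fractions.items():
            counts[rep][frac] = bin_midpoints(frags, step, layout,
                                              max_width=max_width)
    return FractionCounts(cell_type, counts, step)
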