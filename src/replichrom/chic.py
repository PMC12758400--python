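"""ChIC-ChIP chromatin tracks.

Mononucleosomal fragments (paired-end width within [100, 200] bp by
default) are counted at 20 bp steps by midpoint.  Per step, a two-group
maximum-likelihood negative binomial regression with library-size offsets

    log mu_{t,s} = beta0_t + beta1_t * 1[s is IP] + log d_s

yields the H3-abundance intercept (input intensity) and the IP effect,
reported as L2FC = beta1 / ln 2.  The dispersion alpha
(variance = mu + alpha mu^2) is estimated once genome-wide by profile
maximum likelihood on a subsample of steps and then held fixed; the
two-group design separates, so each group's mean solves an independent
concave one-parameter problem (damped Newton, vectorized over steps).

Densities are the Gaussian-kernel smooth (sigma = 40 bp, truncated at
+-4 sigma and renormalized) of the per-step predicted intensities, and
log2FE = log2((IP density + eps) / (input density + eps)).  Nucleosome
dyads appear as strict local maxima of the smoothed input density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks
from scipy.special import gammaln

from .genome import BinnedTrack, GenomeLayout, bin_midpoints

logger = logging.getLogger(__name__)

CHIC_STEP = 20
MONO_BOUNDS = (100, 200)
SIGMA_BP = 40.0


# ---------------------------------------------------------------------------
# counting and normalization
# ---------------------------------------------------------------------------

@dataclass
class ChicSample:
    sample_id: str
    role: str                  # "input" | "IP"
    counts: BinnedTrack        # 20 bp monosome-midpoint counts
    size_factor: float = 1.0


def filter_and_count(frags: pd.DataFrame, layout: GenomeLayout,
                     len_min: int = MONO_BOUNDS[0],
                     len_max: int = MONO_BOUNDS[1],
                     step: int = CHIC_STEP) -> BinnedTrack:
    """Bin mononucleosomal fragment midpoints at 20 bp.

    Only fragments with ``len_min <= width <= len_max`` are kept.
    """
    if len_min >= len_max:
        raise ValueError("len_min must be < len_max")
    width = frags["end"] - frags["start"]
    kept = frags[(width >= len_min) & (width <= len_max)]
    logger.info("filter_and_count: kept %d / %d fragments in [%d, %d] bp",
                len(kept), len(frags), len_min, len_max)
    return bin_midpoints(kept, step, layout)


def autosomal_median_normalize(track: BinnedTrack, layout: GenomeLayout
                               ) -> BinnedTrack:
    """Counts divided by the median of nonzero autosomal bin counts."""
    vals = np.concatenate([track.data[c] for c in track.data
                           if layout.is_autosomal(c)])
    vals = vals[vals > 0]
    if len(vals) == 0:
        raise ValueError("all autosomal counts are zero")
    med = float(np.median(vals))
    return BinnedTrack(track.step,
                       {c: v / med for c, v in track.data.items()},
                       "density")


def size_factors(samples: list[ChicSample], layout: GenomeLayout
                 ) -> list[ChicSample]:
    """Library size factor per sample: total retained autosomal monosome
    count over the geometric mean across samples."""
    totals = []
    for s in samples:
        tot = sum(float(s.counts.data[c].sum()) for c in s.counts.data
                  if layout.is_autosomal(c))
        if tot <= 0:
            raise ValueError(f"sample {s.sample_id}: no autosomal counts")
        totals.append(tot)
    gm = float(np.exp(np.mean(np.log(totals))))
    for s, t in zip(samples, totals):
        s.size_factor = t / gm
    return samples


# ---------------------------------------------------------------------------
# negative binomial fits
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Elementwise NB2 log-likelihood (variance mu + alpha mu^2)."""
    r = 1.0 / alpha
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))


def _fit_group_eta(y: np.ndarray, d: np.ndarray, alpha: float,
                   max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """MLE of eta per step for counts ``y`` (n_steps, n_samples) with
    offsets ``d`` (n_samples) and fixed dispersion: mu = d * exp(eta).

    The log-likelihood is concave in eta; damped Newton from the
    moment start log(mean(y/d)).
    """
    ybar = (y / d).mean(axis=1)
    eta = np.log(np.maximum(ybar, 1e-8))
    for _ in range(max_iter):
        mu = d * np.exp(eta)[:, None]
        score = ((y - mu) / (1.0 + alpha * mu)).sum(axis=1)
        hess = -(mu * (1.0 + alpha * y) / (1.0 + alpha * mu) ** 2).sum(axis=1)
        delta = -score / np.where(hess == 0, -1.0, hess)
        delta = np.clip(delta, -2.0, 2.0)  # damping
        eta = eta + delta
        if np.max(np.abs(delta)) < tol:
            break
    return eta


def estimate_dispersion(y_input: np.ndarray, y_ip: np.ndarray,
                        d_input: np.ndarray, d_ip: np.ndarray,
                        max_steps: int = 10_000,
                        rng: np.random.Generator | None = None) -> float:
    """Profile-ML estimate of the shared NB dispersion alpha.

    Group means are profiled out per step on a uniform random subsample of
    at most ``max_steps`` steps; alpha is optimized on the log scale.
    Returns 0 when the data look Poisson (boundary solution).
    """
    n = y_input.shape[0]
    if rng is None:
        rng = np.random.default_rng(0)
    if n > max_steps:
        idx = rng.choice(n, size=max_steps, replace=False)
        y_input, y_ip = y_input[idx], y_ip[idx]
    # drop all-zero steps: their profile likelihood is flat in alpha
    keep = (y_input.sum(axis=1) + y_ip.sum(axis=1)) > 0
    y_input, y_ip = y_input[keep], y_ip[keep]
    if len(y_input) == 0:
        return 0.0

    def neg_profile(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        tot = 0.0
        for y, d in ((y_input, d_input), (y_ip, d_ip)):
            eta = _fit_group_eta(y, d, alpha)
            mu = d * np.exp(eta)[:, None]
            tot += _nb_loglik(y, np.maximum(mu, 1e-12), alpha).sum()
        return -tot

    res = minimize_scalar(neg_profile, bounds=(np.log(1e-4), np.log(10.0)),
                          method="bounded", options={"xatol": 1e-3})
    alpha = float(np.exp(res.x))
    # boundary: if the optimum hugs the lower bound, call it Poisson-like
    if alpha <= 1.2e-4:
        return 0.0
    return alpha


@dataclass
class ChicFit:
    """Per-step NB regression estimates (natural-log scale intercepts)."""

    step: int
    beta0: dict[str, np.ndarray]   # input (H3) log intensity
    beta1: dict[str, np.ndarray]   # IP effect
    alpha: float

    def l2fc(self) -> dict[str, np.ndarray]:
        return {c: v / np.log(2.0) for c, v in self.beta1.items()}

    def input_intensity(self) -> BinnedTrack:
        return BinnedTrack(self.step,
                           {c: np.exp(v) for c, v in self.beta0.items()},
                           "density")

    def ip_intensity(self) -> BinnedTrack:
        return BinnedTrack(
            self.step,
            {c: np.exp(self.beta0[c] + self.beta1[c]) for c in self.beta0},
            "density")


def fit_nb_per_step(inputs: list[ChicSample], ips: list[ChicSample],
                    layout: GenomeLayout, alpha: float | None = None,
                    zero_continuity: float = 0.5,
                    estimate_size_factors: bool = True,
                    rng: np.random.Generator | None = None) -> ChicFit:
    """Per-20 bp-step NB regression of IP vs input counts.

    With one sample per role the fit is saturated: the fitted mean equals
    the observed depth-normalized count.  When any count at a step is
    zero, ``zero_continuity`` (default 0.5) is added to every count at
    that step before fitting, keeping L2FC finite.  With
    ``estimate_size_factors=False`` the samples' preset ``size_factor``
    values are used (e.g. unit factors when depths are known equal; a
    genome-wide uniform enrichment is not identifiable from totals).
    """
    if not inputs or not ips:
        raise ValueError("need at least one input and one IP sample")
    if estimate_size_factors:
        samples = size_factors(list(inputs) + list(ips), layout)
        inputs, ips = samples[:len(inputs)], samples[len(inputs):]
    d_in = np.array([s.size_factor for s in inputs])
    d_ip = np.array([s.size_factor for s in ips])
    step = inputs[0].counts.step
    chroms = list(inputs[0].counts.data)
    # stack counts (steps x samples) across the genome for dispersion
    y_in_all = np.concatenate([
        np.stack([s.counts.data[c] for s in inputs], axis=1) for c in chroms])
    y_ip_all = np.concatenate([
        np.stack([s.counts.data[c] for s in ips], axis=1) for c in chroms])
    if alpha is None:
        if len(inputs) == 1 and len(ips) == 1:
            alpha = 0.0   # saturated fit: dispersion unidentifiable
        else:
            alpha = estimate_dispersion(y_in_all, y_ip_all, d_in, d_ip,
                                        rng=rng)
    beta0: dict[str, np.ndarray] = {}
    beta1: dict[str, np.ndarray] = {}
    for chrom in chroms:
        y_in = np.stack([s.counts.data[chrom] for s in inputs],
                        axis=1).astype(float)
        y_ip = np.stack([s.counts.data[chrom] for s in ips],
                        axis=1).astype(float)
        anyzero = (np.min(y_in, axis=1) == 0) | (np.min(y_ip, axis=1) == 0)
        y_in = y_in + zero_continuity * anyzero[:, None]
        y_ip = y_ip + zero_continuity * anyzero[:, None]
        if alpha == 0.0:
            # Poisson / saturated closed form: eta = log(sum y / sum d)
            eta_in = np.log(y_in.sum(axis=1) / d_in.sum())
            eta_ip = np.log(y_ip.sum(axis=1) / d_ip.sum())
        else:
            eta_in = _fit_group_eta(y_in, d_in, alpha)
            eta_ip = _fit_group_eta(y_ip, d_ip, alpha)
        beta0[chrom] = eta_in
        beta1[chrom] = eta_ip - eta_in
    return ChicFit(step, beta0, beta1, float(alpha))


# ---------------------------------------------------------------------------
# smoothing, log2FE, nucleosome calls
# ---------------------------------------------------------------------------

def gaussian_kernel(sigma_bp: float = SIGMA_BP, step: int = CHIC_STEP
                    ) -> np.ndarray:
    """Discrete Gaussian kernel truncated at +-4 sigma, renormalized to 1."""
    half = int(np.ceil(4 * sigma_bp / step))
    x = np.arange(-half, half + 1) * step
    k = np.exp(-0.5 * (x / sigma_bp) ** 2)
    return k / k.sum()


def gaussian_density(track: BinnedTrack, sigma_bp: float = SIGMA_BP
                     ) -> BinnedTrack:
    """Gaussian-kernel smooth; mass-conserving on the interior (reflect
    boundaries keep the total within the chromosome)."""
    k = gaussian_kernel(sigma_bp, track.step)
    out = {c: convolve1d(v.astype(float), k, mode="reflect")
           for c, v in track.data.items()}
    return BinnedTrack(track.step, out, "density")


def log2fe(ip_density: BinnedTrack, input_density: BinnedTrack,
           epsilon: float | None = None) -> BinnedTrack:
    """log2((IP + eps) / (input + eps)) on matching grids.

    When ``epsilon`` is None it defaults to the 5th percentile of the
    genome-wide positive input density.
    """
    if ip_density.step != input_density.step or \
            set(ip_density.data) != set(input_density.data):
        raise ValueError("density grids do not match")
    for c in ip_density.data:
        if len(ip_density.data[c]) != len(input_density.data[c]):
            raise ValueError("density grids do not match")
    if epsilon is None:
        pos = np.concatenate([v[v > 0] for v in input_density.data.values()])
        epsilon = float(np.percentile(pos, 5)) if len(pos) else 1e-6
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    out = {c: np.log2((ip_density.data[c] + epsilon) /
                      (input_density.data[c] + epsilon))
           for c in ip_density.data}
    return BinnedTrack(ip_density.step, out, "score")


@dataclass
class NucleosomeCall:
    chrom: str
    dyad: int          # bp, center of the maximum's step
    height: float
    prominence: float


def call_nucleosomes(density: BinnedTrack, min_prominence: float | None = None
                     ) -> list[NucleosomeCall]:
    """Strict local maxima of the smoothed density, ties broken leftward.

    ``min_prominence`` defaults to 25% of the track's median positive
    density.  Calls are at least two steps apart.
    """
    if min_prominence is None:
        pos = np.concatenate([v[v > 0] for v in density.data.values()])
        min_prominence = 0.25 * float(np.median(pos)) if len(pos) else 0.0
    calls: list[NucleosomeCall] = []
    for chrom, v in density.data.items():
        peaks, props = find_peaks(v, prominence=min_prominence, distance=2)
        for p, h, pr in zip(peaks, v[peaks], props["prominences"]):
            calls.append(NucleosomeCall(chrom,
                                        int(p * density.step +
                                            density.step // 2),
                                        float(h), float(pr)))
    calls.sort(key=lambda c: (c.chrom, c.dyad))
    return calls
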