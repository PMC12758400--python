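# Methods

This note documents the models, the defaults and the numerical choices,
and what the synthetic data does and does not emulate.

## Coordinate conventions

All coordinates are 0-based half-open (BED convention).  A fragment's
midpoint is `floor((start+end)/2)` and increments exactly one bin,
`floor(midpoint/step)`; bins are anchored at position 0 of each
chromosome.  Fragment tables are headerless TSV
(`chrom  start  end  mapq`); records with MAPQ below 20 are dropped at
load (uniquely-mapped filter).  The ≤ 500 bp width cap applies to
paired Repli-seq records only; ChIC filtering is separate (below).  The
rDNA transcription unit is modelled as its own 8 kb contig; its reads
are excluded from autosomal normalization totals and fraction depths.

## Replication timing model

Per cell type, each (replicate, fraction) count track is scaled by
(mean depth across the replicate's four fractions)/(its own depth).
This calibrates the early/late collapse under the assumption that each
S-phase fraction contains the same total amount of nascent DNA; timing
scores are therefore relative quantities.  Per 1 kb bin, successes are
`round(E + EM)` and failures `round(LM + L)`; 3 kb windows (1 kb step)
pool three bins over all replicates.  Rounding keeps a proper binomial
likelihood after scaling; the lag-1 autocorrelation of per-bin totals is
reported per chromosome as a diagnostic that pooling consecutive bins as
independent observations is tolerable (≈ 0.05 on simulated data).

The window likelihood depends on the observations only through the
pooled totals (S, F):

    ℓ(θ) = S log σ(θ) + F log(1 − σ(θ)),   prior θ ~ Normal(0, τ²).

* τ = 2.0: near-uniform on the probability scale, weakly informative;
  an empty window returns the prior (RT = 0, posterior sd ≈ 0.63 on the
  score scale).
* Quadrature: trapezoid on θ ∈ [−10, 10], 801 points.  The integrand is
  bell-shaped and vanishes at the grid ends, where trapezoid quadrature
  converges spectrally: doubling the grid density moves scores by
  < 1e-8, and the 801-point result matches step-1e-4 reference
  integration to ~1e-8 for data-like windows.  The prior mass outside
  ±10 is ≈ 6e-7, which bounds the truncation error for near-empty
  windows.
* Exact symmetries: scores are computed on the (max, min) ordering of
  (S, F) and sign-restored, so swapping early and late totals negates
  RT bit-exactly and S = F gives exactly 0.
* LOESS display smoothing is locally linear with tricube weights
  (statsmodels `lowess`, no robustness iterations), span expressed in bp
  (default 100 kb) and converted per chromosome to a fraction of its
  window count; output clamped to [−1, 1]; chromosomes with < 10
  windows are passed through with a warning.  The default span is a
  display choice for broad-scale tracks; variance-reduction against
  ground truth is demonstrated at spans matched to the landscape's
  wiggle scale (~20 kb on the toy genome).

## Differential timing

Bayes factor per window, shared θ-grid and prior:

    m1 = ∫L_A π dθ · ∫L_B π dθ,   m0 = ∫L_A L_B π dθ,
    BF10 = log10(m1/m0),

evaluated with log-sum-exp trapezoid quadrature.  Direction is the sign
of RT_A − RT_B; |ΔRT| < 1e-3 is labelled "none" even when the Bayes
factor passes, preventing zero-effect regions.

Nested region calling is a two-tier seed/extend scheme: seeds at
log₁₀BF ≥ 1.0, extension through contiguous same-direction windows with
log₁₀BF ≥ 0.5, merging of same-direction regions separated by ≤ 3 kb,
and a 20 kb minimum length.  The seed/extend thresholds are exposed in
the configuration; region spans are the union of member windows' 3 kb
extents.  On simulated data at ~300 fragments per window the null
false-positive rate of log₁₀BF ≥ 1 is ≈ 0.1–0.3% and power at a score
difference of 0.4 is ≈ 98%.

Earlier-replicating totals are region overlaps summed per chromosome or
domain; Fisher exact tests use 1 kb units as counting elements, each
domain against the aggregate of all other domains (the rDNA contig is
summarized but excluded from aggregation and from clustering).  RT
Z-scores standardize each cell type over the windows shared by all cell
types; domain summaries are arithmetic mean Z over the 12 domains (11
chromosome-derived + rDNA); cell-type trees are UPGMA on the RMS
Z-difference matrix, emitted as Newick with merge heights.

## ChIC-ChIP model

Mononucleosomal fragments are width-filtered to [100, 200] bp (the
commonly used single-nucleosome band) and midpoint-counted at 20 bp
steps.  Per step t and sample s with role indicator IP:

    y_ts ~ NB(μ_ts, α),  log μ_ts = β0_t + β1_t·1[IP] + log d_s,
    Var = μ + αμ².

* Library size factors d_s default to each sample's total retained
  autosomal monosome count over the geometric mean across samples; they
  can be fixed externally (e.g. to 1) when depths are known equal — a
  genome-wide uniform enrichment is not identifiable from totals.
* The two-group design separates: each group's mean solves an
  independent concave one-parameter problem, fitted by damped Newton
  vectorized across all steps.
* Dispersion α is shared genome-wide (per-step replicate numbers are
  tiny): profile maximum likelihood on a uniform subsample of up to
  10,000 steps, optimized on the log scale; all-zero steps are excluded
  (their profile likelihood is flat in α).  With one sample per role
  the fit is saturated and α is unidentifiable; it is set to 0 and the
  fitted means equal the observed depth-normalized counts.
* Zero-count continuity: 0.5 is added to every count at a step where
  any count is zero (configurable), keeping log-fold-changes finite.
* Densities: the per-step predicted intensities exp(β0) and exp(β0+β1)
  smoothed by a discrete Gaussian kernel, σ = 40 bp, truncated at ±4σ
  and renormalized to sum 1 (mass-conserving on the interior; reflect
  boundaries).  log₂FE = log₂((IP+ε)/(input+ε)) with ε defaulting to
  the 5th percentile of the positive input density — a display
  regularizer that shrinks extreme ratios toward 0; quantitative
  contrasts should use a negligible ε.
* Nucleosome calls: strict local maxima of the smoothed input density
  with prominence ≥ 25% of the median positive density, minimum
  separation two steps, ties broken leftward.

## Expression integration

"On" means CPM strictly above 5; on-genes are ranked by (CPM, gene id)
and split into equal-count tertiles (lower tertiles take the extras on
ties of size).  Cell-cycle reweighting gives each cell weight
(target fraction)/(observed fraction) of its phase — targets default to
1/3 G1, 1/3 S, 1/3 G2/M — so weighted pseudobulk is phase-balanced and
the weights average exactly 1.  DE sets require |fold change| > 1.5 and
s-value < 1e-4 on externally supplied posterior estimates; the
estimation of those log-fold-changes is out of scope and consumed as
input.

Meta-profiles sample tracks on the 20 bp grid over TSS ± 1 kb
(strand-oriented; minus-strand genes are reversed) or over gene bodies
rescaled to 100 positions by linear interpolation with 25 fixed-step
flanks (genes shorter than 2 kb are skipped and counted).  Welch tests
are two-sided with Welch–Satterthwaite degrees of freedom, comparing
each on-category's per-gene values at its profile maximum against the
off category at the same position.  The paired t-test over
differential-timing regions pairs per-region mean log₂FE; pairs with
exactly zero difference variance are flagged (`exact_offset`) rather
than divided by zero.  Gene-level RT is the mean over overlapping
windows (TSS-only mode is a configuration choice we did not default to,
since gene-level scatter plots describe whole-gene timing); region
class requires majority span overlap.  Tertiles are computed after any
phase reweighting.

## Synthetic data

The generators are fixtures with the statistical structure the analysis
assumes, not claims about the real data.

* Toy genome ~6 Mb: chr2 (2.2 Mb) and chr3 (2.0 Mb) with arms and
  per-arm pericentromeres, chrX 1 Mb, chrY 0.5 Mb, chr4 0.3 Mb, rDNA
  8 kb — 11 chromosome-derived domains plus rDNA.
* Timing landscape: per-domain mean score (arms early, pericentromeres/
  Y late, X earlier, chr4 late by default) plus a smooth sum of three
  sinusoids (amplitude 0.35, length scale 150 kb, phases shared across
  cell types so differences come only from domain means).  The
  landscape is recentred so the genome-wide mean early-half probability
  is exactly 1/2 — the equal-DNA-per-fraction condition under which
  fraction-depth normalization is calibrated — then clipped to ±0.96.
* Repli-seq: reads are multinomially spread over bins, then over the
  four fractions with weights (p·a, p·(1−a), (1−p)·(1−a), (1−p)·a),
  sharpness a = 0.7, so the binary collapse recovers exactly p.
  Default 510,000 fragments per replicate (~500 per 3 kb window over
  two replicates; the binomial error budget puts the expected score
  RMSE at ~0.04 there).  Replicate depths are jittered ±15% to
  exercise normalization.
* ChIC: nucleosome dyads on a 185 bp grid with 10 bp per-nucleosome
  jitter; gene +1 dyads (half a spacing downstream of the TSS, to which
  gene TSSs snap) get a 2× occupancy boost and 2 bp jitter, emulating
  promoter phasing.  Fragment midpoints add 10 bp per-fragment noise
  (MNase trimming); lengths are Normal(150, 15) truncated positive.
  Per-nucleosome counts are gamma-mixed Poisson (NB dispersion 0.1);
  IP rates multiply a per-mark ground-truth function (4× in 20 kb
  blocks of euchromatin for H3K4me3/H3K27me3 with a cell-type phase
  offset; 4× across heterochromatin for H3K9me3) and are depth-matched
  to the input.
* Expression: log-normal CPMs with 45% of genes forced near zero, 10%
  DE at ±2 log₂ units with s-values near 0 (non-DE near 1), CPM columns
  normalized to 1e6; per-cell-type phase compositions differ so
  reweighting is non-trivial.

Not emulated: mappability/GC bias, fragment-level sequence, doublets or
ambient RNA, spike-ins, biological replicate structure beyond depth
jitter, and any coupling between expression level and chromatin or
timing beyond the constructs above.  Passing tests therefore show that
the inference machinery recovers the structure it models — not that the
model captures every property of real testis data.

## Problem sizes and determinism

All randomness flows through `numpy.random.Generator` seeded from a
single configuration seed (per-stream sub-seeds via CRC-tagged
`SeedSequence`), so reruns are bit-identical.  The test-suite and the
acceptance script run the full toy genome (≈ 6,000 windows per cell
type), 2,000-window calibration panels, a 30×-coverage phased array on
chr4 (≈ 1,600 nucleosomes) and one complete file-based pipeline run;
these sizes keep any single check within a few tens of seconds while
leaving the acceptance quantities well-determined (sampling slack on
the calibration fractions is a few tenths of a percent).

## Known limitations

* The four-fraction profile is collapsed to a binary early/late
  contrast; an ordinal four-fraction model would use more information
  but is not identified by the binary ground truth the generator
  plants.
* The shared genome-wide dispersion understates per-step variance
  heterogeneity; with ≤ 4 replicates per role a per-step dispersion is
  not estimable.
* Fisher tests on 1 kb units treat units as independent, which
  overstates evidence for spatially correlated regions; the p-values
  are summaries, not calibrated genome-wide inferences.
* The ε-regularized log₂FE compresses ratios near zero coverage; use a
  small ε for quantitative contrasts.
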