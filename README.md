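# replichrom

Cell-type-specific genome regulation in *Drosophila* testis stem cells:
a tested re-implementation of the replication-timing, chromatin-profiling
and integration analyses for germline stem cells (GSC-like) versus
somatic cyst stem cells (CySC-like), exercised end-to-end on synthetic
data that emulates the sequencing inputs.  It is written for
computational biologists who want to run, audit or adapt the statistical
machinery behind Repli-seq timing scores, ChIC-ChIP chromatin tracks and
their integration with single-cell expression — without access to the
original libraries.

## What it computes

**Replication timing.**  Repli-seq fragments from four S-phase sorting
fractions (early, early-mid, late-mid, late) are midpoint-binned into
1 kb steps, depth-normalized per fraction, and collapsed per 3 kb
sliding window into early-half successes *s* and late-half failures *f*.
Each window gets a one-parameter Bayesian logistic regression: with
σ the logistic function and a Normal(0, τ²) prior on the logit timing
score θ (τ = 2),

    ℓ(θ) = s·log σ(θ) + f·log(1 − σ(θ)),
    RT   = E[2σ(θ) − 1 | s, f]  ∈ (−1, 1),

computed by trapezoid quadrature on an 801-point grid.  Positive RT is
early replication, negative is late.  LOESS smoothing produces display
tracks.

**Differential timing.**  Per window, the shared-timing null is compared
with the cell-specific model through a Bayes factor,

    BF10 = log10( ∫L_A π dθ · ∫L_B π dθ / ∫L_A L_B π dθ ),

and two-tier nested peak calling (seed log₁₀BF ≥ 1, extend ≥ 0.5, merge
gaps ≤ 3 kb) emits differential regions of at least 20 kb, labelled by
the earlier-replicating cell type.  Downstream summaries: kb earlier per
chromosome/domain with Fisher exact tests, RT Z-scores, 12-domain mean-Z
profiles, and average-linkage (UPGMA) clustering of cell types on the
root-mean-square Z difference.

**Chromatin tracks.**  ChIC-ChIP mononucleosomal fragments (width
100–200 bp) are midpoint-counted at 20 bp steps and modelled per step by
maximum-likelihood negative binomial regression with library-size
offsets — the intercept is H3 (input) abundance, the IP effect is
reported as log₂ fold change.  Predicted intensities are smoothed with a
Gaussian kernel (σ = 40 bp) and combined into log₂FE tracks; nucleosome
dyads are called as local maxima of the smoothed input density.

**Integration.**  Genes are "on" when CPM > 5, with on-genes split into
equal tertiles; differential expression uses supplied posterior log₂
fold changes (|FC| > 1.5, s-value < 10⁻⁴).  The package builds TSS and
gene-body meta-profiles with Welch tests, labels cell-specific chromatin
(log₂FE > 0.2 in one cell type and < −0.2 in the other), orders windows
early→late against mark enrichment, classifies genes by
differential-timing region overlap, and reports X:A expression ratios.

A synthetic-data module generates all inputs on a ~6 Mb toy genome (two
autosomes with arms and pericentromeres, X, Y, the dot chromosome and an
8 kb rDNA contig) with known ground truth, so every stage is testable at
desk scale.

## Worked example

```
$ python analysis/01_simulate.py --seed 1
wrote 32 fixture files to scratch/bundle
largest planted |score difference|: 0.45 at 2L_peri

$ python analysis/02_replication_timing.py --seed 1
posterior-mean score recovers ground truth with RMSE 0.0448 over 11992 windows (both cell types)

$ python analysis/03_differential_timing.py --seed 1
1 differential regions: 602 kb GSC-earlier, 0 kb CySC-earlier
largest GSC-earlier fraction: 2L_peri (100%, Fisher p = 1.00e+00)
domain-profile correlation GSC vs CySC: 0.89; RMS Z distance 0.39
```

The simulation plants a germline-specific early-replicating
pericentromere on chromosome 2 (score difference ≈ 0.5).  The timing
stage recovers the generating landscape to RMSE ≈ 0.045 on the score
scale; the comparison stage calls a single contiguous GSC-earlier region
spanning the full 602 kb planted domain and nothing on the neutral arms.
Scripts `04_chromatin_tracks.py` (nucleosome recovery, per-mark log₂FE
contrasts) and `05_integration.py` (expression categories, TSS
meta-profile with its +1-nucleosome peak, gene-level timing classes,
X:A ratios) continue the analysis; all tables land under `results/`.

The same stages run from fragment files on disk via the CLI:

```
replichrom simulate --seed 1 --out bundle/
replichrom config --defaults > config.yaml   # edit paths
replichrom run config.yaml
```

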