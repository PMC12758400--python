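"""Synthetic fixture data with the statistical structure the pipeline assumes.

Three generators emulate the study's sequencing inputs on a small toy
genome (~6 Mb):

* ``simulate_repliseq`` — four S-phase fraction count tracks per replicate
  per cell type, driven by a smooth ground-truth replication-timing
  landscape.  Per 1 kb bin, a replicate's reads are split multinomially
  over the fractions (E, EM, LM, L) with weights
  ``(p*a, p*(1-a), (1-p)*(1-a), (1-p)*a)`` where ``p`` is the true
  early-half probability and ``a`` the within-half sharpness, so the binary
  early/late collapse used by inference recovers exactly ``p``.
* ``simulate_chic`` — phased nucleosome arrays (dyad grid + jitter) with
  per-mark enrichment multipliers; input and IP mononucleosomal fragments
  with negative-binomial (gamma-mixed Poisson) per-nucleosome counts.
* ``simulate_expression`` — gene models plus a CPM table with planted
  differential expression (log2 fold changes and s-values) and per-cell-type
  cell-cycle phase compositions.

Everything is fully determined by ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import BinnedTrack, Domain, GenomeLayout

FRACTIONS = ("E", "EM", "LM", "L")


# ---------------------------------------------------------------------------
# default toy genome: 2 autosomes with arms + pericentromeres, X, Y, chr4,
# and an 8 kb rDNA unit contig.  11 chromosome-derived domains + rDNA = 12.
# ---------------------------------------------------------------------------

def default_layout() -> GenomeLayout:
    domains = [
        Domain("2L_arm", "chr2", 0, 800_000, "autosome_arm"),
        Domain("2L_peri", "chr2", 800_000, 1_100_000, "pericentromere"),
        Domain("2R_peri", "chr2", 1_100_000, 1_400_000, "pericentromere"),
        Domain("2R_arm", "chr2", 1_400_000, 2_200_000, "autosome_arm"),
        Domain("3L_arm", "chr3", 0, 700_000, "autosome_arm"),
        Domain("3L_peri", "chr3", 700_000, 1_000_000, "pericentromere"),
        Domain("3R_peri", "chr3", 1_000_000, 1_300_000, "pericentromere"),
        Domain("3R_arm", "chr3", 1_300_000, 2_000_000, "autosome_arm"),
        Domain("chrX", "chrX", 0, 1_000_000, "chrX"),
        Domain("chrY", "chrY", 0, 500_000, "chrY"),
        Domain("chr4", "chr4", 0, 300_000, "chr4"),
        Domain("rDNA", "rDNA", 0, 8_000, "rDNA_unit"),
    ]
    return GenomeLayout(
        chromosomes={"chr2": 2_200_000, "chr3": 2_000_000, "chrX": 1_000_000,
                     "chrY": 500_000, "chr4": 300_000, "rDNA": 8_000},
        domains=domains,
        autosome_names=("chr2", "chr3", "chr4"),
    )


# per-domain-class mean timing score for the baseline landscape: arms mixed,
# pericentromeres / Y late, X early-mid, chr4 / rDNA late by default.
DEFAULT_DOMAIN_SCORES = {
    "2L_arm": 0.3, "2R_arm": 0.3, "3L_arm": 0.25, "3R_arm": 0.25,
    "2L_peri": -0.5, "2R_peri": -0.5, "3L_peri": -0.55, "3R_peri": -0.55,
    "chrX": 0.45, "chrY": -0.6, "chr4": -0.4, "rDNA": -0.5,
    "unassigned": 0.0,
}


@dataclass
class RepliSimConfig:
    cell_types: tuple[str, ...] = ("GSC", "CySC")
    replicates: int = 2
    fragments_per_replicate: int = 510_000
    sharpness: float = 0.7              # within-half multinomial sharpness a
    wiggle_amplitude: float = 0.35
    wiggle_scale_bp: float = 150_000.0  # length scale of the smooth wiggle
    # per-cell-type overrides of domain mean scores (plants differentials)
    domain_scores: dict = field(default_factory=dict)
    # unequal replicate depth multipliers to exercise normalization
    depth_jitter: float = 0.3


@dataclass
class ChicSimConfig:
    cell_types: tuple[str, ...] = ("GSC", "CySC")
    marks: tuple[str, ...] = ("H3K4me3", "H3K27me3", "H3K9me3")
    spacing: int = 185                  # nucleosome repeat length, bp
    dyad_jitter_sd: float = 10.0        # per-nucleosome dyad displacement
    frag_jitter_sd: float = 10.0        # per-fragment midpoint noise (MNase)
    frag_len_mean: float = 150.0
    frag_len_sd: float = 15.0
    coverage: float = 10.0              # monosome coverage of the input
    nb_dispersion: float = 0.1          # NB variance = mu + alpha*mu^2
    enrich_multiplier: float = 4.0      # IP rate multiplier in marked regions
    plus1_boost: float = 2.0            # occupancy boost at gene +1 dyads
    plus1_jitter_sd: float = 2.0        # +1 dyads are well positioned


@dataclass
class ExprSimConfig:
    cell_types: tuple[str, ...] = ("GSC", "CySC")
    n_genes: int = 2000
    log_cpm_mean: float = 1.2           # natural-log CPM location
    log_cpm_sd: float = 1.8
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    off_fraction: float = 0.45          # genes forced near zero expression
    phase_fractions: dict = field(default_factory=lambda: {
        "GSC": {"G1": 0.25, "S": 0.5, "G2M": 0.25},
        "CySC": {"G1": 0.4, "S": 0.3, "G2M": 0.3},
    })


@dataclass
class SimConfig:
    seed: int = 0
    repli: RepliSimConfig = field(default_factory=RepliSimConfig)
    chic: ChicSimConfig = field(default_factory=ChicSimConfig)
    expression: ExprSimConfig = field(default_factory=ExprSimConfig)

    def layout(self) -> GenomeLayout:
        return default_layout()

    def rng(self, stream: str) -> np.random.Generator:
        return _stream_rng(self.seed, stream)


def _stream_rng(seed: int, label: str) -> np.random.Generator:
    # a stable digest of the label (hash() is salted per process)
    import zlib

    tag = zlib.crc32(label.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


# ---------------------------------------------------------------------------
# replication timing landscape
# ---------------------------------------------------------------------------

def timing_landscape(layout: GenomeLayout, cfg: RepliSimConfig, seed: int,
                     cell_type: str) -> BinnedTrack:
    """Ground-truth timing score per 1 kb bin, in (-0.96, 0.96).

    Domain-level mean score plus a smooth wiggle (sum of three
    low-frequency sinusoids with cell-type-shared phases), clipped so the
    early-half probability p = (score+1)/2 stays inside (0.02, 0.98).
    """
    rng = _stream_rng(seed, "landscape")  # shared across cell types
    scores = dict(DEFAULT_DOMAIN_SCORES)
    scores.update(cfg.domain_scores.get(cell_type, {}))
    from .genome import bin_domains

    labels = bin_domains(layout, 1000)
    track = BinnedTrack.zeros(layout, 1000, semantics="score")
    # shared wiggle phases so cell types differ only where domain means do
    phases = rng.uniform(0, 2 * np.pi, size=(len(layout.chromosomes), 3))
    for ci, chrom in enumerate(layout.chromosomes):
        n = layout.n_bins(chrom, 1000)
        x = (np.arange(n) * 1000.0 + 500.0)
        wig = np.zeros(n)
        for k in range(3):
            freq = 2 * np.pi * (k + 1) / cfg.wiggle_scale_bp
            wig += np.sin(freq * x + phases[ci, k]) / (k + 1)
        wig *= cfg.wiggle_amplitude / 1.833  # sum of 1+1/2+1/3 envelopes
        base = np.array([scores.get(lbl, 0.0) for lbl in labels[chrom]])
        track.data[chrom] = base + wig
    # balance the landscape so the genome-wide mean early-half probability
    # is exactly 1/2: each S-phase fraction then carries equal total
    # nascent DNA, the assumption under which fraction-depth
    # normalization is calibrated (timing scores are relative quantities)
    total = sum(v.sum() for v in track.data.values())
    nbins = sum(len(v) for v in track.data.values())
    shift = total / nbins
    for chrom in track.data:
        track.data[chrom] = np.clip(track.data[chrom] - shift, -0.96, 0.96)
    return track


@dataclass
class FractionCounts:
    """Per cell type: per replicate and S-phase fraction, 1 kb count tracks."""

    cell_type: str
    counts: dict  # counts[replicate][fraction] -> BinnedTrack
    step: int = 1000

    def replicates(self) -> list[str]:
        return list(self.counts)

    def depth(self, rep: str, frac: str, exclude_chroms: set | None = None) -> float:
        tr = self.counts[rep][frac]
        tot = 0.0
        for chrom, v in tr.data.items():
            if exclude_chroms and chrom in exclude_chroms:
                continue
            tot += float(v.sum())
        return tot


@dataclass
class RepliGroundTruth:
    p_true: BinnedTrack            # early-half probability per 1 kb bin
    score: dict                    # cell type -> BinnedTrack of 2p-1


def fraction_weights(p: np.ndarray, a: float) -> np.ndarray:
    """Multinomial fraction weights (E, EM, LM, L) for early prob p."""
    return np.stack([p * a, p * (1 - a), (1 - p) * (1 - a), (1 - p) * a], axis=-1)


def simulate_repliseq(config: SimConfig,
                      layout: GenomeLayout | None = None
                      ) -> tuple[dict, dict[str, RepliGroundTruth]]:
    """Simulate Repli-seq fraction counts for every configured cell type.

    Returns ``(tracks, truth)`` where ``tracks[cell_type]`` is a
    :class:`FractionCounts` and ``truth[cell_type]`` the generating
    landscape.  Replicate depths are deliberately unequal (uniform jitter)
    to exercise fraction-depth normalization.
    """
    cfg = config.repli
    layout = layout or config.layout()
    if cfg.fragments_per_replicate <= 0:
        raise ValueError("fragments_per_replicate must be positive")
    out: dict[str, FractionCounts] = {}
    truths: dict[str, RepliGroundTruth] = {}
    for ct in cfg.cell_types:
        rng = _stream_rng(config.seed, f"repliseq:{ct}")
        land = timing_landscape(layout, cfg, config.seed, ct)
        p_track = BinnedTrack(1000, {c: (v + 1) / 2 for c, v in land.data.items()},
                              "score")
        counts: dict[str, dict[str, BinnedTrack]] = {}
        nbins_total = sum(layout.n_bins(c, 1000) for c in layout.chromosomes)
        for r in range(cfg.replicates):
            rep = f"rep{r + 1}"
            depth = int(round(cfg.fragments_per_replicate *
                              (1 + cfg.depth_jitter * (rng.uniform() - 0.5))))
            # distribute reads over bins (uniform multinomial), then over
            # the four fractions per bin
            per_bin = rng.multinomial(depth, np.full(nbins_total, 1 / nbins_total))
            counts[rep] = {f: BinnedTrack.zeros(layout, 1000) for f in FRACTIONS}
            off = 0
            for chrom in layout.chromosomes:
                n = layout.n_bins(chrom, 1000)
                nb = per_bin[off: off + n]
                off += n
                w = fraction_weights(p_track.data[chrom], cfg.sharpness)
                draws = rng.multinomial(nb, w)  # (n, 4)
                for j, f in enumerate(FRACTIONS):
                    counts[rep][f].data[chrom][:] = draws[:, j]
        out[ct] = FractionCounts(ct, counts)
        truths[ct] = RepliGroundTruth(p_track, {ct: land})
    return out, truths


# ---------------------------------------------------------------------------
# ChIC-ChIP
# ---------------------------------------------------------------------------

@dataclass
class ChicGroundTruth:
    dyads: dict[str, np.ndarray]        # chrom -> true dyad positions (bp)
    multipliers: dict                   # mark -> chrom -> per-dyad multiplier


def _mark_multipliers(layout: GenomeLayout, dyads: dict[str, np.ndarray],
                      cfg: ChicSimConfig, cell_type: str) -> dict:
    """Ground-truth per-mark enrichment: a simple domain-driven scheme.

    H3K4me3 marks arm/X euchromatin in alternating blocks, H3K27me3 a
    subset of arm blocks, H3K9me3 pericentromeres, chr4 and Y.  The blocks
    differ slightly between cell types (phase offset) so cell-specific
    enrichment exists.
    """
    from .genome import bin_domains

    classes = {d.name: d.cls for d in layout.domains}
    out: dict[str, dict[str, np.ndarray]] = {m: {} for m in cfg.marks}
    offset = 0 if cell_type == cfg.cell_types[0] else 1
    for chrom, pos in dyads.items():
        lbl = np.array([layout.domain_at(chrom, int(p)) if 0 <= p < layout.length(chrom)
                        else "unassigned" for p in pos], dtype=object)
        cls = np.array([classes.get(l, "unassigned") for l in lbl], dtype=object)
        eu = np.isin(cls, ["autosome_arm", "chrX"])
        het = np.isin(cls, ["pericentromere", "chr4", "chrY"])
        block = ((pos // 20_000) + offset) % 4  # 20 kb blocks
        for m in cfg.marks:
            mult = np.ones(len(pos))
            if m == "H3K4me3":
                mult[eu & (block == 0)] = cfg.enrich_multiplier
            elif m == "H3K27me3":
                mult[eu & (block == 2)] = cfg.enrich_multiplier
            elif m == "H3K9me3":
                mult[het] = cfg.enrich_multiplier
            out[m][chrom] = mult
    return out


def plus1_dyad_index(tss: int, strand: str, spacing: int) -> int:
    """Grid index of the first nucleosome dyad downstream of a TSS."""
    grid0 = spacing // 2
    target = tss + (spacing // 2 if strand == "+" else -spacing // 2)
    return int(round((target - grid0) / spacing))


def simulate_chic(config: SimConfig, layout: GenomeLayout | None = None,
                  chroms: list[str] | None = None,
                  genes: pd.DataFrame | None = None,
                  ) -> tuple[dict, dict[str, ChicGroundTruth]]:
    """Simulate input (H3) and IP mononucleosomal fragments per cell type.

    Returns ``(samples, truth)``: ``samples[cell_type]["input"]`` and
    ``samples[cell_type][mark]`` are fragment DataFrames
    (chrom/start/end/mapq); ``truth[cell_type]`` holds the jittered dyads
    and per-mark multipliers.  Per-nucleosome fragment counts are
    gamma-mixed Poisson, i.e. negative binomial with the configured
    dispersion.
    """
    cfg = config.chic
    layout = layout or config.layout()
    if cfg.spacing <= cfg.frag_len_mean / 2:
        raise ValueError("nucleosome spacing <= fragment mean / 2: phasing "
                         "unresolvable")
    chroms = chroms or list(layout.chromosomes)
    samples: dict[str, dict[str, pd.DataFrame]] = {}
    truths: dict[str, ChicGroundTruth] = {}
    frags_per_nuc = cfg.coverage * cfg.spacing / cfg.frag_len_mean
    for ct in cfg.cell_types:
        rng = _stream_rng(config.seed, f"chic:{ct}")
        dyads: dict[str, np.ndarray] = {}
        boost: dict[str, np.ndarray] = {}
        for chrom in chroms:
            L = layout.length(chrom)
            grid = np.arange(cfg.spacing // 2, L - cfg.spacing // 2, cfg.spacing,
                             dtype=float)
            jitter_sd = np.full(len(grid), cfg.dyad_jitter_sd)
            occ = np.ones(len(grid))
            if genes is not None:
                # the +1 nucleosome downstream of a TSS is strongly
                # positioned and occupancy-enriched (promoter phasing)
                sub = genes[genes["chrom"] == chrom]
                idx = [plus1_dyad_index(int(t), s, cfg.spacing)
                       for t, s in zip(sub["tss"], sub["strand"])]
                idx = np.array([i for i in idx if 0 <= i < len(grid)],
                               dtype=int)
                jitter_sd[idx] = cfg.plus1_jitter_sd
                occ[idx] = cfg.plus1_boost
            dyads[chrom] = grid + rng.normal(0, 1, len(grid)) * jitter_sd
            boost[chrom] = occ
        mults = _mark_multipliers(layout, dyads, cfg, ct)
        truths[ct] = ChicGroundTruth(dyads, mults)
        roles = {"input": None, **{m: m for m in cfg.marks}}
        samples[ct] = {}
        for role, mark in roles.items():
            frames = []
            for chrom in chroms:
                d = dyads[chrom]
                rate = frags_per_nuc * boost[chrom]
                if mark is not None:
                    rate = rate * mults[mark][chrom]
                    rate = rate * (len(d) * frags_per_nuc / rate.sum())  # match depth
                lam = rng.gamma(1 / cfg.nb_dispersion,
                                cfg.nb_dispersion * rate)
                n = rng.poisson(lam)
                mid = np.repeat(d, n) + rng.normal(0, cfg.frag_jitter_sd,
                                                   int(n.sum()))
                length = rng.normal(cfg.frag_len_mean, cfg.frag_len_sd,
                                    int(n.sum()))
                length = np.clip(length, 1, None)
                start = np.maximum(np.round(mid - length / 2), 0).astype(np.int64)
                end = np.minimum(np.round(mid + length / 2),
                                 layout.length(chrom)).astype(np.int64)
                ok = start < end
                frames.append(pd.DataFrame({
                    "chrom": chrom, "start": start[ok], "end": end[ok],
                    "mapq": np.int64(60),
                }))
            samples[ct][role] = pd.concat(frames, ignore_index=True)
    return samples, truths


# ---------------------------------------------------------------------------
# expression + gene models
# ---------------------------------------------------------------------------

BIOTYPES = ("protein_coding", "lncRNA", "miRNA", "other")
BIOTYPE_PROBS = (0.70, 0.18, 0.06, 0.06)


def simulate_genes(config: SimConfig, layout: GenomeLayout | None = None
                   ) -> pd.DataFrame:
    """Gene models: id, chrom, strand, TSS, span, biotype.

    TSSs snap to the nucleosome grid so the +1 dyad sits a fixed offset
    downstream of the TSS (half the nucleosome spacing).
    """
    cfg = config.expression
    layout = layout or config.layout()
    rng = _stream_rng(config.seed, "genes")
    chrom_names = [c for c in layout.chromosomes if c not in layout.rdna_chroms()]
    lens = np.array([layout.length(c) for c in chrom_names], dtype=float)
    probs = lens / lens.sum()
    spacing = config.chic.spacing
    rows = []
    for i in range(cfg.n_genes):
        chrom = chrom_names[rng.choice(len(chrom_names), p=probs)]
        L = layout.length(chrom)
        span = int(np.clip(rng.lognormal(8.0, 0.6), 2000, 50_000))
        strand = "+" if rng.uniform() < 0.5 else "-"
        # snap TSS to the dyad grid minus half a spacing (+1 dyad downstream)
        pos = rng.integers(2000, max(L - span - 2000, 2001))
        grid0 = spacing // 2
        k = round((pos - grid0) / spacing)
        tss = int(grid0 + k * spacing - spacing // 2)
        tss = int(np.clip(tss, 1500, L - span - 1500))
        if strand == "+":
            start, end = tss, tss + span
        else:
            start, end = tss - span + 1, tss + 1
        biotype = BIOTYPES[rng.choice(len(BIOTYPES), p=BIOTYPE_PROBS)]
        rows.append((f"gene{i:05d}", chrom, strand, tss, start, end, biotype))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss",
                                       "start", "end", "biotype"])


def simulate_expression(config: SimConfig, genes: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Per-gene expression table across cell types.

    Columns: gene_id, cpm_<ct> per cell type, log2fc (A vs B, first two
    cell types), s_value, de_label (A/B/none).  CPM columns each sum to
    1e6 up to rounding.  A fixed count (``round(de_fraction * n_genes)``)
    of genes is differentially expressed.
    """
    cfg = config.expression
    rng = _stream_rng(config.seed, "expression")
    if genes is None:
        genes = simulate_genes(config)
    n = len(genes)
    base = rng.lognormal(cfg.log_cpm_mean, cfg.log_cpm_sd, n)
    off = rng.uniform(size=n) < cfg.off_fraction
    base[off] *= rng.uniform(0.0, 0.02, off.sum())
    a, b = cfg.cell_types[:2]
    expr_a = base.copy()
    expr_b = base.copy()
    n_de = int(round(cfg.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    half = n_de // 2
    up_a = de_idx[:half]
    up_b = de_idx[half:]
    expr_a[up_a] *= 2.0 ** cfg.de_log2fc
    expr_b[up_b] *= 2.0 ** cfg.de_log2fc
    cpm_a = expr_a / expr_a.sum() * 1e6
    cpm_b = expr_b / expr_b.sum() * 1e6
    log2fc = np.where(np.isin(np.arange(n), up_a), cfg.de_log2fc,
                      np.where(np.isin(np.arange(n), up_b), -cfg.de_log2fc, 0.0))
    s_value = np.where(log2fc != 0,
                       rng.uniform(0, 1e-8, n),
                       np.clip(rng.uniform(0.5, 1.0, n), 0, 1))
    de_label = np.where(np.isin(np.arange(n), up_a), a,
                        np.where(np.isin(np.arange(n), up_b), b, "none"))
    table = pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        f"cpm_{a}": cpm_a,
        f"cpm_{b}": cpm_b,
        "log2fc": log2fc,
        "s_value": s_value,
        "de_label": de_label,
    })
    return table


def phase_table(config: SimConfig, cells_per_type: int = 300) -> pd.DataFrame:
    """Per-cell-type cell-cycle phase cell counts."""
    cfg = config.expression
    rows = []
    for ct, fr in cfg.phase_fractions.items():
        for phase, f in fr.items():
            rows.append((ct, phase, int(round(cells_per_type * f))))
    return pd.DataFrame(rows, columns=["cell_type", "phase", "n_cells"])


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def counts_to_fragments(track: BinnedTrack, rng: np.random.Generator,
                        read_len: int = 100) -> pd.DataFrame:
    """Expand a 1 kb count track into single-end-like fragment records.

    Each counted fragment gets a uniform start within its bin such that the
    midpoint stays in the bin (used when writing Repli-seq fixture TSVs).
    """
    frames = []
    for chrom, v in track.data.items():
        counts = v.astype(np.int64)
        tot = int(counts.sum())
        if tot == 0:
            continue
        bins = np.repeat(np.arange(len(counts)), counts)
        # midpoint uniform in [bin*step, (bin+1)*step)
        mid = bins * track.step + rng.integers(read_len // 2,
                                               track.step - read_len // 2,
                                               tot)
        start = mid - read_len // 2
        end = start + read_len
        frames.append(pd.DataFrame({"chrom": chrom, "start": start,
                                    "end": end, "mapq": np.int64(60)}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "mapq"])
    return pd.concat(frames, ignore_index=True)


def write_bundle(config: SimConfig, outdir) -> dict:
    """Write a full fixture bundle (layout, fragment TSVs, gene models,
    expression, ground truth) and return its manifest."""
    import json
    import os

    import yaml

    os.makedirs(outdir, exist_ok=True)
    layout = config.layout()
    manifest: dict = {"seed": config.seed, "files": {}}

    def save(df: pd.DataFrame, name: str, header: bool):
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", index=False, header=header)
        manifest["files"][name] = len(df)

    with open(os.path.join(outdir, "layout.yaml"), "w") as fh:
        yaml.safe_dump(layout.to_dict(), fh, sort_keys=False)
    manifest["files"]["layout.yaml"] = 1

    rng = _stream_rng(config.seed, "bundle")
    repli, truth = simulate_repliseq(config, layout)
    for ct, fc in repli.items():
        for rep in fc.replicates():
            for frac in FRACTIONS:
                frags = counts_to_fragments(fc.counts[rep][frac], rng)
                save(frags, f"repli_{ct}_{rep}_{frac}.tsv", header=False)
        tdf = []
        for chrom, v in truth[ct].p_true.data.items():
            tdf.append(pd.DataFrame({"chrom": chrom,
                                     "bin_start": np.arange(len(v)) * 1000,
                                     "p_true": v}))
        save(pd.concat(tdf, ignore_index=True), f"truth_repli_{ct}.tsv",
             header=True)

    genes = simulate_genes(config, layout)
    chic, ctruth = simulate_chic(config, layout, genes=genes)
    for ct, roles in chic.items():
        for role, frags in roles.items():
            save(frags, f"chic_{ct}_{role}.tsv", header=False)
        rows = []
        for chrom, d in ctruth[ct].dyads.items():
            rows.append(pd.DataFrame({"chrom": chrom, "dyad": np.round(d).astype(int)}))
        save(pd.concat(rows, ignore_index=True), f"truth_dyads_{ct}.tsv",
             header=True)

    save(genes, "genes.tsv", header=True)
    expr = simulate_expression(config, genes)
    save(expr, "expression.tsv", header=True)
    save(phase_table(config), "phases.tsv", header=True)

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
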