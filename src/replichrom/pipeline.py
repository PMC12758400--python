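"""End-to-end orchestration on a fixture bundle.

Stages run in dependency order (replication timing and chromatin tracks
independent, then differential timing, then integration); every output
file lands in the manifest with a sha256 checksum, and reruns with the
same config and inputs are bit-identical apart from timestamps (which are
kept out of the outputs entirely).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import chic as chic_mod
from . import diffrt, integrate, repli, trackio
from .config import PipelineConfig
from .genome import GenomeLayout, load_fragments
from .simulate import FRACTIONS

logger = logging.getLogger(__name__)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _require(path, stage: str):
    if not os.path.exists(path):
        raise PipelineError(stage, f"missing input {path}")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the bundle at ``config.input_dir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    config.validate()
    p = config.params
    indir = config.input_dir
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    layout = GenomeLayout.from_dict(
        yaml.safe_load(open(_require(os.path.join(indir, config.layout),
                                     "layout"))))
    manifest: dict = {"outputs": {}, "counts": {}}

    def emit(name: str):
        path = os.path.join(outdir, name)
        manifest["outputs"][name] = _sha256(path)
        return path

    # -- replication timing per cell type ---------------------------------
    stage = "repli_timing"
    tracks: dict[str, repli.TimingTrack] = {}
    windows: dict[str, repli.WindowTable] = {}
    grid = (p.grid_lo, p.grid_hi, p.grid_points)
    for ct in config.cell_types:
        frag_tables: dict = {}
        for r in range(config.replicates):
            rep = f"rep{r + 1}"
            frag_tables[rep] = {}
            for frac in FRACTIONS:
                path = _require(
                    os.path.join(indir, f"repli_{ct}_{rep}_{frac}.tsv"), stage)
                frags = load_fragments(path, mapq_min=p.mapq_min,
                                       layout=layout)
                manifest["counts"][f"repli_{ct}_{rep}_{frac}"] = len(frags)
                frag_tables[rep][frac] = frags
        fc = repli.fraction_counts_from_fragments(
            ct, frag_tables, layout, step=p.repli_bin_bp,
            max_width=p.repli_max_width)
        scaled = repli.normalize_fractions(fc, layout)
        wt = repli.window_observations(scaled, window_bins=p.window_bins)
        tt = repli.timing_track(wt, prior_sd=p.prior_sd, grid=grid)
        windows[ct] = wt
        tracks[ct] = tt
        smooth = repli.loess_track(tt, span_bp=p.loess_span_bp)
        trackio.write_bedgraph(tt.as_binned(layout),
                               os.path.join(outdir, f"rt_{ct}.bedGraph"))
        emit(f"rt_{ct}.bedGraph")
        trackio.write_bedgraph(smooth.as_binned(layout),
                               os.path.join(outdir, f"rt_{ct}_loess.bedGraph"))
        emit(f"rt_{ct}_loess.bedGraph")
    logger.info("replication timing done (%d cell types)", len(tracks))

    # -- chromatin tracks per cell type / mark ----------------------------
    stage = "chic_tracks"
    fe_tracks: dict[str, dict[str, object]] = {}
    norm_input: dict[str, object] = {}
    for ct in config.cell_types:
        input_path = os.path.join(indir, f"chic_{ct}_input.tsv")
        if not os.path.exists(input_path):
            logger.info("no ChIC input for %s; skipping chromatin stage", ct)
            continue
        in_frags = load_fragments(input_path, mapq_min=p.mapq_min,
                                  layout=layout)
        in_counts = chic_mod.filter_and_count(
            in_frags, layout, p.mono_len_min, p.mono_len_max, p.chic_step_bp)
        norm_input[ct] = chic_mod.autosomal_median_normalize(in_counts, layout)
        in_sample = chic_mod.ChicSample(f"{ct}_input", "input", in_counts)
        fe_tracks[ct] = {}
        for mark in config.marks:
            mark_path = os.path.join(indir, f"chic_{ct}_{mark}.tsv")
            if not os.path.exists(mark_path):
                continue
            ip_frags = load_fragments(mark_path, mapq_min=p.mapq_min,
                                      layout=layout)
            ip_counts = chic_mod.filter_and_count(
                ip_frags, layout, p.mono_len_min, p.mono_len_max,
                p.chic_step_bp)
            fit = chic_mod.fit_nb_per_step(
                [chic_mod.ChicSample(f"{ct}_input", "input",
                                     in_counts.copy())],
                [chic_mod.ChicSample(f"{ct}_{mark}", "IP", ip_counts)],
                layout)
            ip_dens = chic_mod.gaussian_density(fit.ip_intensity(), p.sigma_bp)
            in_dens = chic_mod.gaussian_density(fit.input_intensity(),
                                                p.sigma_bp)
            fe = chic_mod.log2fe(ip_dens, in_dens, p.epsilon)
            fe_tracks[ct][mark] = fe
            trackio.write_bedgraph(
                fe, os.path.join(outdir, f"log2fe_{ct}_{mark}.bedGraph"))
            emit(f"log2fe_{ct}_{mark}.bedGraph")
        dens = chic_mod.gaussian_density(norm_input[ct], p.sigma_bp)
        calls = chic_mod.call_nucleosomes(dens, p.min_prominence)
        trackio.write_bed6(
            [trackio.Region(c.chrom, c.dyad - p.chic_step_bp // 2,
                            c.dyad + p.chic_step_bp // 2, "nucleosome",
                            c.prominence) for c in calls],
            os.path.join(outdir, f"nucleosomes_{ct}.bed"))
        emit(f"nucleosomes_{ct}.bed")
        manifest["counts"][f"nucleosomes_{ct}"] = len(calls)

    # -- differential timing ----------------------------------------------
    stage = "differential_timing"
    regions = []
    if len(config.cell_types) >= 2:
        a, b = config.cell_types[:2]
        comp = diffrt.compare_windows(windows[a], windows[b],
                                      prior_sd=p.prior_sd, grid=grid)
        trackio.write_tsv(comp.to_frame(),
                          os.path.join(outdir, "windows_compare.tsv"))
        emit("windows_compare.tsv")
        regions = diffrt.call_differential_regions(
            comp, seed_bf=p.seed_bf, extend_bf=p.extend_bf,
            max_gap_bp=p.max_gap_bp, min_len_bp=p.min_region_bp)
        trackio.write_bed6([r.to_region(a, b) for r in regions],
                           os.path.join(outdir, "differential_regions.bed"))
        emit("differential_regions.bed")
        totals = diffrt.earlier_totals(regions, layout)
        trackio.write_tsv(totals, os.path.join(outdir, "earlier_totals.tsv"))
        emit("earlier_totals.tsv")
        zs = diffrt.zscore_tracks(tracks)
        summary = diffrt.domain_summary(zs, layout)
        trackio.write_tsv(summary, os.path.join(outdir,
                                                "domain_summary.tsv"))
        emit("domain_summary.tsv")
        corr = diffrt.domain_profile_correlations(summary, zs.cell_types)
        trackio.write_tsv(corr, os.path.join(outdir,
                                             "domain_correlations.tsv"))
        emit("domain_correlations.tsv")
        tree = diffrt.cluster_cell_types(zs, layout)
        dist_df = pd.DataFrame(tree.distance, index=tree.cell_types,
                               columns=tree.cell_types)
        dist_df.to_csv(os.path.join(outdir, "distance_matrix.tsv"), sep="\t")
        emit("distance_matrix.tsv")
        with open(os.path.join(outdir, "cell_tree.nwk"), "w") as fh:
            fh.write(tree.newick + "\n")
        emit("cell_tree.nwk")
        manifest["counts"]["differential_regions"] = len(regions)

    # -- expression integration -------------------------------------------
    stage = "expression_integration"
    expr_path = os.path.join(indir, "expression.tsv")
    genes_path = os.path.join(indir, "genes.tsv")
    if os.path.exists(expr_path) and os.path.exists(genes_path):
        expr = pd.read_csv(expr_path, sep="\t")
        genes = pd.read_csv(genes_path, sep="\t")
        expr = expr.set_index("gene_id")
        cat_tables = {}
        for ct in config.cell_types:
            col = f"cpm_{ct}"
            if col not in expr.columns:
                continue
            cats = integrate.classify_expression(expr[col], p.cpm_threshold)
            cat_tables[ct] = cats
        cat_df = pd.DataFrame(cat_tables)
        cat_df.index.name = "gene_id"
        cat_df.reset_index().to_csv(
            os.path.join(outdir, "expression_categories.tsv"),
            sep="\t", index=False)
        emit("expression_categories.tsv")
        a_set, b_set = integrate.de_filter(expr, p.fc_min, p.s_max)
        with open(os.path.join(outdir, "de_sets.json"), "w") as fh:
            json.dump({"A_enriched": sorted(a_set), "B_enriched":
                       sorted(b_set)}, fh, indent=2)
        emit("de_sets.json")
        manifest["counts"]["de_A"] = len(a_set)
        manifest["counts"]["de_B"] = len(b_set)
        # cell-specific chromatin (first mark with both cell types)
        if len(config.cell_types) >= 2:
            a, b = config.cell_types[:2]
            for mark in config.marks:
                if mark in fe_tracks.get(a, {}) and mark in \
                        fe_tracks.get(b, {}):
                    labels, pct = integrate.cellspec_enrichment_domains(
                        fe_tracks[a][mark], fe_tracks[b][mark], layout,
                        p.fe_hi, p.fe_lo)
                    pct.insert(0, "mark", mark)
                    trackio.write_tsv(
                        pct, os.path.join(outdir,
                                          f"cellspec_{mark}.tsv"))
                    emit(f"cellspec_{mark}.tsv")
            gene_table = integrate.gene_rt_classification(
                tracks, regions, genes, de_sets=(a_set, b_set))
            trackio.write_tsv(gene_table,
                              os.path.join(outdir, "gene_rt.tsv"))
            emit("gene_rt.tsv")
        # X:A ratio per cell type
        xa = {}
        for ct in config.cell_types:
            col = f"cpm_{ct}"
            if col in expr.columns:
                xa[ct] = integrate.xa_ratio(expr.reset_index(), genes, layout,
                                            col, p.cpm_threshold)
        with open(os.path.join(outdir, "xa_ratio.json"), "w") as fh:
            json.dump(xa, fh, indent=2)
        emit("xa_ratio.json")

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
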