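#!/usr/bin/env python
"""Infer replication timing per cell type and check ground-truth recovery.

Regenerates the simulated fraction counts (same seed as 01), runs
fraction-depth normalization, 3 kb window assembly and the Bayesian
posterior timing score, and writes per-domain mean scores plus the
recovery error to results/.
"""

import argparse
import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from replichrom import repli
from replichrom.simulate import simulate_repliseq

sys.path.insert(0, os.path.dirname(__file__))
from importlib import import_module

planted_config = import_module("01_simulate").planted_config


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    cfg = planted_config(args.seed)
    layout = cfg.layout()
    tracks, truth = simulate_repliseq(cfg, layout)

    rows, errs = [], []
    for ct, fc in tracks.items():
        scaled = repli.normalize_fractions(fc, layout)
        wt = repli.window_observations(scaled)
        tt = repli.timing_track(wt)
        sm = repli.loess_track(tt)
        p = truth[ct].p_true
        for chrom in tt.chroms():
            c = tt.centers[chrom]
            if len(c) == 0:
                continue
            target = 2 * ((p.data[chrom][c - 1] + p.data[chrom][c] +
                           p.data[chrom][c + 1]) / 3) - 1
            errs.append(tt.rt[chrom] - target)
            for d in layout.domains:
                if d.chrom != chrom:
                    continue
                centers_bp = c * 1000 + 500
                m = (centers_bp >= d.start) & (centers_bp < d.end)
                if m.any():
                    rows.append({
                        "cell_type": ct, "domain": d.name,
                        "mean_rt": float(tt.rt[chrom][m].mean()),
                        "mean_rt_loess": float(sm.rt[chrom][m].mean()),
                        "mean_sd": float(tt.sd[chrom][m].mean()),
                        "n_windows": int(m.sum()),
                        "autocorr_lag1": wt.autocorr[chrom]})
    errs = np.concatenate(errs)
    rmse = float(np.sqrt(np.mean(errs ** 2)))
    os.makedirs(args.results, exist_ok=True)
    out = os.path.join(args.results, "rt_domain_summary.tsv")
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    print(f"per-domain timing -> {out}")
    print(f"posterior-mean score recovers ground truth with RMSE "
          f"{rmse:.4f} over {len(errs)} windows (both cell types)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
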