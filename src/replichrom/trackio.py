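"""bedGraph / BED6 / TSV readers and writers.

Coordinates stay 0-based half-open on disk.  bedGraph writing merges runs
of equal value; round-trips reproduce values to <= 1e-6 relative error.
Regions are BED6 with the direction label in the name field and
score = log10 Bayes factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinnedTrack, GenomeLayout


@dataclass
class Region:
    """A called genomic region (e.g. a differential-timing domain)."""

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a dense track as bedGraph, merging runs of equal value."""
    with open(path, "w") as fh:
        for chrom, values in track.data.items():
            if len(values) == 0:
                continue
            # run-length encode
            change = np.nonzero(np.diff(values))[0]
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(values)]))
            for s, e in zip(starts, ends):
                v = values[s]
                fh.write(f"{chrom}\t{s * track.step}\t{e * track.step}\t{v:.6g}\n")


def read_bedgraph(path, layout: GenomeLayout, step: int,
                  semantics: str = "score") -> BinnedTrack:
    track = BinnedTrack.zeros(layout, step, semantics=semantics)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}")
            chrom, start, end, value = parts
            try:
                s, e, v = int(start), int(end), float(value)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}") from exc
            if chrom not in track.data:
                raise ValueError(f"{path}: unknown chromosome {chrom!r} line {lineno}")
            if s % step or e % step:
                raise ValueError(f"{path}: interval not step-aligned, line {lineno}")
            track.data[chrom][s // step: e // step] = v
    return track


def write_bed6(regions: list[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:.6g}\t"
                     f"{r.strand}\n")


def read_bed6(path) -> list[Region]:
    out: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: malformed BED6 line {lineno}")
            out.append(Region(parts[0], int(parts[1]), int(parts[2]),
                              parts[3], float(parts[4]), parts[5]))
    return out


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
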