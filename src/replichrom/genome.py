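"""Genome coordinate system, fragment tables, binning and domain assignment.

All coordinates are 0-based half-open (BED convention).  A fragment's
midpoint is ``floor((start + end) / 2)`` and falls into bin
``floor(midpoint / step)``; bins are anchored at position 0 on every
chromosome.  Fragment sets are kept as pandas DataFrames with columns
``chrom``, ``start``, ``end``, ``mapq`` (and optionally ``sample_id``,
``paired``); one row corresponds to one sequenced fragment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAIN_CLASSES = (
    "autosome_arm",
    "pericentromere",
    "chr4",
    "chrX",
    "chrY",
    "rDNA_unit",
)

FRAGMENT_COLUMNS = ("chrom", "start", "end", "mapq")


@dataclass(frozen=True)
class Domain:
    """A named chromosomal domain (half-open interval)."""

    name: str
    chrom: str
    start: int
    end: int
    cls: str

    def __post_init__(self) -> None:
        if self.cls not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain class {self.cls!r} for {self.name!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"domain {self.name!r}: require 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeLayout:
    """Chromosome lengths plus named domains.

    Parameters
    ----------
    chromosomes : ordered mapping of chromosome name -> length in bp.
    domains : the named domains (arms, pericentromeres, chr4, X, Y, rDNA).
    autosome_names : chromosomes counted as autosomal for normalization
        (the rDNA contig is never autosomal even if listed).
    """

    chromosomes: dict[str, int]
    domains: list[Domain] = field(default_factory=list)
    autosome_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.chromosomes = dict(self.chromosomes)
        self.autosome_names = tuple(self.autosome_names)
        self.validate()

    def validate(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        for d in self.domains:
            if d.chrom not in self.chromosomes:
                raise ValueError(f"domain {d.name!r} on unknown chromosome {d.chrom!r}")
            if d.end > self.chromosomes[d.chrom]:
                raise ValueError(f"domain {d.name!r} exceeds chromosome {d.chrom!r}")
        # covering domains must not overlap (any class): assign_domain must be
        # a function of position.
        by_chrom: dict[str, list[Domain]] = {}
        for d in self.domains:
            by_chrom.setdefault(d.chrom, []).append(d)
        for chrom, ds in by_chrom.items():
            ds = sorted(ds, key=lambda d: d.start)
            for a, b in zip(ds, ds[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"domains {a.name!r} and {b.name!r} overlap on {chrom}"
                    )
        for name in self.autosome_names:
            if name not in self.chromosomes:
                raise ValueError(f"autosome {name!r} not in layout")
        if not any(
            n in self.chromosomes for n in self.autosome_names
        ):
            raise ValueError("at least one autosome is required")

    # -- queries -----------------------------------------------------------
    def length(self, chrom: str) -> int:
        return self.chromosomes[chrom]

    def n_bins(self, chrom: str, step: int) -> int:
        return -(-self.chromosomes[chrom] // step)

    def domain_at(self, chrom: str, pos: int) -> str:
        """Name of the unique domain covering ``chrom:pos``, or ``"unassigned"``."""
        if chrom not in self.chromosomes:
            raise KeyError(chrom)
        if not (0 <= pos < self.chromosomes[chrom]):
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        for d in self.domains:
            if d.chrom == chrom and d.start <= pos < d.end:
                return d.name
        return "unassigned"

    def domain_names(self) -> list[str]:
        return [d.name for d in self.domains]

    def domain(self, name: str) -> Domain:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)

    def is_autosomal(self, chrom: str) -> bool:
        return chrom in self.autosome_names

    def rdna_chroms(self) -> set[str]:
        return {d.chrom for d in self.domains if d.cls == "rDNA_unit"}

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "chromosomes": dict(self.chromosomes),
            "autosome_names": list(self.autosome_names),
            "domains": [
                {"name": d.name, "chrom": d.chrom, "start": d.start,
                 "end": d.end, "class": d.cls}
                for d in self.domains
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GenomeLayout":
        domains = [
            Domain(d["name"], d["chrom"], int(d["start"]), int(d["end"]), d["class"])
            for d in payload.get("domains", [])
        ]
        return cls(
            chromosomes={k: int(v) for k, v in payload["chromosomes"].items()},
            domains=domains,
            autosome_names=tuple(payload.get("autosome_names", ())),
        )


@dataclass
class BinnedTrack:
    """Dense per-chromosome vectors at a fixed step, anchored at position 0.

    ``semantics`` records what the numbers mean (``count``, ``density`` or
    ``score``); counts must be non-negative.
    """

    step: int
    data: dict[str, np.ndarray]
    semantics: str = "count"

    @classmethod
    def zeros(cls, layout: GenomeLayout, step: int, semantics: str = "count",
              dtype=float) -> "BinnedTrack":
        return cls(
            step=step,
            data={c: np.zeros(layout.n_bins(c, step), dtype=dtype)
                  for c in layout.chromosomes},
            semantics=semantics,
        )

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.step, {c: v.copy() for c, v in self.data.items()},
                           self.semantics)

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def chroms(self) -> list[str]:
        return list(self.data)


# ---------------------------------------------------------------------------
# fragment I/O and binning
# ---------------------------------------------------------------------------

def load_fragments(path, mapq_min: int = 20, layout: GenomeLayout | None = None,
                   sample_id: str | None = None) -> pd.DataFrame:
    """Read a headerless fragment TSV (chrom, start, end[, mapq]).

    Records with ``mapq < mapq_min`` are dropped (uniquely-mapped filter);
    rows failing basic coordinate checks raise with their line number.
    Missing mapq columns are treated as mapq 255 (always kept).
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "mapq"],
            usecols=[0, 1, 2, 3],
            dtype={0: str, 1: np.int64, 2: np.int64, 3: np.int64},
        )
    except ValueError:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end"], usecols=[0, 1, 2],
                         dtype={0: str, 1: np.int64, 2: np.int64})
        df["mapq"] = 255
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise ValueError(f"{path}: start >= end at line {bad[0] + 1}")
    if layout is not None:
        known = set(layout.chromosomes)
        unknown = df.index[~df["chrom"].isin(known)]
        if len(unknown):
            line = unknown[0] + 1
            raise ValueError(
                f"{path}: unknown chromosome {df.at[unknown[0], 'chrom']!r} "
                f"at line {line}"
            )
        lens = df["chrom"].map(layout.chromosomes)
        over = df.index[df["end"] > lens]
        if len(over):
            raise ValueError(f"{path}: fragment end beyond chromosome at line "
                             f"{over[0] + 1}")
    kept = df[df["mapq"] >= mapq_min].reset_index(drop=True)
    logger.info("load_fragments(%s): kept %d, dropped %d (mapq < %d)",
                path, len(kept), len(df) - len(kept), mapq_min)
    if sample_id is not None:
        kept["sample_id"] = sample_id
    return kept


def fragment_widths(frags: pd.DataFrame) -> np.ndarray:
    return (frags["end"] - frags["start"]).to_numpy()


def bin_midpoints(frags: pd.DataFrame, step: int, layout: GenomeLayout,
                  max_width: int | None = None) -> BinnedTrack:
    """Bin fragment midpoints into non-overlapping ``step``-bp bins.

    Each retained fragment (width <= ``max_width`` when given) increments
    exactly one bin, so the track total equals the retained-fragment count.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    track = BinnedTrack.zeros(layout, step, semantics="count")
    if len(frags) == 0:
        return track
    sel = frags
    if max_width is not None:
        sel = frags[(frags["end"] - frags["start"]) <= max_width]
    mid = (sel["start"].to_numpy() + sel["end"].to_numpy()) // 2
    idx = mid // step
    for chrom, sub in pd.DataFrame({"chrom": sel["chrom"].to_numpy(),
                                    "bin": idx}).groupby("chrom", sort=False):
        if chrom not in track.data:
            raise KeyError(f"chromosome {chrom!r} not in layout")
        counts = np.bincount(sub["bin"].to_numpy(),
                             minlength=len(track.data[chrom]))
        track.data[chrom] += counts[: len(track.data[chrom])]
    return track


def assign_domain(chrom: str, pos: int, layout: GenomeLayout) -> str:
    """Domain name covering a position, or ``"unassigned"``."""
    return layout.domain_at(chrom, pos)


def bin_domains(layout: GenomeLayout, step: int) -> dict[str, np.ndarray]:
    """Vector of domain labels per bin (label of the bin's start position)."""
    out: dict[str, np.ndarray] = {}
    for chrom in layout.chromosomes:
        n = layout.n_bins(chrom, step)
        labels = np.full(n, "unassigned", dtype=object)
        for d in layout.domains:
            if d.chrom != chrom:
                continue
            lo = -(-d.start // step)  # first bin whose start is inside
            hi = -(-d.end // step)
            lo = max(lo, 0)
            labels[lo:min(hi, n)] = d.name
        out[chrom] = labels
    return out
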