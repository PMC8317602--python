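"""Candidate sweep regions: top-1% intersection and gene co-localization.

A window is a candidate selective-sweep region when it sits in the top 1%
of all three statistics (F_ST, -ZHp, normalized XP-CLR) simultaneously.
Candidates are annotated with every gene overlapping the window by at
least 1 bp (genes 1-based inclusive, windows half-open); adjacent
candidate windows stay separate rows, so a gene spanning two windows
appears in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError
from .window_stats import WindowKey

logger = logging.getLogger(__name__)


@dataclass
class CandidateRegion:
    """One candidate window with its statistics and overlapping genes
    (ordered by genomic start, deduplicated; empty list renders as '-')."""

    key: WindowKey
    fst: float = float("nan")
    hp: float = float("nan")
    zhp: float = float("nan")
    xpclr: float = float("nan")
    genes: list = field(default_factory=list)


def intersect_top_windows(set_a, set_b, set_c) -> list:
    """Exact three-way intersection of top-window keys, sorted by
    (chromosome, start).  All sets must share one window grid."""
    sets = [set(set_a), set(set_b), set(set_c)]
    sizes = {k.end - k.start for s in sets for k in s}
    if len(sizes) > 1:
        raise ConfigError(f"window sets use different grids: sizes {sorted(sizes)}")
    out = sorted(sets[0] & sets[1] & sets[2])
    logger.info("three-way top-window intersection: %d candidates", len(out))
    return out


def overlap_genes(candidates, genes: pd.DataFrame, stats: pd.DataFrame | None = None) -> list:
    """Attach overlapping genes (and optionally per-window statistics) to
    candidate windows.

    A gene [start, end] overlaps a window iff ``gene.start <= window.end``
    and ``gene.end > window.start`` — at least 1 bp shared under the
    window's half-open occupancy.  ``stats`` may carry columns
    fst/hp/zhp/xpclr indexed by (chrom, start).
    """
    trees: dict = {}
    for g in genes.itertuples(index=False):
        trees.setdefault(g.chrom, IntervalTree()).addi(
            int(g.start), int(g.end) + 1, g.symbol)
    lookup = {}
    if stats is not None:
        for r in stats.itertuples(index=False):
            lookup[(r.chrom, int(r.start))] = r
    regions = []
    for key in sorted(candidates):
        key = WindowKey(*key)
        hits = trees.get(key.chrom, IntervalTree()).overlap(key.start + 1, key.end + 1)
        ordered = sorted(hits, key=lambda iv: (iv.begin, iv.data))
        symbols = list(dict.fromkeys(iv.data for iv in ordered))
        region = CandidateRegion(key=key, genes=symbols)
        row = lookup.get((key.chrom, key.start))
        if row is not None:
            for attr in ("fst", "hp", "zhp", "xpclr"):
                if hasattr(row, attr):
                    setattr(region, attr, float(getattr(row, attr)))
        regions.append(region)
    return regions


@dataclass
class SweepReport:
    """Summary of the candidate-region table."""

    regions: list
    distinct_genes: list
    geneless: list

    @property
    def n_distinct_genes(self) -> int:
        return len(self.distinct_genes)

    @property
    def n_geneless(self) -> int:
        return len(self.geneless)


def summarize(regions) -> SweepReport:
    """Count distinct gene symbols once across all regions and tally
    regions without any overlapping gene."""
    seen: dict = {}
    geneless = []
    for r in regions:
        if not r.genes:
            geneless.append(r.key)
        for g in r.genes:
            seen.setdefault(g, None)
    return SweepReport(regions=list(regions), distinct_genes=list(seen), geneless=geneless)


def regions_frame(regions) -> pd.DataFrame:
    """Candidate regions as a table (gene column '-' when empty)."""
    rows = [
        (r.key.chrom, r.key.start, r.key.end, r.fst, r.hp, r.zhp, r.xpclr,
         ", ".join(r.genes) if r.genes else "-")
        for r in regions
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "fst", "hp", "zhp", "xpclr", "genes"])


def write_candidates(regions, path) -> None:
    regions_frame(regions).to_csv(path, sep="\t", index=False)


def merge_adjacent(regions) -> list:
    """Optionally merge runs of adjacent candidate windows into single
    spans (off by default in the pipeline; rows stay per-window there)."""
    merged = []
    for r in sorted(regions, key=lambda r: r.key):
        if merged and merged[-1].key.chrom == r.key.chrom \
                and merged[-1].key.end == r.key.start:
            prev = merged[-1]
            prev.key = WindowKey(prev.key.chrom, prev.key.start, r.key.end)
            prev.genes = list(dict.fromkeys(prev.genes + r.genes))
        else:
            merged.append(CandidateRegion(
                key=r.key, fst=r.fst, hp=r.hp, zhp=r.zhp, xpclr=r.xpclr,
                genes=list(r.genes)))
    return merged
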