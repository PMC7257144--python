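"""Derive the per-gene genomic region sets: gene body, promoter, exon, intron, TE.

The promoter is the fixed-width window immediately upstream of the oriented
gene start (default 2 kb), clipped at position 1; a gene starting at the
chromosome edge may have a zero-length promoter, which is recorded as an
empty interval list rather than treated as an error. Introns are the exact
complement of the exon union inside the gene body, so exon and intron bases
always tile the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ._utils import Interval, complement_intervals
from .errors import DataError
from .io import GeneModel

REGION_TYPES = ("genebody", "promoter", "exon", "intron", "te")


@dataclass
class RegionSet:
    """Mapping (gene_id, region_type) -> list of 1-based inclusive intervals."""

    intervals: dict[tuple[str, str], list[Interval]]
    chrom: dict[str, str]
    strand: dict[str, str]
    promoter_bp: int = 2000

    def genes(self) -> list[str]:
        return list(self.chrom)

    def chromosomes(self) -> set[str]:
        return set(self.chrom.values())

    def get(self, gene_id: str, region_type: str) -> list[Interval]:
        return self.intervals.get((gene_id, region_type), [])

    def region_types(self) -> list[str]:
        present = {rt for (_, rt) in self.intervals}
        return [rt for rt in REGION_TYPES if rt in present]

    def items(self, region_type: str):
        """Yield (gene_id, intervals) for one region type."""
        for (gid, rt), ivals in self.intervals.items():
            if rt == region_type:
                yield gid, ivals


def derive_regions(genes: Iterable[GeneModel], promoter_bp: int = 2000) -> RegionSet:
    """Build the :class:`RegionSet` for a gene collection.

    For ``+`` strand genes the promoter is ``[start - promoter_bp, start - 1]``;
    for ``-`` strand genes it is ``[end + 1, end + promoter_bp]`` (the oriented
    upstream side). TE models additionally get a ``te`` region equal to their
    body.
    """
    if promoter_bp < 1:
        raise DataError("promoter_bp must be >= 1")
    intervals: dict[tuple[str, str], list[Interval]] = {}
    chrom: dict[str, str] = {}
    strand: dict[str, str] = {}
    for g in genes:
        chrom[g.gene_id] = g.chrom
        strand[g.gene_id] = g.strand
        body = [(g.start, g.end)]
        exons = list(g.exons)
        introns = complement_intervals((g.start, g.end), exons)
        if g.strand == "+":
            lo, hi = g.start - promoter_bp, g.start - 1
            lo = max(lo, 1)
            promoter = [(lo, hi)] if hi >= lo else []
        else:
            promoter = [(g.end + 1, g.end + promoter_bp)]
        intervals[(g.gene_id, "genebody")] = body
        intervals[(g.gene_id, "promoter")] = promoter
        intervals[(g.gene_id, "exon")] = exons
        intervals[(g.gene_id, "intron")] = introns
        if g.is_te:
            intervals[(g.gene_id, "te")] = body
    return RegionSet(intervals=intervals, chrom=chrom, strand=strand, promoter_bp=promoter_bp)


def export_bed(regions: RegionSet, region_type: str, path: str | Path) -> int:
    """Write one region type as BED6 (0-based half-open), sorted by position.

    Zero-length regions are omitted. Returns the number of lines written.
    """
    if region_type not in REGION_TYPES:
        raise DataError(f"unknown region type {region_type!r}")
    rows = []
    for gid, ivals in regions.items(region_type):
        for start, end in ivals:
            rows.append((regions.chrom[gid], start - 1, end, gid, regions.strand[gid]))
    rows.sort()
    with open(path, "wt") as out:
        for chrom, start0, end0, gid, strand in rows:
            out.write(f"{chrom}\t{start0}\t{end0}\t{gid}\t.\t{strand}\n")
    return len(rows)
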