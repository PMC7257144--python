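"""Readers and converters for methylation calls, expression tables and GTF annotation.

The native methylation-call format is CGmap: one cytosine per line with eight
tab-separated columns ``chrom, nucleotide (C/G), position, context, dinucleotide
context, level, methylated reads, total reads``. Converters are provided for
Bismark CX reports, BSMAP ``methratio.py`` output, methylpy allc files and
METHimpute TSV exports.

Coordinates are 1-based inclusive throughout the package; BED export converts
at the boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import pandas as pd

from ._utils import merge_intervals, open_text
from .errors import DataError, FormatError

log = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

#: nucleotide column -> strand of the cytosine on the reference
_NUC_STRAND = {"C": "+", "G": "-"}
_STRAND_NUC = {"+": "C", "-": "G"}


class CytosineRecord(NamedTuple):
    """A single cytosine methylation call.

    ``level`` is recomputed from the read counts (the level column of CGmap
    files is rounded and is only used for validation).
    """

    chrom: str
    pos: int  # 1-based
    strand: str  # "+" or "-"
    context: str  # CG / CHG / CHH
    dinucleotide_context: str
    level: float
    meth_reads: int
    total_reads: int


# ---------------------------------------------------------------------------
# CGmap reading
# ---------------------------------------------------------------------------


class CGmapReader:
    """Stream :class:`CytosineRecord` from a CGmap file (optionally gzipped).

    Lines with an unknown context (``--``) or zero total reads are skipped and
    counted; malformed lines are skipped and counted separately. After
    iteration the reader raises :class:`FormatError` if no valid record was
    seen or if more than ``max_malformed_frac`` of data lines were malformed.

    Counters (``n_records``, ``n_malformed``, ``n_unknown_context``,
    ``n_uncovered``) are available once iteration finishes.
    """

    def __init__(self, path: str | Path, max_malformed_frac: float = 0.01):
        self.path = Path(path)
        if not self.path.exists():
            raise FormatError(f"no such file: {self.path}")
        self.max_malformed_frac = max_malformed_frac
        self.n_records = 0
        self.n_malformed = 0
        self.n_unknown_context = 0
        self.n_uncovered = 0
        self.n_lines = 0

    def __iter__(self) -> Iterator[CytosineRecord]:
        with open_text(self.path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                self.n_lines += 1
                rec = self._parse_line(line)
                if rec is not None:
                    self.n_records += 1
                    yield rec
        if self.n_records == 0:
            raise FormatError(f"{self.path}: zero valid records")
        if self.n_malformed > self.max_malformed_frac * self.n_lines:
            raise FormatError(
                f"{self.path}: {self.n_malformed}/{self.n_lines} malformed lines "
                f"(> {self.max_malformed_frac:.0%})"
            )
        if self.n_unknown_context:
            log.warning(
                "%s: skipped %d records with unknown context",
                self.path,
                self.n_unknown_context,
            )

    def _parse_line(self, line: str) -> CytosineRecord | None:
        parts = line.split("\t")
        if len(parts) != 8:
            self.n_malformed += 1
            return None
        chrom, nuc, pos_s, context, dinuc, level_s, meth_s, total_s = parts
        if context not in CONTEXTS:
            self.n_unknown_context += 1
            return None
        strand = _NUC_STRAND.get(nuc)
        try:
            pos = int(pos_s)
            meth = int(meth_s)
            total = int(total_s)
            level = float(level_s)
        except ValueError:
            self.n_malformed += 1
            return None
        if strand is None or pos < 1 or meth < 0:
            self.n_malformed += 1
            return None
        if total == 0:
            self.n_uncovered += 1
            return None
        if meth > total:
            self.n_malformed += 1
            return None
        exact = meth / total
        if abs(level - exact) > 0.01 + 1e-9:
            self.n_malformed += 1
            return None
        return CytosineRecord(chrom, pos, strand, context, dinuc, exact, meth, total)


def read_cgmap(path: str | Path, max_malformed_frac: float = 0.01) -> CGmapReader:
    """Return a streaming reader over the CGmap file at ``path``."""
    return CGmapReader(path, max_malformed_frac=max_malformed_frac)


# ---------------------------------------------------------------------------
# Foreign-dialect conversion
# ---------------------------------------------------------------------------


def classify_context(seq: str) -> str | None:
    """Collapse a (tri)nucleotide context string to CG / CHG / CHH.

    ``CG*`` -> CG, ``C[ACT]G`` -> CHG, ``C[ACT][ACT]`` -> CHH. Bismark's
    ``CpG`` spelling and already-collapsed classes pass through. Returns
    ``None`` when the string matches no class.
    """
    seq = seq.upper()
    if seq in ("CG", "CPG"):
        return "CG"
    if seq in ("CHG", "CHH"):
        return seq
    if len(seq) >= 2 and seq[0] == "C":
        if seq[1] == "G":
            return "CG"
        if len(seq) >= 3 and seq[1] in "ACT":
            if seq[2] == "G":
                return "CHG"
            if seq[2] in "ACT":
                return "CHH"
    return None


@dataclass
class ConversionStats:
    n_out: int = 0
    n_skipped: int = 0


def _iter_bismark_cx(fh) -> Iterator[tuple]:
    # chrom, pos, strand, count_methylated, count_unmethylated, context, trinucleotide
    for line in fh:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 7:
            yield None
            continue
        chrom, pos, strand, cm, cu, context, tri = parts[:7]
        try:
            meth, unmeth = int(cm), int(cu)
        except ValueError:
            yield None
            continue
        ctx = classify_context(context) or classify_context(tri)
        if ctx is None or strand not in _STRAND_NUC or meth + unmeth == 0:
            yield None
            continue
        yield chrom, int(pos), strand, ctx, tri[:2].upper(), meth, meth + unmeth


def _iter_bsmap_methratio(fh) -> Iterator[tuple]:
    # header line; chr, pos, strand, context, ratio, eff_CT, C_count, CT_count, ...
    for i, line in enumerate(fh):
        parts = line.rstrip("\n").split("\t")
        if i == 0 and (parts[0].lower() in ("chr", "chrom", "chromosome")):
            continue
        if len(parts) < 8:
            yield None
            continue
        chrom, pos, strand, context = parts[:4]
        try:
            meth = int(round(float(parts[6])))
            total = int(round(float(parts[7])))
        except ValueError:
            yield None
            continue
        # methratio reports a 5-mer centred on the cytosine
        if len(context) == 5 and context[2].upper() == "C":
            ctx = classify_context(context[2:])
        else:
            ctx = classify_context(context)
        if ctx is None or strand not in _STRAND_NUC or total == 0 or meth > total:
            yield None
            continue
        dinuc = context[2:4].upper() if len(context) == 5 else context[:2].upper()
        yield chrom, int(pos), strand, ctx, dinuc, meth, total


def _iter_methylpy_allc(fh) -> Iterator[tuple]:
    # chrom, pos, strand, trinucleotide context, mc, cov, methylated_flag
    for line in fh:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            yield None
            continue
        chrom, pos, strand, tri = parts[:4]
        try:
            meth, total = int(parts[4]), int(parts[5])
        except ValueError:
            yield None
            continue
        ctx = classify_context(tri)
        if ctx is None or strand not in _STRAND_NUC or total == 0 or meth > total:
            yield None
            continue
        yield chrom, int(pos), strand, ctx, tri[:2].upper(), meth, total


def _iter_methimpute_tsv(fh) -> Iterator[tuple]:
    # chrom, pos, strand, context, counts.methylated, counts.total (header allowed)
    for i, line in enumerate(fh):
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            yield None
            continue
        if i == 0:
            try:
                int(parts[1])
            except ValueError:
                continue  # header
        chrom, pos, strand, context = parts[:4]
        try:
            meth, total = int(parts[4]), int(parts[5])
        except ValueError:
            yield None
            continue
        ctx = classify_context(context)
        if ctx is None or strand not in _STRAND_NUC or total == 0 or meth > total:
            yield None
            continue
        yield chrom, int(pos), strand, ctx, context[:2].upper(), meth, total


DIALECTS = {
    "bismark_cx": _iter_bismark_cx,
    "bsmap": _iter_bsmap_methratio,
    "bsmap_methratio": _iter_bsmap_methratio,
    "allc": _iter_methylpy_allc,
    "methylpy_allc": _iter_methylpy_allc,
    "methimpute": _iter_methimpute_tsv,
    "methimpute_tsv": _iter_methimpute_tsv,
}


def convert_to_cgmap(path: str | Path, dialect: str, out_path: str | Path) -> ConversionStats:
    """Convert a foreign methylation-call file to CGmap format.

    Lines whose context matches no class, or with zero coverage, are skipped
    and counted. Raises :class:`FormatError` on an unknown dialect or when no
    valid record is produced.
    """
    if dialect not in DIALECTS:
        raise FormatError(
            f"unknown dialect {dialect!r}; expected one of {sorted(set(DIALECTS))}"
        )
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    stats = ConversionStats()
    with open_text(path) as fh, open(out_path, "wt") as out:
        for item in DIALECTS[dialect](fh):
            if item is None:
                stats.n_skipped += 1
                continue
            chrom, pos, strand, ctx, dinuc, meth, total = item
            out.write(
                f"{chrom}\t{_STRAND_NUC[strand]}\t{pos}\t{ctx}\t{dinuc}\t"
                f"{meth / total:.6f}\t{meth}\t{total}\n"
            )
            stats.n_out += 1
    if stats.n_out == 0:
        raise FormatError(f"{path}: zero valid records after conversion")
    if stats.n_skipped:
        log.warning("%s: skipped %d unconvertible lines", path, stats.n_skipped)
    return stats


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Gene name -> non-negative expression value (unit-agnostic)."""

    data: pd.Series
    n_dropped_nan: int = 0

    def __post_init__(self):
        self.data = self.data.astype(float)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene names: {dupes[:10]}")
        neg = self.data[self.data < 0]
        if len(neg):
            raise DataError(f"negative expression for gene {neg.index[0]!r}")

    @classmethod
    def from_mapping(cls, mapping) -> "ExpressionTable":
        return cls(pd.Series(mapping, dtype=float, name="expression"))

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, gene: str) -> float:
        return float(self.data[gene])

    def __contains__(self, gene: str) -> bool:
        return gene in self.data.index

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def to_series(self) -> pd.Series:
        return self.data.copy()


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a two-column tab-delimited expression file.

    A header row is auto-detected: if column 2 of the first row is not
    numeric, the row is treated as a header and skipped. Rows with a NaN
    value are dropped (counted); duplicates or negative values are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected >=2 tab-separated columns")
    first_val = df.iloc[0, 1]
    try:
        float(first_val)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    values = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    nan_mask = values.isna()
    n_nan = int(nan_mask.sum())
    if n_nan:
        log.warning("%s: dropped %d rows with non-numeric values", path, n_nan)
    series = pd.Series(
        values[~nan_mask].to_numpy(float),
        index=df.iloc[:, 0][~nan_mask].to_numpy(str),
        name="expression",
    )
    return ExpressionTable(series, n_dropped_nan=n_nan)


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware single-annotation gene model (union of all transcripts).

    ``start``/``end`` are genomic (start <= end); the TSS/TES properties
    orient them by strand. ``exons`` are merged, non-overlapping, 1-based
    inclusive intervals covering the exon union.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    is_te: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise DataError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise DataError(f"{self.gene_id}: no exons")
        if self.exons[0][0] < self.start or self.exons[-1][1] > self.end:
            raise DataError(f"{self.gene_id}: exons outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def body_length(self) -> int:
        return self.end - self.start + 1


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf(path: str | Path, feature_kind: str = "gene") -> list[GeneModel]:
    """Parse a GTF file into one :class:`GeneModel` per gene.

    Exon features are grouped by ``gene_id`` (falling back to ``gene_name``);
    each gene's body spans min..max over its exons and its exon set is the
    merged union over all transcripts. ``feature_kind="te"`` marks the models
    as transposable elements. Genes with exons on multiple chromosomes or
    strands are dropped with a warning.
    """
    if feature_kind not in ("gene", "te"):
        raise DataError(f"feature_kind must be 'gene' or 'te', got {feature_kind!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, set[tuple[str, str]]] = {}
    n_exon_lines = 0
    with open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "exon":
                continue
            n_exon_lines += 1
            chrom, _, _, start_s, end_s, _, strand, _, attrs_s = parts[:9]
            attrs = dict(_ATTR_RE.findall(attrs_s))
            gid = attrs.get("gene_id") or attrs.get("gene_name")
            if gid is None:
                continue
            exons.setdefault(gid, []).append((int(start_s), int(end_s)))
            meta.setdefault(gid, set()).add((chrom, strand))
    if n_exon_lines == 0:
        raise FormatError(f"{path}: no exon features found")
    genes: list[GeneModel] = []
    n_dropped = 0
    for gid, ivals in exons.items():
        placements = meta[gid]
        if len(placements) != 1:
            log.warning("gene %s spans multiple chromosomes/strands; dropped", gid)
            n_dropped += 1
            continue
        (chrom, strand), = placements
        merged = tuple(merge_intervals(ivals))
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                start=merged[0][0],
                end=merged[-1][1],
                exons=merged,
                is_te=(feature_kind == "te"),
            )
        )
    if n_dropped:
        log.warning("%s: dropped %d inconsistent genes", path, n_dropped)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes
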