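"""Per-gene, per-context, per-region methylation averaging.

The central product is the :class:`RegionMethylationTable`: for every
(gene, context, region type) cell it holds the mean methylation level over the
region's cytosines of that context, after a per-site coverage filter. Two
estimators are supported:

``weighted``
    sum(meth_reads) / sum(total_reads) over in-region sites — the
    read-count-weighted methylation level (default; robust to shallow sites).
``site_mean``
    unweighted mean of per-site levels.

Strand is ignored for region membership: records on both strands inside an
interval contribute. A cytosine inside k overlapping regions contributes to
each of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError
from .io import CONTEXTS, CytosineRecord
from .regions import RegionSet

log = logging.getLogger(__name__)

CTX_CODE = {ctx: i for i, ctx in enumerate(CONTEXTS)}
ESTIMATORS = ("weighted", "site_mean")


class SiteTable:
    """Position-sorted per-chromosome arrays of cytosine calls.

    Columns per chromosome: ``pos`` (int64, 1-based, sorted), ``ctx`` (int8
    code into CONTEXTS), ``meth``, ``total`` (int64), ``level`` (float64).
    """

    def __init__(self, data: dict[str, dict[str, np.ndarray]]):
        self._data = data

    @classmethod
    def from_records(cls, records: Iterable[CytosineRecord]) -> "SiteTable":
        accum: dict[str, list[list]] = {}
        for rec in records:
            cols = accum.setdefault(rec.chrom, [[], [], [], []])
            cols[0].append(rec.pos)
            cols[1].append(CTX_CODE[rec.context])
            cols[2].append(rec.meth_reads)
            cols[3].append(rec.total_reads)
        data = {}
        for chrom, (pos, ctx, meth, total) in accum.items():
            pos = np.asarray(pos, dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            meth_a = np.asarray(meth, dtype=np.int64)[order]
            total_a = np.asarray(total, dtype=np.int64)[order]
            data[chrom] = {
                "pos": pos[order],
                "ctx": np.asarray(ctx, dtype=np.int8)[order],
                "meth": meth_a,
                "total": total_a,
                "level": meth_a / total_a,
            }
        return cls(data)

    def chromosomes(self) -> set[str]:
        return set(self._data)

    def sites(self, chrom: str) -> dict[str, np.ndarray] | None:
        return self._data.get(chrom)

    @property
    def n_sites(self) -> int:
        return sum(len(cols["pos"]) for cols in self._data.values())


def as_site_table(records) -> SiteTable:
    return records if isinstance(records, SiteTable) else SiteTable.from_records(records)


@dataclass
class RegionMethylationTable:
    """gene x context x region-type -> mean methylation level.

    ``data`` is indexed by (gene, context, region) with columns ``level``
    (NaN when fewer than ``min_sites`` sites survive the coverage filter),
    ``n_sites`` and ``coverage`` (summed total reads).
    """

    data: pd.DataFrame
    min_coverage: int = 4
    min_sites: int = 1
    estimator: str = "weighted"

    def get(self, gene: str, context: str, region_type: str) -> float | None:
        try:
            val = self.data.loc[(gene, context, region_type), "level"]
        except KeyError:
            return None
        return None if pd.isna(val) else float(val)

    def n_sites(self, gene: str, context: str, region_type: str) -> int:
        try:
            return int(self.data.loc[(gene, context, region_type), "n_sites"])
        except KeyError:
            return 0

    def level_series(self, context: str, region_type: str) -> pd.Series:
        """Gene -> level for one context/region, missing cells dropped."""
        idx = self.data.index
        mask = (idx.get_level_values(1) == context) & (idx.get_level_values(2) == region_type)
        sub = self.data.loc[mask, "level"].dropna()
        sub.index = sub.index.get_level_values(0)
        return sub.rename("level")

    def genes(self) -> list[str]:
        return list(self.data.index.get_level_values(0).unique())

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.reset_index()
        out.columns = ["gene", "context", "region", "level", "n_sites", "coverage"]
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "RegionMethylationTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        df = df.set_index(["gene", "context", "region"])
        return cls(df, **kwargs)


def average_region_methylation(
    records,
    regions: RegionSet,
    min_coverage: int = 4,
    estimator: str = "weighted",
    min_sites: int = 1,
) -> RegionMethylationTable:
    """Aggregate cytosine records into a :class:`RegionMethylationTable`.

    ``records`` may be an iterable of :class:`CytosineRecord` or a prebuilt
    :class:`SiteTable`. Sites with ``total_reads < min_coverage`` are
    excluded. Fails if record and region chromosome namespaces do not overlap,
    or if fewer than half of the genes lie on chromosomes present in the
    records (likely a naming mismatch such as "1" vs "Chr1").
    """
    if estimator not in ESTIMATORS:
        raise DataError(f"estimator must be one of {ESTIMATORS}, got {estimator!r}")
    if min_coverage < 1:
        raise DataError("min_coverage must be >= 1")
    sites = as_site_table(records)
    rec_chroms = sites.chromosomes()
    reg_chroms = regions.chromosomes()
    shared = rec_chroms & reg_chroms
    if not shared:
        raise DataError(
            "no chromosome overlap between methylation records and regions; "
            f"records have {sorted(rec_chroms)[:5]}, regions have {sorted(reg_chroms)[:5]}"
        )
    genes = regions.genes()
    n_covered = sum(1 for g in genes if regions.chrom[g] in rec_chroms)
    if n_covered < 0.5 * len(genes):
        raise DataError(
            f"only {n_covered}/{len(genes)} genes are on chromosomes present in the "
            "methylation records; check chromosome naming"
        )

    # Per chromosome: coverage-filtered, per-context views for fast interval sums.
    filtered: dict[str, dict[int, dict[str, np.ndarray]]] = {}
    for chrom in shared:
        cols = sites.sites(chrom)
        keep = cols["total"] >= min_coverage
        per_ctx = {}
        for code in range(len(CONTEXTS)):
            mask = keep & (cols["ctx"] == code)
            per_ctx[code] = {
                "pos": cols["pos"][mask],
                "meth": cols["meth"][mask],
                "total": cols["total"][mask],
                "level": cols["level"][mask],
            }
        filtered[chrom] = per_ctx

    index = []
    rows = []
    for gid in genes:
        chrom = regions.chrom[gid]
        per_ctx = filtered.get(chrom)
        for rtype in regions.region_types():
            key = (gid, rtype)
            if key not in regions.intervals:
                continue
            ivals = regions.intervals[key]
            for code, ctx in enumerate(CONTEXTS):
                n = 0
                meth_sum = 0
                total_sum = 0
                level_sum = 0.0
                if per_ctx is not None:
                    cols = per_ctx[code]
                    pos = cols["pos"]
                    for start, end in ivals:
                        i = np.searchsorted(pos, start, side="left")
                        j = np.searchsorted(pos, end, side="right")
                        if j > i:
                            n += j - i
                            meth_sum += int(cols["meth"][i:j].sum())
                            total_sum += int(cols["total"][i:j].sum())
                            level_sum += float(cols["level"][i:j].sum())
                if n >= min_sites:
                    level = meth_sum / total_sum if estimator == "weighted" else level_sum / n
                else:
                    level = np.nan
                index.append((gid, ctx, rtype))
                rows.append((level, n, total_sum))
    df = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["gene", "context", "region"]),
        columns=["level", "n_sites", "coverage"],
    )
    return RegionMethylationTable(
        df, min_coverage=min_coverage, min_sites=min_sites, estimator=estimator
    )


def write_context_bigwig(
    records,
    out_prefix: str | Path,
    contexts: tuple[str, ...] = CONTEXTS,
    chrom_sizes: dict[str, int] | None = None,
) -> dict[str, Path]:
    """Write one bigwig track per context with the per-site methylation level.

    Optional cache for genome browsers; analyses never read these back.
    Requires the optional ``pyBigWig`` dependency. Chromosome sizes default to
    the maximum observed position per chromosome. Duplicate positions (e.g.
    both strands reported at one coordinate) are averaged, since bigwig
    intervals may not overlap.
    """
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - depends on optional extra
        raise DataError(
            "pyBigWig is required for bigwig export; install methget[bigwig]"
        ) from exc
    sites = as_site_table(records)
    chroms = sorted(sites.chromosomes())
    if chrom_sizes is None:
        chrom_sizes = {c: int(sites.sites(c)["pos"].max()) for c in chroms}
    header = [(c, int(chrom_sizes[c])) for c in chroms]
    paths = {}
    for ctx in contexts:
        code = CTX_CODE[ctx]
        path = Path(f"{out_prefix}.{ctx}.bw")
        bw = pyBigWig.open(str(path), "w")
        bw.addHeader(header)
        for chrom in chroms:
            cols = sites.sites(chrom)
            mask = cols["ctx"] == code
            pos = cols["pos"][mask]
            if len(pos) == 0:
                continue
            level = cols["level"][mask]
            uniq, inverse, counts = np.unique(pos, return_inverse=True, return_counts=True)
            summed = np.zeros(len(uniq))
            np.add.at(summed, inverse, level)
            values = summed / counts
            bw.addEntries(
                [chrom] * len(uniq),
                (uniq - 1).tolist(),
                ends=uniq.tolist(),
                values=values.tolist(),
            )
        bw.close()
        paths[ctx] = path
    return paths
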