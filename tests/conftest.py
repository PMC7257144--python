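"""Shared fixtures and independent oracles.

The oracles here (naive per-base region scan, brute-force interval union)
deliberately use plain Python loops so they share no code path with the
package implementations they check.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from methget import CytosineRecord, RegionMethylationTable
from methget.io import GeneModel
from methget.regions import RegionSet, derive_regions


def make_record(chrom="Chr1", pos=1, strand="+", context="CG", meth=1, total=2):
    return CytosineRecord(chrom, pos, strand, context, context[:2],
                          meth / total, meth, total)


def write_cgmap(records, path: Path) -> Path:
    with open(path, "wt") as fh:
        for r in records:
            nuc = "C" if r.strand == "+" else "G"
            fh.write(f"{r.chrom}\t{nuc}\t{r.pos}\t{r.context}\t"
                     f"{r.dinucleotide_context}\t{r.meth_reads / r.total_reads:.2f}\t"
                     f"{r.meth_reads}\t{r.total_reads}\n")
    return path


def make_meth_table(levels: dict[str, float], context="CG", region="genebody",
                    **kwargs) -> RegionMethylationTable:
    """Region methylation table with one cell per gene (for analysis tests)."""
    idx = pd.MultiIndex.from_tuples(
        [(g, context, region) for g in levels],
        names=["gene", "context", "region"],
    )
    df = pd.DataFrame({"level": list(levels.values()), "n_sites": 1, "coverage": 4},
                      index=idx)
    return RegionMethylationTable(df, **kwargs)


def naive_region_table(records, regions: RegionSet, min_coverage: int,
                       estimator: str) -> dict:
    """Per-base oracle: (gene, context, region) -> (level or None, n_sites)."""
    out = {}
    for (gid, rtype), ivals in regions.intervals.items():
        chrom = regions.chrom[gid]
        for ctx in ("CG", "CHG", "CHH"):
            sel = [r for r in records
                   if r.chrom == chrom and r.context == ctx
                   and r.total_reads >= min_coverage
                   and any(s <= r.pos <= e for s, e in ivals)]
            if not sel:
                out[(gid, ctx, rtype)] = (None, 0)
            elif estimator == "weighted":
                level = (sum(r.meth_reads for r in sel)
                         / sum(r.total_reads for r in sel))
                out[(gid, ctx, rtype)] = (level, len(sel))
            else:
                level = math.fsum(r.meth_reads / r.total_reads for r in sel) / len(sel)
                out[(gid, ctx, rtype)] = (level, len(sel))
    return out


def random_fixture(rng: np.random.Generator, max_genes=10, chrom_len=5000):
    """Random tiny genome: gene models + cytosine records on 1-2 chromosomes."""
    n_chroms = int(rng.integers(1, 3))
    chroms = [f"Chr{i + 1}" for i in range(n_chroms)]
    genes = []
    n_genes = int(rng.integers(1, max_genes + 1))
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(0, n_chroms))]
        length = int(rng.integers(40, 600))
        start = int(rng.integers(1, chrom_len - length))
        end = start + length - 1
        n_ex = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, length), size=min(2 * n_ex - 2, length - 1),
                                 replace=False).tolist())
        bounds = [0] + cuts + [length]
        segs = [(start + bounds[j], start + bounds[j + 1] - 1)
                for j in range(len(bounds) - 1)]
        exons = tuple(segs[::2])
        genes.append(GeneModel(gene_id=f"t{i:03d}", chrom=chrom,
                               strand="+" if rng.random() < 0.5 else "-",
                               start=exons[0][0], end=exons[-1][1], exons=exons))
    records = []
    n_sites = int(rng.integers(50, 400))
    for _ in range(n_sites):
        chrom = chroms[int(rng.integers(0, n_chroms))]
        pos = int(rng.integers(1, chrom_len + 1))
        total = int(rng.integers(1, 20))
        meth = int(rng.integers(0, total + 1))
        ctx = ("CG", "CHG", "CHH")[int(rng.integers(0, 3))]
        records.append(make_record(chrom, pos, "+" if rng.random() < 0.5 else "-",
                                   ctx, meth, total))
    return genes, records


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def meth_table_factory():
    return make_meth_table


@pytest.fixture
def toy_genes():
    """Two genes on opposite strands with introns."""
    return [
        GeneModel("gA", "Chr1", "+", 5000, 8000,
                  exons=((5000, 6000), (7000, 8000))),
        GeneModel("gB", "Chr1", "-", 12000, 15000, exons=((12000, 15000),)),
    ]


@pytest.fixture
def toy_regions(toy_genes):
    return derive_regions(toy_genes, promoter_bp=2000)
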