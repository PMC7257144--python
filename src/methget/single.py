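"""Within-sample analyses: correlation, ordinal association, expression-quantile
grouping statistics and metagene profiles.

All four consume a :class:`~methget.methylation.RegionMethylationTable` (or the
raw cytosine stream for metagene profiles, which need sub-gene resolution)
together with an :class:`~methget.io.ExpressionTable`. Genes missing either
quantity are excluded and counted, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import CONTEXTS, ExpressionTable
from .methylation import CTX_CODE, RegionMethylationTable, as_site_table

log = logging.getLogger(__name__)


def _paired(meth: RegionMethylationTable, expr: ExpressionTable, context: str,
            region_type: str) -> tuple[pd.DataFrame, int]:
    """Align methylation and expression on shared genes.

    Returns (pairs, n_excluded) where pairs has columns level/expression.
    """
    levels = meth.level_series(context, region_type)
    e = expr.to_series()
    shared = levels.index.intersection(e.index)
    pairs = pd.DataFrame({"level": levels.loc[shared], "expression": e.loc[shared]})
    n_excluded = (len(levels) - len(shared)) + (len(e) - len(shared))
    return pairs.sort_index(), n_excluded


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    """Pearson/Spearman correlation of methylation level vs expression.

    p-values are two-sided, from the t statistic on the coefficient. When a
    variable has zero variance the coefficients are ``None`` and ``message``
    explains why. ``pairs`` holds the analyzed (level, expression) table for
    plotting.
    """

    pearson_r: float | None
    pearson_p: float | None
    spearman_rho: float | None
    spearman_p: float | None
    n_genes: int
    n_excluded: int
    pairs: pd.DataFrame = field(repr=False)
    message: str | None = None


def correlate(meth: RegionMethylationTable, expr: ExpressionTable, context: str,
              region_type: str) -> CorrelationResult:
    pairs, n_excluded = _paired(meth, expr, context, region_type)
    n = len(pairs)
    if n < 3:
        raise DataError(f"need >=3 genes with both values, got {n}")
    x = pairs["level"].to_numpy()
    y = pairs["expression"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        which = "methylation" if np.std(x) == 0 else "expression"
        return CorrelationResult(None, None, None, None, n, n_excluded, pairs,
                                 message=f"zero variance in {which}")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        n_genes=n,
        n_excluded=n_excluded,
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# Ordinal association
# ---------------------------------------------------------------------------


@dataclass
class OrdinalAssociation:
    """Methylation against expression rank with a moving-average trend curve.

    ``table`` is sorted by ascending expression (ties broken by gene name);
    ``boundary_index`` is the count of unexpressed genes (expression exactly
    zero), i.e. the first rank belonging to an expressed gene.
    """

    table: pd.DataFrame
    curve: np.ndarray
    boundary_index: int
    ma_window: int


def ordinal_association(meth: RegionMethylationTable, expr: ExpressionTable,
                        context: str, region_type: str,
                        ma_window: int = 200) -> OrdinalAssociation:
    pairs, _ = _paired(meth, expr, context, region_type)
    if pairs.empty:
        raise DataError("no genes with both methylation and expression")
    if ma_window < 1:
        raise DataError("ma_window must be >= 1")
    ma_window = min(ma_window, len(pairs))
    tab = pairs.reset_index(names="gene").sort_values(
        ["expression", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    tab["rank"] = np.arange(len(tab))
    boundary = int((tab["expression"] == 0).sum())
    curve = (
        tab["level"].rolling(ma_window, center=True, min_periods=1).mean().to_numpy()
    )
    return OrdinalAssociation(table=tab, curve=curve, boundary_index=boundary,
                              ma_window=ma_window)


# ---------------------------------------------------------------------------
# Expression grouping
# ---------------------------------------------------------------------------


def assign_expression_groups(expr: pd.Series, n_groups: int = 5,
                             include_unexpressed: bool = True) -> pd.Series:
    """Group genes by expression: group 0 = unexpressed (exactly zero),
    groups 1..n = rank-based quantile bins of expressed genes, low to high.

    Bin sizes differ by at most one; ties are broken by gene name for
    determinism. Genes with zero expression are dropped when
    ``include_unexpressed`` is false.
    """
    if n_groups < 2:
        raise DataError("n_groups must be >= 2")
    expr = expr.astype(float)
    expressed = expr[expr > 0]
    if len(expressed) < n_groups:
        raise DataError(
            f"only {len(expressed)} expressed genes for {n_groups} bins; "
            "use fewer bins"
        )
    order = expressed.reset_index()
    order.columns = ["gene", "expression"]
    order = order.sort_values(["expression", "gene"], kind="mergesort")
    labels = {}
    for i, chunk in enumerate(np.array_split(order["gene"].to_numpy(), n_groups)):
        for g in chunk:
            labels[g] = i + 1
    if include_unexpressed:
        for g in expr.index[expr == 0]:
            labels[g] = 0
    out = pd.Series(labels, name="group", dtype=int)
    return out.loc[[g for g in expr.index if g in labels]]


@dataclass
class GroupStats:
    """Per-group descriptive statistics of methylation levels.

    ``table`` columns: group, n, mean, sd, median, q1, q3, pearson_r,
    pearson_p (within-group methylation vs expression). ``membership`` maps
    each analyzed gene to its group.
    """

    table: pd.DataFrame
    membership: pd.Series
    values: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    n_zero_excluded: int = 0


def grouping_statistics(meth: RegionMethylationTable, expr: ExpressionTable,
                        context: str, region_type: str, n_quantiles: int = 5,
                        include_unexpressed: bool = True) -> GroupStats:
    pairs, _ = _paired(meth, expr, context, region_type)
    if pairs.empty:
        raise DataError("no genes with both methylation and expression")
    groups = assign_expression_groups(
        pairs["expression"], n_quantiles, include_unexpressed=include_unexpressed
    )
    n_zero_excluded = 0 if include_unexpressed else int((pairs["expression"] == 0).sum())
    rows = []
    values = {}
    for grp in sorted(groups.unique()):
        members = groups.index[groups == grp]
        lv = pairs.loc[members, "level"].to_numpy()
        ex = pairs.loc[members, "expression"].to_numpy()
        values[int(grp)] = lv
        if len(lv) >= 3 and np.std(lv) > 0 and np.std(ex) > 0:
            pr = stats.pearsonr(lv, ex)
            r, p = float(pr.statistic), float(pr.pvalue)
        else:
            r, p = np.nan, np.nan
        rows.append({
            "group": int(grp),
            "n": len(lv),
            "mean": float(np.mean(lv)),
            "sd": float(np.std(lv, ddof=1)) if len(lv) > 1 else np.nan,
            "median": float(np.median(lv)),
            "q1": float(np.percentile(lv, 25)),
            "q3": float(np.percentile(lv, 75)),
            "pearson_r": r,
            "pearson_p": p,
        })
    return GroupStats(table=pd.DataFrame(rows), membership=groups, values=values,
                      n_zero_excluded=n_zero_excluded)


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------


@dataclass
class MetageneProfile:
    """Expression-group x window matrix of mean methylation levels.

    Window 1 is always the 5' end regardless of strand. ``matrix`` rows are
    group labels (0 = unexpressed when present), columns window labels;
    ``n_genes`` counts profiled genes per group.
    """

    matrix: pd.DataFrame
    n_genes: pd.Series
    mode: str
    window_labels: list[str]
    n_excluded_short: int = 0


def _per_gene_window_levels(cols, edges: np.ndarray, code: int,
                            min_coverage: int, estimator: str) -> np.ndarray:
    """Window levels for one gene given chromosome site arrays and window
    edges (half-open, ascending floats). NaN where a window has no site."""
    n_windows = len(edges) - 1
    out = np.full(n_windows, np.nan)
    if cols is None:
        return out
    pos = cols["pos"]
    i = np.searchsorted(pos, edges[0], side="left")
    j = np.searchsorted(pos, edges[-1], side="left")
    if j <= i:
        return out
    pos = pos[i:j]
    mask = (cols["ctx"][i:j] == code) & (cols["total"][i:j] >= min_coverage)
    if not mask.any():
        return out
    pos = pos[mask]
    meth = cols["meth"][i:j][mask].astype(float)
    total = cols["total"][i:j][mask].astype(float)
    level = cols["level"][i:j][mask]
    w = np.searchsorted(edges, pos, side="right") - 1
    ok = (w >= 0) & (w < n_windows)
    w = w[ok]
    if estimator == "weighted":
        num = np.bincount(w, weights=meth[ok], minlength=n_windows)
        den = np.bincount(w, weights=total[ok], minlength=n_windows)
    else:
        num = np.bincount(w, weights=level[ok], minlength=n_windows)
        den = np.bincount(w, minlength=n_windows).astype(float)
    has = den > 0
    out[has] = num[has] / den[has]
    return out


def _group_profiles(per_gene: dict[str, np.ndarray], expr: ExpressionTable,
                    n_groups: int, n_windows: int, labels: list[str],
                    mode: str, n_excluded: int) -> MetageneProfile:
    e = expr.to_series()
    profiled = [g for g in per_gene if g in e.index]
    if not profiled:
        raise DataError("no profiled gene has an expression value")
    groups = assign_expression_groups(e.loc[profiled], n_groups)
    mat = {}
    counts = {}
    for grp in sorted(groups.unique()):
        members = groups.index[groups == grp]
        stack = np.vstack([per_gene[g] for g in members])
        present = (~np.isnan(stack)).sum(axis=0)
        sums = np.nansum(stack, axis=0)
        mat[grp] = np.where(present > 0, sums / np.maximum(present, 1), np.nan)
        counts[grp] = len(members)
    matrix = pd.DataFrame(mat).T
    matrix.columns = labels
    matrix.index.name = "group"
    return MetageneProfile(matrix=matrix, n_genes=pd.Series(counts, name="n_genes"),
                           mode=mode, window_labels=labels,
                           n_excluded_short=n_excluded)


def metagene_region(records, genes, expr: ExpressionTable, context: str,
                    n_body_windows: int = 30, n_flank_windows: int = 15,
                    n_groups: int = 5, min_coverage: int = 1,
                    estimator: str = "weighted") -> MetageneProfile:
    """Length-normalized profile: each gene body is split into
    ``n_body_windows`` windows and each flank spans half the gene's own body
    length, split into ``n_flank_windows`` windows. Genes shorter than
    ``n_body_windows`` bp are excluded (counted). Minus-strand genes are
    flipped so window 1 is 5'.
    """
    sites = as_site_table(records)
    code = CTX_CODE[context]
    per_gene = {}
    n_short = 0
    for g in genes:
        length = g.body_length
        if length < n_body_windows:
            n_short += 1
            continue
        flank = length / 2.0
        edges = np.concatenate([
            np.linspace(g.start - flank, g.start, n_flank_windows + 1)[:-1],
            np.linspace(g.start, g.end + 1, n_body_windows + 1)[:-1],
            np.linspace(g.end + 1, g.end + 1 + flank, n_flank_windows + 1),
        ])
        prof = _per_gene_window_levels(sites.sites(g.chrom), edges, code,
                                       min_coverage, estimator)
        if g.strand == "-":
            prof = prof[::-1]
        per_gene[g.gene_id] = prof
    if not per_gene:
        raise DataError(f"no gene passes the length filter (>= {n_body_windows} bp)")
    labels = ([f"u{i + 1}" for i in range(n_flank_windows)]
              + [f"b{i + 1}" for i in range(n_body_windows)]
              + [f"d{i + 1}" for i in range(n_flank_windows)])
    return _group_profiles(per_gene, expr, n_groups,
                           n_body_windows + 2 * n_flank_windows, labels,
                           "region", n_short)


def metagene_site(records, genes, expr: ExpressionTable, context: str,
                  anchor: str = "TSS", flank_bp: int = 2000,
                  n_windows: int = 10, n_groups: int = 5,
                  min_coverage: int = 1,
                  estimator: str = "weighted") -> MetageneProfile:
    """Anchored profile: ``n_windows`` windows of width ``flank_bp/n_windows``
    on each side of the oriented TSS or TES. With ``n_windows == flank_bp``
    the profile is single-base resolution. Oriented offset 0 (the anchor
    base) falls in the first downstream window.
    """
    if anchor not in ("TSS", "TES"):
        raise DataError(f"anchor must be TSS or TES, got {anchor!r}")
    if n_windows < 1 or flank_bp < n_windows:
        raise DataError("need n_windows >= 1 and flank_bp >= n_windows")
    sites = as_site_table(records)
    code = CTX_CODE[context]
    width = flank_bp / n_windows
    per_gene = {}
    for g in genes:
        point = g.tss if anchor == "TSS" else g.tes
        cols = sites.sites(g.chrom)
        n_total = 2 * n_windows
        prof = np.full(n_total, np.nan)
        if cols is not None:
            pos = cols["pos"]
            i = np.searchsorted(pos, point - flank_bp, side="left")
            j = np.searchsorted(pos, point + flank_bp + 1, side="left")
            if j > i:
                sub_pos = pos[i:j]
                mask = (cols["ctx"][i:j] == code) & (cols["total"][i:j] >= min_coverage)
                sub_pos = sub_pos[mask]
                meth = cols["meth"][i:j][mask].astype(float)
                total = cols["total"][i:j][mask].astype(float)
                level = cols["level"][i:j][mask]
                offset = (sub_pos - point) if g.strand == "+" else (point - sub_pos)
                w = np.floor((offset + flank_bp) / width).astype(int)
                ok = (w >= 0) & (w < n_total)
                w = w[ok]
                if estimator == "weighted":
                    num = np.bincount(w, weights=meth[ok], minlength=n_total)
                    den = np.bincount(w, weights=total[ok], minlength=n_total)
                else:
                    num = np.bincount(w, weights=level[ok], minlength=n_total)
                    den = np.bincount(w, minlength=n_total).astype(float)
                has = den > 0
                prof[has] = num[has] / den[has]
        per_gene[g.gene_id] = prof
    if not per_gene:
        raise DataError("no genes to profile")
    labels = [f"{int(round(-flank_bp + k * width))}" for k in range(2 * n_windows)]
    return _group_profiles(per_gene, expr, n_groups, 2 * n_windows, labels,
                           f"site:{anchor}", 0)
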