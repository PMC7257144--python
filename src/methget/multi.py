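"""Two-group analyses: per-gene methylation change vs expression fold change,
Gaussian-mixture differential-gene calling, and joint clustered heatmap.

Group-level values are unweighted means over the samples of a group. The
differential caller fits a bivariate Gaussian mixture (scikit-learn) on the
(log2 fold change, delta methylation) cloud and flags low-density outliers:
with one component the p-value is the chi-square(2) survival function of the
squared Mahalanobis distance; with k > 1 components it is a Monte-Carlo tail
probability of the mixture density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.mixture import GaussianMixture

from .errors import DataError
from .io import ExpressionTable
from .methylation import RegionMethylationTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Group averaging
# ---------------------------------------------------------------------------


def group_average(
    samples: list[RegionMethylationTable],
    exprs: list[ExpressionTable],
) -> tuple[RegionMethylationTable, ExpressionTable, pd.Series]:
    """Average methylation tables and expression tables within one group.

    Per-cell/per-gene unweighted mean over the samples where the value is
    present; a cell is missing only if missing in every sample. Returns the
    averaged tables plus a gene -> n-samples-present series for expression.
    """
    if not samples or not exprs:
        raise DataError("need at least one sample per group")
    shared_meth = set(samples[0].data.index.get_level_values(0))
    for s in samples[1:]:
        shared_meth &= set(s.data.index.get_level_values(0))
    shared_expr = set(exprs[0].data.index)
    for e in exprs[1:]:
        shared_expr &= set(e.data.index)
    if not shared_meth or not shared_expr:
        raise DataError(
            "disjoint gene sets across samples within a group "
            f"(methylation overlap {len(shared_meth)}, expression overlap {len(shared_expr)})"
        )
    levels = pd.concat([s.data["level"] for s in samples], axis=1)
    n_sites = pd.concat([s.data["n_sites"] for s in samples], axis=1).sum(axis=1)
    coverage = pd.concat([s.data["coverage"] for s in samples], axis=1).sum(axis=1)
    avg = pd.DataFrame({
        "level": levels.mean(axis=1, skipna=True),
        "n_sites": n_sites.astype(int),
        "coverage": coverage.astype(int),
    })
    meth = RegionMethylationTable(
        avg,
        min_coverage=samples[0].min_coverage,
        min_sites=samples[0].min_sites,
        estimator=samples[0].estimator,
    )
    expr_df = pd.concat([e.data for e in exprs], axis=1)
    expr = ExpressionTable(expr_df.mean(axis=1, skipna=True).rename("expression"))
    n_present = expr_df.notna().sum(axis=1).rename("n_samples")
    return meth, expr, n_present


# ---------------------------------------------------------------------------
# Comparison (delta methylation vs log2 fold change)
# ---------------------------------------------------------------------------


@dataclass
class Comparison:
    """Per-gene (delta methylation, log2 fold change) with overall Pearson r.

    ``table`` is indexed by gene with columns meth_a, meth_b, delta_meth,
    expr_a, expr_b, log2fc. delta_meth = mean level A - mean level B;
    log2fc = log2((exprA + pseudocount) / (exprB + pseudocount)).
    """

    table: pd.DataFrame
    pearson_r: float | None
    pearson_p: float | None
    context: str
    region_type: str
    pseudocount: float
    n_excluded: int = 0


def compare(
    meth_a: RegionMethylationTable,
    expr_a: ExpressionTable,
    meth_b: RegionMethylationTable,
    expr_b: ExpressionTable,
    context: str,
    region_type: str,
    pseudocount: float = 1.0,
) -> Comparison:
    la = meth_a.level_series(context, region_type)
    lb = meth_b.level_series(context, region_type)
    ea = expr_a.to_series()
    eb = expr_b.to_series()
    shared = la.index.intersection(lb.index).intersection(ea.index).intersection(eb.index)
    n_all = len(set(la.index) | set(lb.index) | set(ea.index) | set(eb.index))
    if len(shared) < 3:
        raise DataError(f"need >=3 genes present in both groups, got {len(shared)}")
    shared = shared.sort_values()
    tab = pd.DataFrame({
        "meth_a": la.loc[shared],
        "meth_b": lb.loc[shared],
        "expr_a": ea.loc[shared],
        "expr_b": eb.loc[shared],
    })
    tab["delta_meth"] = tab["meth_a"] - tab["meth_b"]
    tab["log2fc"] = np.log2((tab["expr_a"] + pseudocount) / (tab["expr_b"] + pseudocount))
    tab = tab[["meth_a", "meth_b", "delta_meth", "expr_a", "expr_b", "log2fc"]]
    x = tab["delta_meth"].to_numpy()
    y = tab["log2fc"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        r = p = None
    else:
        pr = stats.pearsonr(x, y)
        r, p = float(pr.statistic), float(pr.pvalue)
    return Comparison(table=tab, pearson_r=r, pearson_p=p, context=context,
                      region_type=region_type, pseudocount=pseudocount,
                      n_excluded=n_all - len(shared))


# ---------------------------------------------------------------------------
# Differential-gene calling
# ---------------------------------------------------------------------------


def _quadrant(x: float, y: float) -> int:
    """Quadrant by signs of (x=expression change, y=methylation change);
    0 when a coordinate is exactly zero (on an axis)."""
    if x == 0 or y == 0:
        return 0
    if x > 0:
        return 1 if y > 0 else 4
    return 2 if y > 0 else 3


@dataclass
class DifferentialResult:
    """Comparison table augmented with gmm_p, is_differential and quadrant.

    ``quadrant_counts`` counts differential genes per quadrant (1..4; genes
    on an axis carry quadrant 0 and are excluded from the counts).
    """

    table: pd.DataFrame
    quadrant_counts: pd.Series
    alpha: float
    n_components: int
    seed: int
    means: np.ndarray = field(repr=False, default=None)
    covariances: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)


def call_differential(
    comparison: Comparison,
    alpha: float = 1e-6,
    n_components: int = 1,
    seed: int = 0,
    n_draws: int = 100_000,
) -> DifferentialResult:
    """Flag genes whose (log2fc, delta_meth) point is a low-density outlier.

    Fits a full-covariance Gaussian mixture with deterministic k-means++
    initialization at ``seed``. For ``n_components == 1`` the p-value is
    ``chi2.sf(mahalanobis^2, df=2)``; otherwise the Monte-Carlo tail of the
    mixture density with ``n_draws`` draws (>= 1e5).
    """
    if not (0 < alpha < 1):
        raise DataError("alpha must be in (0, 1)")
    tab = comparison.table.copy()
    if len(tab) < 10:
        raise DataError(f"need >=10 genes for differential calling, got {len(tab)}")
    X = tab[["log2fc", "delta_meth"]].to_numpy()
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        init_params="k-means++",
        n_init=1,
        random_state=seed,
        reg_covar=1e-8,
    )
    try:
        gm.fit(X)
    except ValueError:
        log.warning("singular covariance; refitting with larger ridge")
        gm.set_params(reg_covar=1e-6)
        gm.fit(X)
    if n_components == 1:
        mu = gm.means_[0]
        cov = gm.covariances_[0]
        try:
            prec = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            log.warning("singular covariance; adding ridge 1e-8")
            prec = np.linalg.inv(cov + 1e-8 * np.eye(2))
        d = X - mu
        d2 = np.einsum("ij,jk,ik->i", d, prec, d)
        pvals = stats.chi2.sf(d2, df=2)
    else:
        n_draws = max(n_draws, 100_000)
        log_dens = gm.score_samples(X)
        draws, _ = gm.sample(n_draws)
        log_dens_draws = gm.score_samples(draws)
        # add-one tail estimate keeps p in (0, 1]
        pvals = np.array([
            (1 + np.count_nonzero(log_dens_draws <= ld)) / (n_draws + 1)
            for ld in log_dens
        ])
    tab["gmm_p"] = pvals
    tab["is_differential"] = tab["gmm_p"] < alpha
    tab["quadrant"] = [
        _quadrant(x, y) for x, y in zip(tab["log2fc"], tab["delta_meth"])
    ]
    diff = tab[tab["is_differential"] & (tab["quadrant"] > 0)]
    counts = pd.Series(
        {q: int((diff["quadrant"] == q).sum()) for q in (1, 2, 3, 4)},
        name="n_differential",
    )
    counts.index.name = "quadrant"
    return DifferentialResult(
        table=tab, quadrant_counts=counts, alpha=alpha,
        n_components=n_components, seed=seed,
        means=gm.means_, covariances=gm.covariances_, weights=gm.weights_,
    )


def differential_table(result: DifferentialResult, path=None) -> pd.DataFrame:
    """Table of differential genes sorted by ascending p-value.

    Columns: gene, meanA_meth, meanB_meth, delta_meth, exprA, exprB, log2fc,
    gmm_p, quadrant. Written as TSV when ``path`` is given.
    """
    diff = result.table[result.table["is_differential"]].sort_values(
        ["gmm_p", "delta_meth"], kind="mergesort"
    )
    out = diff.reset_index(names="gene")[
        ["gene", "meth_a", "meth_b", "delta_meth", "expr_a", "expr_b",
         "log2fc", "gmm_p", "quadrant"]
    ].rename(columns={
        "meth_a": "meanA_meth", "meth_b": "meanB_meth",
        "expr_a": "exprA", "expr_b": "exprB",
    })
    if path is not None:
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return out


# ---------------------------------------------------------------------------
# Joint clustered heatmap
# ---------------------------------------------------------------------------


@dataclass
class HeatmapResult:
    """Row-clustered joint methylation/expression matrix.

    ``matrix`` columns: meth_A, meth_B (raw levels in [0, 1]) and expr_A,
    expr_B (log2(x + pseudocount), z-scored across the two expression cells
    of each row so both data types share a color scale). ``order`` is the
    dendrogram leaf order (a permutation of the input genes).
    """

    matrix: pd.DataFrame
    order: list[str]
    linkage: np.ndarray = field(repr=False, default=None)
    method: str = "average"
    metric: str = "euclidean"


def heatmap_cluster(
    meth_a: RegionMethylationTable,
    expr_a: ExpressionTable,
    meth_b: RegionMethylationTable,
    expr_b: ExpressionTable,
    context: str,
    region_type: str,
    genes: list[str] | None = None,
    linkage: str = "average",
    metric: str = "euclidean",
    pseudocount: float = 1.0,
) -> HeatmapResult:
    if linkage not in ("average", "complete", "ward"):
        raise DataError(f"unsupported linkage {linkage!r}")
    la = meth_a.level_series(context, region_type)
    lb = meth_b.level_series(context, region_type)
    ea = expr_a.to_series()
    eb = expr_b.to_series()
    shared = la.index.intersection(lb.index).intersection(ea.index).intersection(eb.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    shared = shared.sort_values()
    if len(shared) < 2:
        raise DataError(f"need >=2 genes with complete rows, got {len(shared)}")
    log_a = np.log2(ea.loc[shared].to_numpy() + pseudocount)
    log_b = np.log2(eb.loc[shared].to_numpy() + pseudocount)
    center = (log_a + log_b) / 2
    scale = np.abs(log_a - log_b) / 2  # population sd of the two cells
    with np.errstate(invalid="ignore", divide="ignore"):
        za = np.where(scale > 0, (log_a - center) / scale, 0.0)
        zb = np.where(scale > 0, (log_b - center) / scale, 0.0)
    matrix = pd.DataFrame(
        {
            "meth_A": la.loc[shared].to_numpy(),
            "meth_B": lb.loc[shared].to_numpy(),
            "expr_A": za,
            "expr_B": zb,
        },
        index=shared,
    )
    Z = hierarchy.linkage(matrix.to_numpy(), method=linkage, metric=metric)
    leaves = hierarchy.leaves_list(Z)
    order = [shared[i] for i in leaves]
    return HeatmapResult(matrix=matrix, order=order, linkage=Z,
                         method=linkage, metric=metric)
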