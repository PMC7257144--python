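"""Synthetic CGmap / GTF / expression fixtures with planted structure.

Every analysis in the package is testable offline against these fixtures: the
generator plants (a) a per-gene correlation between region methylation and
expression and (b), in two-group mode, a designated differential subset with a
known (delta methylation, log2 fold change) shift, and records every latent
value in a truth table.

Construction: each gene draws a latent z ~ N(0,1); its expression is affine in
z (truncated at zero) and its promoter/body target methylation levels are
Gaussian-copula coupled to z with the configured correlations, squashed into
[level_low, level_high] via the normal CDF. Per-cytosine counts are
total ~ 1 + Poisson(coverage_mean), meth ~ Binomial(total, target level), so
region averages recover the targets up to binomial noise. Intergenic gaps are
kept >= 2 x promoter span so promoter and body assignment regions of distinct
genes never overlap, keeping the planted correlations clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DataError
from .io import CONTEXTS

PROMOTER_BP = 2000


@dataclass
class SynthConfig:
    """Configuration for :func:`generate`. ``seed`` is mandatory."""

    seed: int
    n_chroms: int = 2
    n_genes: int = 100
    gene_length_range: tuple[int, int] = (900, 3000)
    intergenic_range: tuple[int, int] = (4200, 5200)
    exons_per_gene_range: tuple[int, int] = (1, 4)
    coverage_mean: float = 8.0
    context_density: dict = field(
        default_factory=lambda: {"CG": 0.06, "CHG": 0.03, "CHH": 0.06}
    )
    promoter_rho: float = -0.5
    body_rho: float = 0.2
    level_low: float = 0.05
    level_high: float = 0.95
    background_level: float = 0.08
    zero_expr_frac: float = 0.1
    expr_mean: float = 50.0
    expr_sd: float = 12.0
    two_group: bool = False
    n_samples_per_group: int = 1
    n_diff_genes: int = 0
    group_effect: tuple[float, float] = (-0.4, -2.0)  # (delta_meth, log2fc)

    def __post_init__(self):
        if self.seed is None:
            raise DataError("seed is mandatory")
        for name in ("gene_length_range", "intergenic_range", "exons_per_gene_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise DataError(f"invalid {name}: {(lo, hi)}")
        for name in ("promoter_rho", "body_rho"):
            if abs(getattr(self, name)) > 1:
                raise DataError(f"|{name}| must be <= 1")
        if not 0 <= self.zero_expr_frac < 1:
            raise DataError("zero_expr_frac must be in [0, 1)")
        if self.intergenic_range[0] < 2 * PROMOTER_BP + 100:
            raise DataError(
                "intergenic_range must start >= 2 x promoter span + 100 so planted "
                "region levels stay disjoint"
            )


@dataclass
class SynthOutput:
    gtf: Path
    cgmap: dict[str, Path]       # sample name -> path
    expression: dict[str, Path]  # sample name -> path
    truth: Path
    truth_table: pd.DataFrame
    chrom_sizes: dict[str, int]


def _squash(g: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) * norm.cdf(g)


def _copula(z: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(len(z))
    return rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eps


def generate(config: SynthConfig, outdir: str | Path) -> SynthOutput:
    """Write fixture files under ``outdir`` and return their paths plus the
    truth table. Deterministic: the same config yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    # --- gene layout -------------------------------------------------------
    chrom_of = np.array([i % config.n_chroms for i in range(n)])
    lengths = rng.integers(*config.gene_length_range, size=n, endpoint=True)
    gaps = rng.integers(*config.intergenic_range, size=n, endpoint=True)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    starts = np.zeros(n, dtype=np.int64)
    ends = np.zeros(n, dtype=np.int64)
    cursor = {c: PROMOTER_BP + 500 for c in range(config.n_chroms)}
    for i in range(n):
        c = chrom_of[i]
        start = cursor[c] + gaps[i]
        starts[i] = start
        ends[i] = start + lengths[i] - 1
        cursor[c] = ends[i]
    chrom_sizes = {
        f"Chr{c + 1}": int(cursor[c] + 2 * PROMOTER_BP) for c in range(config.n_chroms)
    }
    gene_ids = [f"g{i + 1:05d}" for i in range(n)]
    chrom_names = [f"Chr{c + 1}" for c in chrom_of]

    # --- latent structure --------------------------------------------------
    z = rng.standard_normal(n)
    level_prom = _squash(_copula(z, config.promoter_rho, rng),
                         config.level_low, config.level_high)
    level_body = _squash(_copula(z, config.body_rho, rng),
                         config.level_low, config.level_high)
    expr = np.maximum(config.expr_mean + config.expr_sd * z, 0.0)
    n_zero = int(round(config.zero_expr_frac * n))
    zero_idx = rng.choice(n, size=n_zero, replace=False) if n_zero else np.array([], int)
    expr[zero_idx] = 0.0

    is_diff = np.zeros(n, dtype=bool)
    level_prom_a = level_prom.copy()
    level_body_a = level_body.copy()
    expr_a = expr.copy()
    if config.two_group and config.n_diff_genes:
        d_meth, d_lfc = config.group_effect
        candidates = np.flatnonzero(expr > 0)
        if len(candidates) < config.n_diff_genes:
            raise DataError("not enough expressed genes for the differential subset")
        chosen = rng.choice(candidates, size=config.n_diff_genes, replace=False)
        is_diff[chosen] = True
        level_prom_a[chosen] = np.clip(level_prom[chosen] + d_meth, 0.01, 0.99)
        level_body_a[chosen] = np.clip(level_body[chosen] + d_meth, 0.01, 0.99)
        # invert log2((eA+1)/(eB+1)) = d_lfc exactly
        expr_a[chosen] = np.maximum((expr[chosen] + 1.0) * 2.0**d_lfc - 1.0, 0.0)

    # --- GTF ---------------------------------------------------------------
    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "wt") as gtf:
        for i in range(n):
            gid, chrom, strand = gene_ids[i], chrom_names[i], strands[i]
            s, e = int(starts[i]), int(ends[i])
            attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1";'
            gtf.write(f"{chrom}\tsynth\tgene\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n")
            for xs, xe in _exon_layout(s, e, config.exons_per_gene_range, rng):
                gtf.write(f"{chrom}\tsynth\texon\t{xs}\t{xe}\t.\t{strand}\t.\t{attrs}\n")

    # --- cytosine sites ----------------------------------------------------
    # assignment intervals (disjoint by construction): body and promoter per gene
    site_plan = {}  # chrom -> (positions, contexts)
    for c in range(config.n_chroms):
        chrom = f"Chr{c + 1}"
        length = chrom_sizes[chrom]
        pos_list, ctx_list = [], []
        for ctx in CONTEXTS:
            density = config.context_density.get(ctx, 0.0)
            n_sites = int(length * density)
            if n_sites == 0:
                continue
            pos = rng.choice(np.arange(1, length + 1), size=n_sites, replace=False)
            pos_list.append(pos)
            ctx_list.append(np.full(n_sites, ctx, dtype=object))
        if not pos_list:
            raise DataError("context_density produced zero sites")
        pos = np.concatenate(pos_list)
        ctx = np.concatenate(ctx_list)
        order = np.argsort(pos, kind="stable")
        site_plan[chrom] = (pos[order], ctx[order])

    def _targets(chrom: str, pos: np.ndarray, prom_levels, body_levels) -> np.ndarray:
        """Per-site target level from the gene whose body/promoter contains it.

        Bodies and promoters are disjoint by construction, so a sorted
        interval array plus searchsorted resolves each site in O(log n).
        """
        ivals = []  # (start, end, level)
        for i in range(n):
            if chrom_names[i] != chrom:
                continue
            ivals.append((starts[i], ends[i], body_levels[i]))
            if strands[i] == "+":
                ivals.append((max(1, starts[i] - PROMOTER_BP), starts[i] - 1,
                              prom_levels[i]))
            else:
                ivals.append((ends[i] + 1, ends[i] + PROMOTER_BP, prom_levels[i]))
        ivals.sort()
        iv_start = np.array([v[0] for v in ivals], dtype=np.int64)
        iv_end = np.array([v[1] for v in ivals], dtype=np.int64)
        iv_level = np.array([v[2] for v in ivals])
        idx = np.searchsorted(iv_start, pos, side="right") - 1
        idx_c = np.clip(idx, 0, None)
        inside = (idx >= 0) & (pos <= iv_end[idx_c])
        return np.where(inside, iv_level[idx_c], config.background_level)

    if config.two_group:
        sample_levels = {}
        for r in range(config.n_samples_per_group):
            sample_levels[f"groupA_rep{r + 1}"] = (level_prom_a, level_body_a)
        for r in range(config.n_samples_per_group):
            sample_levels[f"groupB_rep{r + 1}"] = (level_prom, level_body)
    else:
        sample_levels = {"sample": (level_prom, level_body)}

    strand_draw = {}  # per-site strand shared across samples
    for chrom, (pos, _) in site_plan.items():
        strand_draw[chrom] = np.where(rng.random(len(pos)) < 0.5, "C", "G")

    cgmap_paths = {}
    for sample, (prom_levels, body_levels) in sample_levels.items():
        path = outdir / f"{sample}.cgmap"
        with open(path, "wt") as out:
            for chrom in sorted(site_plan):
                pos, ctx = site_plan[chrom]
                target = _targets(chrom, pos, prom_levels, body_levels)
                total = 1 + rng.poisson(config.coverage_mean, size=len(pos))
                meth = rng.binomial(total, target)
                nuc = strand_draw[chrom]
                for k in range(len(pos)):
                    dinuc = "CG" if ctx[k] == "CG" else "CH"
                    out.write(
                        f"{chrom}\t{nuc[k]}\t{pos[k]}\t{ctx[k]}\t{dinuc}\t"
                        f"{meth[k] / total[k]:.2f}\t{meth[k]}\t{total[k]}\n"
                    )
        cgmap_paths[sample] = path

    # --- expression --------------------------------------------------------
    expr_paths = {}
    for sample in sample_levels:
        vals = expr_a if sample.startswith("groupA") else expr
        path = outdir / f"{sample}.expression.tsv"
        with open(path, "wt") as out:
            out.write("gene\texpression\n")
            for i in range(n):
                out.write(f"{gene_ids[i]}\t{vals[i]:.4f}\n")
        expr_paths[sample] = path

    # --- truth table -------------------------------------------------------
    truth = pd.DataFrame({
        "gene": gene_ids,
        "chrom": chrom_names,
        "start": starts,
        "end": ends,
        "strand": strands,
        "z": z,
        "expression": expr,
        "promoter_level": level_prom,
        "body_level": level_body,
        "expression_a": expr_a,
        "promoter_level_a": level_prom_a,
        "body_level_a": level_body_a,
        "is_differential": is_diff,
    })
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.8g")
    return SynthOutput(
        gtf=gtf_path, cgmap=cgmap_paths, expression=expr_paths,
        truth=truth_path, truth_table=truth, chrom_sizes=chrom_sizes,
    )


def _exon_layout(start: int, end: int, k_range: tuple[int, int],
                 rng: np.random.Generator) -> list[tuple[int, int]]:
    """Split a gene body into alternating exon/intron segments (k exons)."""
    length = end - start + 1
    k = int(rng.integers(k_range[0], k_range[1], endpoint=True))
    k = max(1, min(k, (length + 1) // 2))
    n_segments = 2 * k - 1
    if n_segments == 1 or length < n_segments:
        return [(start, end)]
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_segments - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    segments = [
        (start + int(bounds[i]), start + int(bounds[i + 1]) - 1)
        for i in range(n_segments)
    ]
    return segments[::2]  # even segments are exons
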