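"""Continuity versus discreteness of expression between two cell populations.

Cells from a pair of populations are ordered along a dominant expression
trajectory (external pseudotime if supplied, otherwise the first principal
axis of scaled expression).  For each gene, a four-parameter logistic

    y(x) = a + (d - a) / (1 + exp(-b (x - x0)))

is fit by nonlinear least squares to scaled expression against the
normalized pseudotime rank x = rank/N in (0, 1].  The analytic maximum
slope of the curve is b (d - a) / 4; dividing by the dynamic range (d - a)
and working on the per-unit rank scale gives the continuity metric

    m = b / 4

which is comparable across genes and across pairs of different sizes: small
m indicates graded, continuous variation, large m a step-like, discrete
switch.  Pairs are compared through the empirical CDF of log10(m) over
their top differentially expressed genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import NormalizedMatrix, ValidationError, bh_adjust

__all__ = [
    "TrajectoryOrdering",
    "LogisticFit",
    "order_cells",
    "scale_expression",
    "fit_logistic_gene",
    "continuity_m",
    "rank_trajectory_genes",
    "wilcoxon_de_genes",
    "compare_pair",
    "ecdf",
]

log = logging.getLogger(__name__)

MIN_CELLS = 20
Z_CLIP = 10.0


@dataclass
class TrajectoryOrdering:
    """Pseudotime ranks 1..N and normalized positions x = rank/N."""

    cell_ids: np.ndarray
    rank: np.ndarray
    source: str

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if sorted(self.rank) != list(range(1, n + 1)):
            raise ValidationError("ranks must be a permutation of 1..N")

    @property
    def x(self) -> np.ndarray:
        return self.rank / len(self.rank)


@dataclass
class LogisticFit:
    """Four-parameter logistic fit; asymptotes ordered so d >= a, b >= 0."""

    a: float
    d: float
    b: float
    x0: float
    converged: bool
    rss: float
    b_capped: bool = False

    @property
    def dynamic_range(self) -> float:
        return self.d - self.a


def order_cells(expr: NormalizedMatrix, pseudotime=None, n_top_var: int = 500) -> TrajectoryOrdering:
    """Rank cells along the trajectory.

    With ``pseudotime`` supplied, ranks are its ranks (ties broken by cell
    order).  Otherwise cells are projected onto the first principal axis of
    z-scored expression of the most variable genes; orientation is fixed so
    the first supplied cell falls in the lower half (a flippable convention).
    """
    n = expr.n_cells
    if n < MIN_CELLS:
        raise ValidationError(f"need at least {MIN_CELLS} cells, got {n}")
    if pseudotime is not None:
        pt = np.asarray(pseudotime, dtype=float)
        if pt.shape[0] != n:
            raise ValidationError("pseudotime length does not match cell count")
        order = np.argsort(pt, kind="mergesort")
        source = "external"
    else:
        scaled = scale_expression(expr)
        if scaled.n_genes == 0:
            raise ValidationError("no dominant expression axis (constant matrix)")
        z = scaled.dense()
        var = z.var(axis=1)
        top = np.argsort(var)[::-1][: min(n_top_var, z.shape[0])]
        zt = z[top]
        # first right singular vector = projection on the first principal axis
        _, _, vt = np.linalg.svd(zt - zt.mean(axis=1, keepdims=True), full_matrices=False)
        score = vt[0]
        if np.allclose(score, score[0]):
            raise ValidationError("no dominant expression axis (constant matrix)")
        order = np.argsort(score, kind="mergesort")
        source = "internal-pc1"
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    if source == "internal-pc1" and rank[0] > (n + 1) / 2:
        # PC sign is arbitrary; orient so the first supplied cell ranks low
        rank = n + 1 - rank
    return TrajectoryOrdering(cell_ids=np.asarray(expr.cell_ids), rank=rank, source=source)


def scale_expression(expr: NormalizedMatrix, clip: float = Z_CLIP) -> NormalizedMatrix:
    """Per-gene z-score across cells, clipped to [-clip, clip].

    Zero-variance genes are excluded (logged), mirroring the standard
    highly-variable-gene scaling step of single-cell pipelines.
    """
    y = expr.dense().astype(float)
    sd = y.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        log.info("excluding %d zero-variance genes from scaling", int((~keep).sum()))
    y = y[keep]
    z = (y - y.mean(axis=1, keepdims=True)) / sd[keep, np.newaxis]
    np.clip(z, -clip, clip, out=z)
    return NormalizedMatrix(
        z, expr.gene_ids[keep], expr.cell_ids,
        normalization_record=expr.normalization_record + f"; z-scored, clipped +-{clip:g}",
    )


def _logistic(x, a, d, b, x0):
    z = np.clip(-b * (x - x0), -700.0, 700.0)
    return a + (d - a) / (1.0 + np.exp(z))


def fit_logistic_gene(y, ordering: TrajectoryOrdering, max_nfev: int = 2000) -> LogisticFit:
    """Nonlinear least-squares logistic fit of scaled expression vs x.

    Initialization a=min(y), d=max(y), x0=0.5, b=4, with a restart grid over
    x0 in {0.25, 0.5, 0.75} and b in {1, 10, 100} if the first attempt fails
    to converge.  Steepness is bounded in [1e-3, 4N] so a single-cell
    transition is representable but log10(m) stays finite.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("expression values must be finite")
    x = ordering.x
    if y.shape[0] != x.shape[0]:
        raise ValidationError("expression length does not match ordering")
    n = len(x)
    b_max = 4.0 * n
    lo, hi = y.min(), y.max()
    # asymptotes of shallow curves sit far outside the observed range, so
    # only steepness and midpoint are bounded
    bounds = ([-np.inf, -np.inf, 1e-3, 0.0], [np.inf, np.inf, b_max, 1.0])

    def attempt(p0):
        try:
            popt, _ = optimize.curve_fit(
                _logistic, x, y, p0=p0, bounds=bounds, max_nfev=max_nfev
            )
        except (RuntimeError, optimize.OptimizeWarning, ValueError):
            return None
        rss = float(np.sum((_logistic(x, *popt) - y) ** 2))
        return popt, rss

    best = attempt([lo, hi, 4.0, 0.5])
    if best is None:
        for x0_init in (0.25, 0.5, 0.75):
            for b_init in (1.0, 10.0, 100.0):
                best = attempt([lo, hi, b_init, x0_init])
                if best is not None:
                    break
            if best is not None:
                break
    if best is None:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, converged=False, rss=np.nan)
    (a, d, b, x0), rss = best
    if d < a:  # falling curve: swap asymptotes, slope magnitude unchanged
        a, d = d, a
    capped = bool(np.isclose(b, b_max, rtol=1e-3))
    return LogisticFit(float(a), float(d), float(b), float(x0),
                       converged=True, rss=rss, b_capped=capped)


def continuity_m(fit: LogisticFit) -> float:
    """Normalized maximum slope m = b/4 of a converged fit (NaN otherwise)."""
    if not fit.converged:
        return float("nan")
    return fit.b / 4.0


def rank_trajectory_genes(
    scaled: NormalizedMatrix, ordering: TrajectoryOrdering, n_top: int = 200
) -> pd.DataFrame:
    """Genes ordered by |Spearman rho| with pseudotime rank, top n_top kept.

    Ties in |rho| are broken by gene id lexicographically.
    """
    z = scaled.dense()
    rho = np.array([stats.spearmanr(row, ordering.rank).statistic for row in z])
    rho = np.nan_to_num(rho)
    df = pd.DataFrame({"gene_id": scaled.gene_ids, "spearman_rho": rho})
    df["abs_rho"] = df["spearman_rho"].abs()
    df = df.sort_values(["abs_rho", "gene_id"], ascending=[False, True],
                        kind="mergesort").drop(columns="abs_rho")
    if n_top > len(df):
        log.warning("n_top=%d exceeds %d genes; returning all", n_top, len(df))
        n_top = len(df)
    return df.head(n_top).reset_index(drop=True)


def wilcoxon_de_genes(
    expr: NormalizedMatrix, group_a_mask, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum between the two populations, BH-adjusted.

    The standard marker-gene pre-filter; isolated here so it can be swapped
    for another differential-expression routine.
    """
    mask = np.asarray(group_a_mask, dtype=bool)
    y = expr.dense()
    a, b = y[:, mask], y[:, ~mask]
    stat_p = [stats.mannwhitneyu(ra, rb, alternative="two-sided") for ra, rb in zip(a, b)]
    p = np.array([sp.pvalue for sp in stat_p])
    q = bh_adjust(p)
    return pd.DataFrame({"gene_id": expr.gene_ids, "p": p, "q": q,
                         "significant": q < alpha})


def ecdf(values) -> pd.DataFrame:
    """Empirical CDF evaluated at the sorted sample points."""
    v = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"value": v, "cdf": np.arange(1, len(v) + 1) / len(v)})


def compare_pair(
    expr_a: NormalizedMatrix,
    expr_b: NormalizedMatrix,
    n_top: int = 200,
    max_cells: int = 5000,
    seed: int = 0,
    pseudotime=None,
    de_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Continuity analysis of one population pair.

    Pools the two populations, downsamples to ``max_cells`` nuclei, orders
    cells along the trajectory, selects differentially expressed genes,
    keeps the top ``n_top`` by |Spearman| with pseudotime rank, fits the
    logistic per gene, and returns (per-gene results, ECDF of log10(m)).
    An empty result frame (with a ``status`` attribute) is returned when no
    gene passes the differential-expression filter.
    """
    if not np.array_equal(expr_a.gene_ids, expr_b.gene_ids):
        raise ValidationError("populations must share the same gene space")
    values = _hstack(expr_a.values, expr_b.values)
    cell_ids = np.concatenate([expr_a.cell_ids, expr_b.cell_ids])
    group_a = np.zeros(len(cell_ids), dtype=bool)
    group_a[: expr_a.n_cells] = True
    pooled = NormalizedMatrix(values, expr_a.gene_ids, cell_ids,
                              expr_a.normalization_record)

    if pooled.n_cells > max_cells:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(pooled.n_cells, size=max_cells, replace=False))
        pooled = pooled.subset_cells(np.isin(np.arange(len(cell_ids)), keep))
        group_a = group_a[keep]
        if pseudotime is not None:
            pseudotime = np.asarray(pseudotime, dtype=float)[keep]
    if pooled.n_cells < MIN_CELLS:
        raise ValidationError("fewer than 20 cells after downsampling")

    de = wilcoxon_de_genes(pooled, group_a, alpha=de_alpha)
    sig_genes = de.loc[de["significant"], "gene_id"].to_numpy()
    empty_cols = ["gene_id", "spearman_rho", "a", "d", "b", "x0", "m",
                  "log10_m", "b_capped", "n_cells_used"]
    if len(sig_genes) == 0:
        log.warning("no significant DE genes between the populations")
        out = pd.DataFrame(columns=empty_cols)
        out.attrs["status"] = "no-de-genes"
        return out, pd.DataFrame(columns=["value", "cdf"])

    ordering = order_cells(pooled, pseudotime=pseudotime)
    scaled = scale_expression(pooled)
    keep_genes = np.isin(scaled.gene_ids, sig_genes)
    scaled = NormalizedMatrix(scaled.dense()[keep_genes], scaled.gene_ids[keep_genes],
                              scaled.cell_ids, scaled.normalization_record)
    ranked = rank_trajectory_genes(scaled, ordering, n_top=n_top)

    gene_pos = {g: i for i, g in enumerate(scaled.gene_ids)}
    z = scaled.dense()
    rows = []
    for _, rec in ranked.iterrows():
        fit = fit_logistic_gene(z[gene_pos[rec.gene_id]], ordering)
        m = continuity_m(fit)
        rows.append({
            "gene_id": rec.gene_id, "spearman_rho": rec.spearman_rho,
            "a": fit.a, "d": fit.d, "b": fit.b, "x0": fit.x0,
            "m": m, "log10_m": np.log10(m) if np.isfinite(m) else np.nan,
            "b_capped": fit.b_capped, "n_cells_used": pooled.n_cells,
        })
    results = pd.DataFrame(rows, columns=empty_cols)
    results.attrs["status"] = "ok"
    curve = ecdf(results["log10_m"].dropna().to_numpy())
    return results, curve


def _hstack(a, b):
    import scipy.sparse as sp

    if sp.issparse(a) or sp.issparse(b):
        return sp.hstack([sp.csr_matrix(a), sp.csr_matrix(b)], format="csr")
    return np.concatenate([np.asarray(a, float), np.asarray(b, float)], axis=1)
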