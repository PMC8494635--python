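"""Regional composition testing and lobule enrichment.

Does a fine cluster distribute across lobules differently from the coarse
cell type it belongs to?  With n_ij nuclei of cluster i in lobule j and
N_j = sum_i n_ij the outer type's lobule totals, the expected counts under
the homogeneous-composition null are

    E_ij = N_i * N_j / sum_j N_j

and the multinomial null is tested with Pearson's chi-squared statistic on
k-1 degrees of freedom (k = number of lobules with nonzero expectation).
Lobule enrichment is the ratio of the cluster's regional proportion to the
outer type's:

    LE_ij = (n_ij / sum_j n_ij) / (N_j / sum_j N_j)

so LE = 1 means no enrichment.  Replicate consistency splits nuclei into
two per-region replicate sets (most vs second-most represented replicate)
and correlates the resulting LE vectors per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CellAnnotation, ValidationError, bh_adjust

__all__ = [
    "CompositionTable",
    "composition_table_from_annotation",
    "expected_counts",
    "composition_test",
    "lobule_enrichment",
    "replicate_consistency",
    "split_replicate_sets",
    "downsample_outer_type",
    "label_clusters",
    "analyze_composition",
]

log = logging.getLogger(__name__)


@dataclass
class CompositionTable:
    """Clusters x lobules count table with the outer type of each cluster.

    Lobule totals N_j used in testing and enrichment are computed within
    each cluster's outer type.
    """

    counts: pd.DataFrame  # index: cluster ids, columns: lobule ids
    outer_type: pd.Series  # per cluster

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any() or np.any(vals != np.round(vals)):
            raise ValidationError("composition counts must be non-negative integers")
        self.outer_type = self.outer_type.reindex(self.counts.index)
        if self.outer_type.isna().any():
            raise ValidationError("every cluster needs an outer_type")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValidationError("clusters with zero total nuclei are not testable")

    @property
    def cluster_ids(self):
        return self.counts.index

    @property
    def lobule_ids(self):
        return self.counts.columns

    def outer_totals(self, cluster) -> pd.Series:
        """N_j for the outer type containing ``cluster``."""
        members = self.outer_type.index[self.outer_type == self.outer_type[cluster]]
        return self.counts.loc[members].sum(axis=0)


def composition_table_from_annotation(ann: CellAnnotation) -> CompositionTable:
    df = ann.table
    counts = pd.crosstab(df["cluster"], df["lobule"])
    outer = df.drop_duplicates("cluster").set_index("cluster")["outer_type"]
    return CompositionTable(counts, outer.reindex(counts.index))


def expected_counts(table: CompositionTable, cluster) -> pd.Series:
    """E_ij over lobules for one cluster; sums exactly to N_i."""
    nj = table.outer_totals(cluster).astype(float)
    total = nj.sum()
    if total == 0:
        raise ValidationError(f"outer type of {cluster!r} has zero total nuclei")
    ni = table.counts.loc[cluster].sum()
    return ni * nj / total


def _outer_groups(table: CompositionTable):
    """Yield (member cluster index, lobule totals N_j) per outer type."""
    for _, members in table.outer_type.groupby(table.outer_type, observed=True).groups.items():
        yield members, table.counts.loc[members].sum(axis=0).astype(float)


def composition_test(table: CompositionTable) -> pd.DataFrame:
    """Per-cluster Pearson chi-squared test against the outer composition.

    Lobules with zero expected count are dropped from the sum and the
    degrees of freedom reduced accordingly.  BH adjustment is applied across
    all clusters in the table.
    """
    out = pd.DataFrame(index=table.cluster_ids,
                       columns=["chi2", "df", "p"], dtype=float)
    for members, nj in _outer_groups(table):
        if len(members) == 1:
            log.info("cluster %s equals its entire outer type; test is degenerate",
                     members[0])
        frac = (nj / nj.sum()).to_numpy()
        obs = table.counts.loc[members].to_numpy(dtype=float)
        ni = obs.sum(axis=1, keepdims=True)
        exp = ni * frac[np.newaxis, :]
        keep = exp > 0
        dropped = obs[~keep].sum()
        if dropped:
            log.warning("%d nuclei fall in lobules with zero expectation", int(dropped))
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(keep, (obs - exp) ** 2 / np.where(keep, exp, 1.0), 0.0)
        chi2 = terms.sum(axis=1)
        df = keep.sum(axis=1) - 1
        p = np.where(df > 0, stats.chi2.sf(chi2, np.maximum(df, 1)), 1.0)
        out.loc[members, "chi2"] = chi2
        out.loc[members, "df"] = df
        out.loc[members, "p"] = p
    out["df"] = out["df"].astype(int)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out.index.name = "cluster"
    return out


def lobule_enrichment(table: CompositionTable) -> pd.DataFrame:
    """LE_ij matrix (clusters x lobules); NaN where the outer N_j is zero."""
    le = pd.DataFrame(index=table.cluster_ids, columns=table.lobule_ids, dtype=float)
    for members, nj in _outer_groups(table):
        outer_frac = (nj / nj.sum()).to_numpy()
        obs = table.counts.loc[members].to_numpy(dtype=float)
        cluster_frac = obs / obs.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            le.loc[members] = np.where(outer_frac > 0,
                                       cluster_frac / outer_frac, np.nan)
    return le


def split_replicate_sets(ann: CellAnnotation) -> pd.Series:
    """Assign each cell to replicate set 1 or 2 (or neither -> 0).

    Within each (outer type, lobule), the most represented replicate's
    nuclei form set 1 and the second most represented replicate's form
    set 2; further replicates are unused.  Ties are broken by replicate
    label order for determinism.
    """
    df = ann.table
    assignment = np.zeros(len(df), dtype=int)
    for (_, _), idx in df.groupby(["outer_type", "lobule"], observed=True).groups.items():
        sub = df.loc[idx]
        sizes = sub["replicate"].value_counts().sort_index()
        ranked = sizes.sort_values(ascending=False, kind="mergesort").index
        set1 = ranked[0]
        assignment[np.asarray(idx)[sub["replicate"].to_numpy() == set1]] = 1
        if len(ranked) > 1:
            set2 = ranked[1]
            assignment[np.asarray(idx)[sub["replicate"].to_numpy() == set2]] = 2
        else:
            log.info("single replicate in a region; it contributes to set 1 only")
    return pd.Series(assignment, index=df.index, name="replicate_set")


def replicate_consistency(ann: CellAnnotation) -> pd.Series:
    """Per-cluster Pearson r between LE vectors of the two replicate sets.

    Clusters represented in only one set are returned as NaN.
    """
    sets = split_replicate_sets(ann)
    les = {}
    for s in (1, 2):
        sub = ann.subset((sets == s).to_numpy())
        if len(sub) == 0:
            continue
        les[s] = lobule_enrichment(composition_table_from_annotation(sub))
    clusters = pd.unique(ann.table["cluster"])
    out = pd.Series(np.nan, index=pd.Index(clusters, name="cluster"), name="replicate_r")
    if len(les) < 2:
        return out
    for cluster in clusters:
        if cluster not in les[1].index or cluster not in les[2].index:
            log.info("cluster %s present in only one replicate set; r undefined", cluster)
            continue
        shared = les[1].columns.intersection(les[2].columns)
        a = les[1].loc[cluster, shared].to_numpy(dtype=float)
        b = les[2].loc[cluster, shared].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
            continue
        out[cluster] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return out


def downsample_outer_type(
    ann: CellAnnotation, outer_type: str, n_target: int, seed: int
) -> CellAnnotation:
    """Uniform random subset of one outer type to ``n_target`` cells.

    Used to keep a hugely abundant class (e.g. granule cells, downsampled to
    60,000 in the reference analysis) from dominating composition tests.
    """
    mask = (ann.table["outer_type"] == outer_type).to_numpy()
    n_have = int(mask.sum())
    if n_target > n_have:
        raise ValidationError(
            f"cannot downsample {outer_type!r} to {n_target}: only {n_have} cells"
        )
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(mask)
    keep_idx = rng.choice(idx, size=n_target, replace=False)
    keep = ~mask
    keep[keep_idx] = True
    return ann.subset(keep)


def label_clusters(
    results: pd.DataFrame, q_max: float = 0.001, min_max_le: float = 2.0,
    min_r: float = 0.85
) -> pd.Series:
    """Spatially significant label: q < q_max AND max LE > min_max_le AND
    replicate r > min_r (all strict; undefined r means unlabeled)."""
    r = results["replicate_r"]
    undefined = r.isna()
    if undefined.any():
        log.info("%d clusters with undefined replicate r left unlabeled", int(undefined.sum()))
    return (
        (results["q"] < q_max)
        & (results["max_le"] > min_max_le)
        & (r > min_r)
    ).fillna(False).rename("labeled")


def analyze_composition(
    ann: CellAnnotation,
    downsample: tuple[str, int] | None = None,
    seed: int = 0,
    q_max: float = 0.001,
    min_max_le: float = 2.0,
    min_r: float = 0.85,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full composition analysis: test, enrichment, replicate r, labels.

    Returns (per-cluster results, LE matrix).  Downsampling of one outer
    type, if requested, happens before both testing and replicate analysis.
    """
    if downsample is not None:
        outer, n_target = downsample
        ann = downsample_outer_type(ann, outer, n_target, seed)
    table = composition_table_from_annotation(ann)
    res = composition_test(table)
    le = lobule_enrichment(table)
    res["max_le"] = le.max(axis=1, skipna=True)
    with np.errstate(divide="ignore"):
        res["log2_max_le"] = np.log2(res["max_le"])
        res["neg_log10_q"] = -np.log10(res["q"])
    res["replicate_r"] = replicate_consistency(ann).reindex(res.index)
    res["labeled"] = label_clusters(res, q_max, min_max_le, min_r)
    res.insert(0, "outer_type", table.outer_type.reindex(res.index))
    return res, le
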