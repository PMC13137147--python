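"""Segment-level expression analysis: variable-gene selection, graph-based
clustering into inflamed/non-inflamed groups, mixed-model differential
expression, single-sample GSEA, differential pathway selection, and
majority-vote sample classification.

The differential model is a linear mixed model per feature,
``expression ~ group`` with a random intercept per sample, fit by REML;
inference is a Wald z test on the group coefficient with Benjamini-Hochberg
correction across features.  The random intercept absorbs the correlation
between the multiple segments profiled per tumor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .graph import snn_graph, louvain_fixed_k
from .stats import bh_adjust, student_t_unpaired

#: immune genes used to name the inflamed cluster (post-hoc labeling is by
#: higher mean expression of these markers); configurable per call.
DEFAULT_IMMUNE_MARKERS = ("B2M", "HLA-A", "HLA-B", "HLA-E", "C1S", "C1R", "TRAC")


@dataclass
class ClusterAssignment:
    """Two-way segment clustering with inflamed/non-inflamed naming."""

    segment_cluster: pd.Series           # segment -> {0, 1}
    cluster_label: dict                  # {0,1} -> inflamed / non-inflamed
    resolution: float

    @property
    def segment_label(self) -> pd.Series:
        return self.segment_cluster.map(self.cluster_label)


def select_variable_genes(expr: pd.DataFrame, frac: float = 0.20) -> list[str]:
    """Top ``floor(frac * G)`` genes by variance of log2 expression across
    segments (descending; ties broken by stable gene order)."""
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    if expr.shape[1] < 2:
        raise ValueError("need >=2 segments to rank variances")
    n = int(np.floor(frac * expr.shape[0]))
    var = expr.var(axis=1, ddof=1).values
    order = np.argsort(-var, kind="stable")
    return [expr.index[i] for i in order[:n]]


def cluster_segments(
    expr: pd.DataFrame,
    k_target: int = 2,
    seed: int = 0,
    markers=DEFAULT_IMMUNE_MARKERS,
    k_neighbors: int | None = None,
) -> ClusterAssignment:
    """Cluster segments (columns) on a shared-nearest-neighbour graph with
    Louvain, binary-searching the resolution to exactly ``k_target``
    communities, then name the cluster with the higher mean marker
    expression "inflamed"."""
    n = expr.shape[1]
    if n < k_target:
        raise ValueError("fewer segments than target clusters")
    X = expr.values.T
    k = k_neighbors if k_neighbors is not None else min(10, n - 1)
    g = snn_graph(X, k)
    member, res = louvain_fixed_k(g, k_target, seed=seed)
    clusters = pd.Series(member, index=expr.columns, name="cluster")

    labels: dict = {c: str(c) for c in np.unique(member)}
    if k_target == 2:
        present = [m for m in markers if m in expr.index]
        score_rows = expr.loc[present] if present else expr
        means = {c: score_rows.loc[:, clusters == c].values.mean() for c in (0, 1)}
        hot = max(means, key=means.get)
        labels = {hot: "inflamed", 1 - hot: "non-inflamed"}
    return ClusterAssignment(clusters, labels, res)


def embed_umap(expr: pd.DataFrame, seed: int = 0, n_neighbors: int = 10) -> pd.DataFrame:
    """2-D UMAP embedding of segments (reporting only; clustering never
    depends on it).  Deterministic for a fixed seed."""
    import umap

    n = expr.shape[1]
    if n < 3:
        raise ValueError("need >=3 segments to embed")
    emb = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        random_state=seed,
    ).fit_transform(expr.values.T)
    return pd.DataFrame(emb, index=expr.columns, columns=["UMAP1", "UMAP2"])


def _fit_one_lmm(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """REML random-intercept fit; returns (coef, se, used_ols_fallback)."""
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            res = MixedLM(y, X, groups=groups).fit(reml=True)
            coef, se = res.params[1], res.bse[1]
            if np.isfinite(coef) and np.isfinite(se) and se > 0:
                return float(coef), float(se), False
        except (np.linalg.LinAlgError, ValueError):
            pass
    ols = sm.OLS(y, X).fit()
    return float(ols.params[1]), float(ols.bse[1]), True


def lmm_de(
    expr: pd.DataFrame, group: pd.Series, sample_id: pd.Series
) -> pd.DataFrame:
    """Per-feature mixed-model differential expression.

    ``group`` and ``sample_id`` are per-segment factors aligned with the
    expression columns.  The contrast is group2 - group1 on the log2 scale
    (groups in sorted order).  Returns a DataFrame with columns
    feature, log2FC, p, q, ols_fallback.
    """
    segs = list(expr.columns)
    group = group.loc[segs]
    sample_id = sample_id.loc[segs]
    levels = sorted(group.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    if sample_id.nunique() < 2:
        raise ValueError("need >=2 samples")
    x = (group == levels[1]).astype(float).values
    groups = sample_id.values

    rows = []
    for feat in expr.index:
        y = expr.loc[feat].values.astype(float)
        if np.allclose(y, y[0]):
            rows.append((feat, 0.0, 1.0, False))
            continue
        coef, se, fallback = _fit_one_lmm(y, x, groups)
        z = coef / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((feat, coef, max(min(p, 1.0), np.finfo(float).tiny), fallback))
    out = pd.DataFrame(rows, columns=["feature", "log2FC", "p", "ols_fallback"])
    out["q"] = bh_adjust(out["p"].values)
    return out[["feature", "log2FC", "p", "q", "ols_fallback"]]


# ---------------------------------------------------------------------------
# single-sample GSEA
# ---------------------------------------------------------------------------


def _ssgsea_one(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """ssGSEA enrichment score for one sample.

    Genes are ranked by expression, descending, ties broken by stable input
    order; the score is the summed difference between the weighted ECDF of
    in-set genes (weights |rank statistic|^alpha, rank statistic = rank
    position from the bottom) and the unweighted ECDF of out-of-set genes.
    """
    n = values.size
    order = np.argsort(-values, kind="stable")
    ranks = np.arange(n, 0, -1, dtype=float)          # rank stat along sorted order
    inset_sorted = in_set[order]
    w = np.where(inset_sorted, np.abs(ranks) ** alpha, 0.0)
    denom_in = w.sum()
    n_out = n - int(in_set.sum())
    if denom_in == 0 or n_out == 0:
        raise ValueError("gene set empty or spans the whole universe")
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(~inset_sorted) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(
    expr: pd.DataFrame, sets: dict[str, list[str]], alpha: float = 0.25
) -> pd.DataFrame:
    """ssGSEA score matrix (pathways x segments).

    Gene sets are intersected with the expression universe; empty
    intersections are dropped with a warning.
    """
    universe = list(expr.index)
    pos = {g: i for i, g in enumerate(universe)}
    rows, names = [], []
    for name, members in sets.items():
        idx = [pos[g] for g in members if g in pos]
        if not idx:
            warnings.warn(f"gene set {name!r} has no genes in the matrix; dropped")
            continue
        mask = np.zeros(len(universe), bool)
        mask[idx] = True
        scores = [
            _ssgsea_one(expr[seg].values.astype(float), mask, alpha)
            for seg in expr.columns
        ]
        rows.append(scores)
        names.append(name)
    return pd.DataFrame(rows, index=names, columns=expr.columns)


def differential_pathways(
    scores: pd.DataFrame,
    group: pd.Series,
    sample_id: pd.Series,
    top_frac: float = 0.10,
    rank_by: str = "q",
) -> pd.DataFrame:
    """Mixed-model differential enrichment on pathway scores; returns the
    top ``floor(top_frac * P)`` pathways ranked by adjusted p ascending
    (ties broken by |effect| descending), or by |effect| when
    ``rank_by='effect'``."""
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    de = lmm_de(scores, group, sample_id)
    n = int(np.floor(top_frac * len(de)))
    de = de.assign(abs_effect=de["log2FC"].abs())
    if rank_by == "q":
        de = de.sort_values(["q", "abs_effect"], ascending=[True, False], kind="stable")
    elif rank_by == "effect":
        de = de.sort_values("abs_effect", ascending=False, kind="stable")
    else:
        raise ValueError("rank_by must be 'q' or 'effect'")
    return de.head(n).drop(columns="abs_effect").reset_index(drop=True)


def classify_samples(
    assignment: ClusterAssignment, sample_id: pd.Series
) -> pd.Series:
    """Per-sample majority vote over its segments' cluster labels; exact
    ties are reported as 'tied'."""
    seg_label = assignment.segment_label
    out = {}
    for sample, segs in sample_id.groupby(sample_id).groups.items():
        labels = seg_label.loc[list(segs)]
        if labels.empty:
            raise ValueError(f"sample {sample} has no segments")
        counts = labels.value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            out[sample] = "tied"
        else:
            out[sample] = counts.index[0]
    return pd.Series(out, name="sample_label")


def compare_segment_features(values: pd.Series, group: pd.Series) -> tuple[float, float]:
    """Unpaired two-sided Student t test on a per-segment feature (nuclei
    count, detected-gene count, ...) between two groups."""
    levels = sorted(group.unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    a = values[group == levels[0]].values
    b = values[group == levels[1]].values
    return student_t_unpaired(a, b)
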