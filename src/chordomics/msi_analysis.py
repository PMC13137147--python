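"""Region-level MSI analysis: artifact-pixel exclusion, Louvain pixel
clustering, cluster-to-region assignment against a histology stand-in
mask, per-sample region means, and the two differential abundance
contrasts (paired tumor vs stroma with BH correction; unpaired inflamed
vs non-inflamed on raw p-values)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .graph import snn_graph, louvain
from .stats import bh_adjust, student_t_paired, student_t_unpaired

__all__ = [
    "exclude_artifact_pixels",
    "cluster_pixels",
    "assign_regions",
    "region_means",
    "diff_tumor_vs_stroma",
    "diff_inflamed_vs_noninflamed",
]


def exclude_artifact_pixels(
    matrix: pd.DataFrame,
    tic: np.ndarray,
    k: int = 5,
    seed: int = 0,
    tic_frac: float = 0.2,
) -> pd.Index:
    """Drop hole/necrosis-like pixels: k-means on the normalized profiles,
    then exclude clusters whose mean raw TIC falls below ``tic_frac`` times
    the median cluster TIC.  Returns the retained pixel index."""
    tic = np.asarray(tic, dtype=float)
    if tic.size != matrix.shape[0]:
        raise ValueError("tic length must match pixel count")
    k = min(k, matrix.shape[0])
    km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(matrix.values)
    cluster_tic = np.array([tic[km.labels_ == c].mean() for c in range(k)])
    cutoff = tic_frac * np.median(cluster_tic)
    bad = np.flatnonzero(cluster_tic < cutoff)
    keep = ~np.isin(km.labels_, bad)
    if not keep.any():
        raise ValueError("all pixel clusters excluded as artifacts")
    return matrix.index[keep]


def cluster_pixels(
    matrix: pd.DataFrame,
    seed: int = 0,
    k_neighbors: int = 15,
    resolution: float = 1.0,
) -> pd.Series:
    """Louvain communities of pixels on a shared-nearest-neighbour graph of
    log1p-transformed normalized intensities (default resolution 1.0; the
    community count is data-driven, not forced)."""
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need >=2 pixels")
    X = np.log1p(matrix.values)
    if np.allclose(X, X[0]):
        return pd.Series(np.zeros(n, int), index=matrix.index, name="cluster")
    k = min(k_neighbors, n - 1)
    g = snn_graph(X, k)
    member = louvain(g, resolution=resolution, seed=seed)
    return pd.Series(member, index=matrix.index, name="cluster")


def assign_regions(
    clusters: pd.Series, region_reference: pd.Series
) -> tuple[pd.Series, dict]:
    """Label each pixel cluster tumor/stroma by majority vote over the
    labeled reference subset (the histology stand-in); clusters with no
    labeled overlap are 'excluded'.  Returns per-pixel region labels and
    the cluster -> label map."""
    ref = region_reference.dropna()
    ref = ref[ref != ""]
    if ref.empty:
        raise ValueError("empty region reference")
    mapping = {}
    for c in sorted(clusters.unique()):
        members = clusters.index[clusters == c]
        overlap = ref.reindex(members).dropna()
        if overlap.empty:
            mapping[c] = "excluded"
        else:
            mapping[c] = overlap.value_counts().index[0]
    return clusters.map(mapping).rename("region"), mapping


def region_means(
    matrix: pd.DataFrame, sample_id: pd.Series, region: pd.Series
) -> pd.DataFrame:
    """Mean intensity per peak over each (sample, region) pixel set.

    Returns a DataFrame indexed by (sample_id, region) with peak columns;
    'excluded' and unlabeled pixels are ignored, empty combinations are
    simply absent.
    """
    keep = region.isin(["tumor", "stroma"])
    if not keep.any():
        warnings.warn("no tumor/stroma pixels; empty region-mean table")
        return pd.DataFrame(columns=matrix.columns)
    sub = matrix.loc[keep[keep].index]
    out = sub.groupby(
        [sample_id.reindex(sub.index).values, region.reindex(sub.index).values]
    ).mean()
    out.index = out.index.set_names(["sample_id", "region"])
    return out.sort_index()


def diff_tumor_vs_stroma(table: pd.DataFrame) -> pd.DataFrame:
    """Paired Student t test (tumor vs stroma per sample) per peak, BH
    corrected; log2FC of the grand region means (tumor over stroma)."""
    wide_t = table.xs("tumor", level="region")
    wide_s = table.xs("stroma", level="region")
    common = wide_t.index.intersection(wide_s.index)
    if len(common) < 2:
        raise ValueError("need >=2 samples with both regions for pairing")
    wide_t, wide_s = wide_t.loc[common], wide_s.loc[common]
    rows = []
    for peak in table.columns:
        t, p = student_t_paired(wide_t[peak].values, wide_s[peak].values)
        mt, ms = wide_t[peak].mean(), wide_s[peak].mean()
        lfc = np.log2(mt / ms) if mt > 0 and ms > 0 else np.nan
        rows.append((peak, lfc, t, p))
    out = pd.DataFrame(rows, columns=["peak", "log2FC", "t", "p"])
    out["q"] = bh_adjust(out["p"].values)
    return out


def diff_inflamed_vs_noninflamed(
    table: pd.DataFrame, sample_inflamed: pd.Series, region: str
) -> pd.DataFrame:
    """Unpaired Student t test per peak between inflamed and non-inflamed
    samples within one region; raw p only (no multiple-testing column)."""
    sub = table.xs(region, level="region")
    labels = sample_inflamed.reindex(sub.index)
    grp_in = sub[labels.astype(bool)]
    grp_out = sub[~labels.astype(bool)]
    if len(grp_in) < 2 or len(grp_out) < 2:
        raise ValueError("need >=2 samples per inflammation group")
    rows = []
    for peak in table.columns:
        t, p = student_t_unpaired(grp_in[peak].values, grp_out[peak].values)
        mi, mo = grp_in[peak].mean(), grp_out[peak].mean()
        lfc = np.log2(mi / mo) if mi > 0 and mo > 0 else np.nan
        rows.append((peak, lfc, t, p))
    return pd.DataFrame(rows, columns=["peak", "log2FC", "t", "p"])
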