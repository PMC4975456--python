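"""Molecular subtyping: variable-gene PCA + K-means and cluster naming.

Tumors are clustered on the top-variance genes (500 by default) of the
normalized-log matrix, embedded with PCA and partitioned with K-means
(K = 3): the expression-defined BRAF-like / RAS-like / NBNR subtypes.
Clusters are named by the plurality driver class of their members.

Lymphocytic thyroiditis injects a strong immunoglobulin signal that can
dominate the variance ranking and hijack the clustering; the gene universe
passed through ``exclude`` exists precisely to strip such confounder panels
before selecting variable genes.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .expr_core import DataError, ExpressionMatrix

logger = logging.getLogger("thyrotype")

SUBTYPE_LABELS = ("BRAF-like", "RAS-like", "NBNR")


@dataclass
class SubtypeResult:
    clusters: pd.Series      # sample -> cluster id
    labels: pd.Series        # sample -> subtype label (or 'unassigned')
    embedding: pd.DataFrame  # sample x PC coordinates
    genes_used: list
    k: int
    seed: int


def select_variable_genes(
    m: ExpressionMatrix, n: int = 500, exclude=None
) -> list:
    """Top-*n* genes by variance across samples, after removing *exclude*.

    Ties are broken by lexicographic gene id so the selection is total-order
    deterministic.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    excl = set(exclude) if exclude is not None else set()
    keep = [g for g in m.gene_ids if g not in excl]
    var = m.values.loc[keep].var(axis=1, ddof=1)
    order = sorted(keep, key=lambda g: (-var[g], g))
    return order[: min(n, len(order))]


def pca_embed(m: ExpressionMatrix, n_components: int = 2) -> pd.DataFrame:
    """PCA embedding of samples; genes are mean-centered, not scaled.

    Components are ordered by explained variance; each component's sign is
    fixed so that its largest-magnitude gene loading is positive.
    """
    x = m.values.to_numpy(dtype=float).T  # samples x genes
    if n_components > min(x.shape):
        raise DataError(
            f"n_components={n_components} exceeds min(genes, samples)={min(x.shape)}"
        )
    if np.allclose(x.var(axis=0), 0.0):
        raise DataError("zero-variance input; nothing to embed")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x)
    # deterministic sign: largest-|loading| positive per component
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1.0
    return pd.DataFrame(
        coords,
        index=m.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )


def kmeans_subtypes(
    embedding: pd.DataFrame, k: int = 3, seed: int = 0, restarts: int = 50
) -> pd.Series:
    """Best-inertia K-means over *restarts* k-means++ initializations."""
    if k > len(embedding):
        raise DataError(f"K={k} exceeds number of samples ({len(embedding)})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    ids = km.fit_predict(embedding.to_numpy(dtype=float))
    return pd.Series(ids, index=embedding.index, name="cluster")


def label_clusters(clusters: pd.Series, driver_class: pd.Series) -> pd.Series:
    """Name clusters by plurality driver class.

    The cluster holding the plurality of BRAF-class drivers becomes
    BRAF-like; plurality of RAS-class becomes RAS-like; remaining clusters
    are NBNR. A tie for a name leaves the contested clusters unassigned,
    with a warning.
    """
    labels = {}
    counts = {
        c: Counter(driver_class.loc[clusters.index[clusters == c]])
        for c in sorted(clusters.unique())
    }
    for cls, name in (("BRAF-class", "BRAF-like"), ("RAS-class", "RAS-like")):
        per_cluster = {c: cnt.get(cls, 0) for c, cnt in counts.items() if c not in labels}
        if not per_cluster or max(per_cluster.values()) == 0:
            continue
        best = max(per_cluster.values())
        winners = [c for c, v in per_cluster.items() if v == best]
        if len(winners) > 1:
            warnings.warn(
                f"tie between clusters {winners} for {name}; leaving unassigned",
                stacklevel=2,
            )
            for c in winners:
                labels[c] = "unassigned"
        else:
            labels[winners[0]] = name
    for c in counts:
        labels.setdefault(c, "NBNR")
    return clusters.map(labels).rename("subtype")


def subtype_cohort(
    m: ExpressionMatrix,
    driver_class: pd.Series,
    n_genes: int = 500,
    exclude=None,
    k: int = 3,
    n_components: int = 2,
    seed: int = 0,
    restarts: int = 50,
) -> SubtypeResult:
    """Full subtyping pass: variable genes -> PCA -> K-means -> naming."""
    samples = list(driver_class.index)
    sub = m.subset_samples(samples)
    genes = select_variable_genes(sub, n=n_genes, exclude=exclude)
    emb = pca_embed(sub.subset_genes(genes), n_components=n_components)
    clusters = kmeans_subtypes(emb, k=k, seed=seed, restarts=restarts)
    labels = label_clusters(clusters, driver_class)
    return SubtypeResult(
        clusters=clusters, labels=labels, embedding=emb,
        genes_used=genes, k=k, seed=seed,
    )


def subtype_recovery_ari(labels: pd.Series, truth: pd.Series) -> float:
    """Adjusted Rand index between called and true subtype partitions."""
    common = labels.index.intersection(truth.index)
    return float(adjusted_rand_score(truth.loc[common], labels.loc[common]))


def aggressiveness_table(labels: pd.Series, flags: pd.Series) -> dict:
    """Per-subtype frequency of a binary pathology flag (LNM or ETE).

    Returns the frequency table plus an omnibus association p-value:
    chi-square, or Fisher's exact test on 2x2 tables when any expected
    count is below 5 (larger tables fall back to chi-square with a
    warning).
    """
    from .cohort_report import _omnibus

    common = labels.index.intersection(flags.index)
    lab, fl = labels.loc[common], flags.loc[common].astype(bool)
    tab = pd.crosstab(lab, fl).reindex(columns=[True, False], fill_value=0)
    freq = pd.DataFrame(
        {
            "n_pos": tab[True],
            "n_total": tab.sum(axis=1),
        }
    )
    freq["percent"] = 100.0 * freq["n_pos"] / freq["n_total"]
    test, p = _omnibus(tab.to_numpy())
    return {"table": freq, "test": test, "p": p}
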