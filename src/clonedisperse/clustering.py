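"""Mutation clustering into putative clones by joint CCF profiles.

Mutations are clustered on their per-sample CCF vectors with a diagonal
Gaussian mixture; the number of components is selected by BIC over
``k = 1..k_max``.  This is a deterministic surrogate for Dirichlet-process
binomial clustering: at several-hundred-fold depth the CCF noise of a
mutation is close to Gaussian, and a seeded mixture fit gives reproducible
desk-scale results.  Mutations absent from a sample are imputed as CCF 0 --
at this depth, absence of supporting reads is strong evidence of prevalence
zero rather than missingness.

Clusters below the minimum size (default 3, the minimum mutation cluster
size used for clone detection) are merged into the nearest center when one
is close in max-norm, otherwise their members are dropped.  Near-duplicate
centers are merged so overfitted splits of one clone collapse back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

DEFAULT_MIN_CLUSTER_SIZE = 3
DEFAULT_K_MAX = 12
DEFAULT_MERGE_DISTANCE = 0.10
DEFAULT_DUPLICATE_MERGE_DISTANCE = 0.06


@dataclass
class MutationCluster:
    cluster_id: int
    members: tuple[str, ...]
    center: pd.Series
    size: int


def mean_cluster_prevalence(cluster: MutationCluster) -> pd.Series:
    """Per-sample mean CCF of the cluster, clipped to [0, 1]."""
    return cluster.center.clip(0.0, 1.0)


def _maxnorm(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.abs(a - b).max())


def cluster_mutations(
    ccf_matrix: pd.DataFrame,
    k_max: int = DEFAULT_K_MAX,
    seed: int = 0,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    merge_distance: float = DEFAULT_MERGE_DISTANCE,
    duplicate_merge_distance: float = DEFAULT_DUPLICATE_MERGE_DISTANCE,
    n_init: int = 2,
) -> tuple[list[MutationCluster], list[str]]:
    """Cluster mutations by joint CCF profile.

    Parameters
    ----------
    ccf_matrix
        Rows: mutation keys; columns: samples; entries: CCF (NaN = absent,
        imputed as 0).  Rows are sorted internally, so the result does not
        depend on input ordering.

    Returns
    -------
    (clusters, dropped)
        Clusters sorted by decreasing mean prevalence, and the keys of
        mutations dropped from undersized, unmergeable clusters.
    """
    matrix = ccf_matrix.sort_index()
    X = matrix.fillna(0.0).to_numpy(float)
    keys = list(matrix.index)
    n = len(keys)
    if n == 0:
        raise ValueError("empty CCF matrix")
    if n < min_cluster_size:
        warnings.warn(
            f"only {n} mutations; returning a single cluster", stacklevel=2)
        center = pd.Series(X.mean(axis=0), index=matrix.columns)
        return [MutationCluster(0, tuple(keys), center, n)], []

    n_unique = len(np.unique(X.round(9), axis=0))
    ks = range(1, min(k_max, n_unique, n) + 1)
    best_k, best_bic, best_model = 1, np.inf, None
    for k in ks:
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", reg_covar=1e-6,
            random_state=int(seed) % (2**32), n_init=n_init, max_iter=300,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
            bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best_k, best_bic, best_model = k, bic, gm
    labels = best_model.predict(X)

    # Collapse near-duplicate centers (overfitted splits of one clone).
    centers = {lab: X[labels == lab].mean(axis=0) for lab in np.unique(labels)}
    merged = True
    while merged:
        merged = False
        labs = sorted(centers)
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                if _maxnorm(centers[a], centers[b]) < duplicate_merge_distance:
                    labels[labels == b] = a
                    centers[a] = X[labels == a].mean(axis=0)
                    del centers[b]
                    merged = True
                    break
            if merged:
                break

    # Undersized clusters: merge into a close center, otherwise drop.
    dropped: list[str] = []
    changed = True
    while changed:
        changed = False
        sizes = {lab: int((labels == lab).sum()) for lab in centers}
        small = [lab for lab, s in sizes.items() if s < min_cluster_size]
        if not small:
            break
        lab = min(small, key=lambda l: sizes[l])
        others = [l for l in centers if l != lab]
        if others:
            nearest = min(others, key=lambda l: _maxnorm(centers[l], centers[lab]))
            if _maxnorm(centers[nearest], centers[lab]) < merge_distance:
                labels[labels == lab] = nearest
                centers[nearest] = X[labels == nearest].mean(axis=0)
                del centers[lab]
                changed = True
                continue
        dropped.extend(keys[i] for i in np.flatnonzero(labels == lab))
        labels[labels == lab] = -1
        del centers[lab]
        changed = True

    clusters = []
    for lab in centers:
        idx = np.flatnonzero(labels == lab)
        center = pd.Series(X[idx].mean(axis=0), index=matrix.columns)
        clusters.append((center.sum(), tuple(keys[i] for i in idx), center))
    clusters.sort(key=lambda t: (-t[0], t[1]))
    out = [
        MutationCluster(i, members, center, len(members))
        for i, (_, members, center) in enumerate(clusters)
    ]
    if not out:
        # Everything was undersized; fall back to one cluster of all input.
        warnings.warn("all clusters undersized; single-cluster fallback",
                      stacklevel=2)
        center = pd.Series(X.mean(axis=0), index=matrix.columns)
        return [MutationCluster(0, tuple(keys), center, n)], []
    return out, sorted(dropped)


def ccf_matrix_from_table(ccf_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long CCF table to the mutation-by-sample matrix."""
    return ccf_table.pivot_table(index="key", columns="sample", values="ccf",
                                 aggfunc="first")
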