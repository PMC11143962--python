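"""Clone-tree enumeration under the sum (pigeonhole) rule and model selection.

Given cluster prevalences, every rooted tree over the clusters is returned
for which (a) each parent's prevalence is at least each child's in every
sample, and (b) in every sample the prevalences of a node's children sum to
at most the node's own prevalence -- both within a configurable tolerance
that absorbs estimation noise.  Enumeration is exhaustive with pruning for
up to 9 clusters (the realistic clone range); larger problems fall back to
a greedy best-parent construction with a warning.

Among the enumerated trees, the least complex and most parsimonious model
is selected: fewer branching nodes first (linear over branched evolution),
then fewer implied disseminated clones (dissemination of a single clone
over multiple), with a deterministic lexicographic tie-break.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .core import CloneTree, ModelFailureError

DEFAULT_TOLERANCE = 0.05
DEFAULT_ROOT_THRESHOLD = 0.9
MAX_EXHAUSTIVE_NODES = 9


def find_root_cluster(
    prevalence: pd.DataFrame, root_threshold: float = DEFAULT_ROOT_THRESHOLD
):
    """The cluster with prevalence ~1 in every sample (the truncal clone).

    Raises :class:`ModelFailureError` naming the closest candidate when no
    cluster qualifies.
    """
    mins = prevalence.min(axis=1)
    qualifying = mins[mins >= root_threshold]
    if qualifying.empty:
        closest = mins.idxmax()
        raise ModelFailureError(
            f"no cluster has prevalence >= {root_threshold} in all samples; "
            f"closest candidate is {closest!r} (min prevalence {mins.max():.3f})"
        )
    return prevalence.loc[qualifying.index].mean(axis=1).idxmax()


def enumerate_trees(
    prevalence: pd.DataFrame,
    mutations: Optional[Mapping] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    root_threshold: float = DEFAULT_ROOT_THRESHOLD,
    max_exhaustive: int = MAX_EXHAUSTIVE_NODES,
) -> list[CloneTree]:
    """All rooted trees over the clusters consistent with the sum rule.

    Parameters
    ----------
    prevalence
        Cluster-by-sample prevalence matrix in [0, 1].
    mutations
        Optional cluster -> mutation-key mapping attached to each tree.

    Returns an empty list when a root exists but no consistent tree does.
    """
    nodes = sorted(prevalence.index, key=str)
    root = find_root_cluster(prevalence, root_threshold)
    if len(nodes) == 1:
        return [CloneTree({root: None}, _muts(mutations, nodes), prevalence)]
    if len(nodes) > max_exhaustive:
        warnings.warn(
            f"{len(nodes)} clusters exceed the exhaustive enumeration bound "
            f"({max_exhaustive}); using greedy construction", stacklevel=2)
        tree = greedy_tree(prevalence, mutations, tolerance, root_threshold)
        return [tree]

    P = prevalence.loc[nodes].to_numpy(float)
    n = len(nodes)
    ridx = nodes.index(root)
    others = [i for i in range(n) if i != ridx]

    candidates = {
        u: [v for v in range(n)
            if v != u and np.all(P[v] >= P[u] - tolerance)]
        for u in others
    }
    if any(not c for c in candidates.values()):
        return []

    results: list[dict] = []
    parent = {ridx: None}
    child_sum = np.zeros((n, P.shape[1]))

    def rec(pos: int) -> None:
        if pos == len(others):
            results.append(dict(parent))
            return
        u = others[pos]
        for v in candidates[u]:
            new_sum = child_sum[v] + P[u]
            if np.any(new_sum > P[v] + tolerance + 1e-12):
                continue
            parent[u] = v
            child_sum[v] = new_sum
            rec(pos + 1)
            child_sum[v] = child_sum[v] - P[u]
            del parent[u]

    rec(0)

    trees = []
    for pmap in results:
        if not _is_rooted_tree(pmap, ridx):
            continue
        named = {nodes[u]: (None if p is None else nodes[p])
                 for u, p in pmap.items()}
        trees.append(CloneTree(named, _muts(mutations, nodes), prevalence))
    return trees


def _muts(mutations: Optional[Mapping], nodes: Iterable) -> dict:
    if mutations is None:
        return {}
    return {u: mutations.get(u, ()) for u in nodes}


def _is_rooted_tree(parent: dict, root: int) -> bool:
    for u in parent:
        seen = {u}
        v = parent[u]
        while v is not None:
            if v in seen:
                return False
            seen.add(v)
            v = parent[v]
    return True


def greedy_tree(
    prevalence: pd.DataFrame,
    mutations: Optional[Mapping] = None,
    tolerance: float = DEFAULT_TOLERANCE,
    root_threshold: float = DEFAULT_ROOT_THRESHOLD,
) -> CloneTree:
    """Best-parent construction: always yields one tree, minimizing the
    total sum-rule excess when perfect consistency is impossible."""
    nodes = sorted(prevalence.index, key=str)
    root = find_root_cluster(prevalence, root_threshold)
    order = sorted(
        (u for u in nodes if u != root),
        key=lambda u: (-float(prevalence.loc[u].mean()), str(u)),
    )
    parent = {root: None}
    child_sum = {u: np.zeros(prevalence.shape[1]) for u in nodes}
    for u in order:
        pu = prevalence.loc[u].to_numpy(float)
        best, best_cost = None, np.inf
        for v in parent:  # only already-placed nodes are candidate parents
            pv = prevalence.loc[v].to_numpy(float)
            dom = np.maximum(pu - pv - tolerance, 0).sum()
            excess = np.maximum(child_sum[v] + pu - pv - tolerance, 0).sum()
            cost = dom + excess
            if cost < best_cost - 1e-12:
                best, best_cost = v, cost
        parent[u] = best
        child_sum[best] = child_sum[best] + pu
    return CloneTree(parent, _muts(mutations, nodes), prevalence)


def select_model(
    trees: list[CloneTree],
    dissemination_count: Optional[Callable[[CloneTree], int]] = None,
) -> tuple[CloneTree, list[CloneTree]]:
    """Pick the most parsimonious tree; also return the full ranking.

    Ranking: fewer branching nodes, then fewer implied disseminated clones
    (when a counter is supplied), then a lexicographic tie-break on the
    canonical parent map so the choice is deterministic.
    """
    if not trees:
        raise ModelFailureError("no sum-rule-consistent clone tree")

    def key(t: CloneTree):
        d = dissemination_count(t) if dissemination_count is not None else 0
        return (t.n_branching, d, t.parent_map_key())

    ranked = sorted(trees, key=key)
    return ranked[0], ranked


def relative_clone_time(tree: CloneTree) -> dict:
    """Per-clone cumulative mutation fraction of the whole model.

    The value for a clone is the number of mutations on its root lineage
    (inherited plus private) divided by the total mutations in the model.
    """
    total = tree.total_mutations
    if total == 0:
        return {u: 0.0 for u in tree.nodes}
    return {u: tree.cumulative_count(u) / total for u in tree.nodes}
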