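"""Scoring helpers: match inferred clones to simulated truth.

Used by the recovery tests and the reproduction script to ask whether the
pipeline recovered the generating dissemination mode and the true seeding
directions.  Inferred clusters are matched to truth clones by maximal
overlap of their private mutation sets.
"""

from __future__ import annotations

from typing import Optional

from .core import CloneTree
from .dissemination import DisseminationReport, UNDETERMINED
from .simdata import SimulatedPatient


def match_clones(truth_tree: CloneTree, inferred_tree: CloneTree) -> dict:
    """Map truth clone -> inferred clone with the largest mutation overlap.

    Truth clones whose mutations were not recovered map to ``None``.
    """
    out = {}
    for u in truth_tree.nodes:
        target = truth_tree.mutations[u]
        best, best_overlap = None, 0
        for v in inferred_tree.nodes:
            overlap = len(target & inferred_tree.mutations[v])
            if overlap > best_overlap:
                best, best_overlap = v, overlap
        out[u] = best
    return out


def mode_recovered(patient: SimulatedPatient, report: DisseminationReport) -> bool:
    return report.mode == patient.truth.mode


def direction_calls(
    patient: SimulatedPatient,
    report: DisseminationReport,
    inferred_tree: CloneTree,
    max_origin_ratio: Optional[float] = None,
) -> list[tuple[str, Optional[str]]]:
    """(true origin, inferred origin) pairs for scorable disseminated clones.

    A truth clone is scorable when it has a defined origin site and, if
    ``max_origin_ratio`` is given, its simulated origin-site prevalence is
    at most that fraction of its largest destination prevalence.
    """
    truth = patient.truth
    tree = truth.tree
    site_of = patient.panel.site_of
    site_prev = tree.prevalence.T.groupby(
        tree.prevalence.columns.map(site_of)).mean().T
    mapping = match_clones(tree, inferred_tree)
    pairs = []
    for u in sorted(truth.disseminated, key=str):
        origin = truth.origin_site.get(u)
        if origin is None:
            continue
        row = site_prev.loc[u]
        dest = row.drop(origin).max()
        if max_origin_ratio is not None and row[origin] > max_origin_ratio * dest:
            continue
        v = mapping.get(u)
        inferred = report.directions.get(str(v)) if v is not None else None
        if inferred == UNDETERMINED:
            inferred = None
        pairs.append((origin, inferred))
    return pairs
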