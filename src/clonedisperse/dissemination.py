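"""Dissemination-mode classification, seeding direction, and mutation timing.

Clone designation follows the prevalence-based rules of multi-site clonal
ordering: the root of the selected tree is the *initial* (truncal) clone;
non-root clones present at two or more anatomical sites are *disseminated*;
clones confined to a single site are *local*.  When no subclone is shared
across sites, the initial clone itself is the disseminated clone
(seeding predated subclonal diversification).

Modes partition every cancer with at least one disseminated clone:

* monoclonal -- exactly one disseminated clone;
* monophyletic polyclonal -- several disseminated clones, all on one
  root-to-leaf lineage;
* polyphyletic polyclonal -- at least two disseminated clones on branched,
  mutually non-ancestral lineages.

Seeding direction uses the smallest-prevalence rule: among the sites where
a disseminated clone is present, the site with the strictly smallest
prevalence is called the origin; ties within a margin, or an initial clone
at prevalence ~1 everywhere, leave the direction undetermined.

Mutation time of a clone is its cumulative root-lineage mutation count
relative to the most-mutated clone of the model (scale 0-1, the latest
developed subclone defining 1).  The dissemination interval is the
mutation-time span of the disseminated clones for monophyletic cancers; for
polyphyletic cancers it is the largest unique-mutation load between two
mutually non-ancestral disseminated clones, relative to all modeled
mutations.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx
import pandas as pd

from .core import CloneTree

MONOCLONAL = "monoclonal"
MONOPHYLETIC = "monophyletic_polyclonal"
POLYPHYLETIC = "polyphyletic_polyclonal"

MONOCLONAL_ORIGIN = "monoclonal_origin"
POLYCLONAL_ORIGIN = "polyclonal_origin"

DEFAULT_PRESENCE_THRESHOLD = 0.02
DEFAULT_DIRECTION_MARGIN = 0.05
UNDETERMINED = "undetermined"


@dataclass
class CloneDesignation:
    initial: object
    disseminated: frozenset
    local: frozenset

    @property
    def no_dissemination(self) -> bool:
        return not self.disseminated


@dataclass
class DisseminationReport:
    """Per-patient summary of the dissemination analysis."""

    patient_id: str
    mode: Optional[str]
    origin_model: str
    initial_clone: Optional[str]
    disseminated: list[str]
    local: list[str]
    n_clones: int
    directions: dict[str, str]
    mutation_times: dict[str, float]
    first_dissemination_time: Optional[float]
    last_dissemination_time: Optional[float]
    interval: Optional[float]
    interval_method: Optional[str]
    site_unique_clones: dict[str, int]
    pairwise_modeled: bool = False
    subreports: list["DisseminationReport"] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "patient_id": self.patient_id,
            "mode": self.mode,
            "origin_model": self.origin_model,
            "initial_clone": self.initial_clone,
            "disseminated": sorted(self.disseminated),
            "local": sorted(self.local),
            "n_clones": self.n_clones,
            "directions": dict(sorted(self.directions.items())),
            "mutation_times": {k: round(v, 9) for k, v in
                               sorted(self.mutation_times.items())},
            "first_dissemination_time": _round(self.first_dissemination_time),
            "last_dissemination_time": _round(self.last_dissemination_time),
            "interval": _round(self.interval),
            "interval_method": self.interval_method,
            "site_unique_clones": dict(sorted(self.site_unique_clones.items())),
            "pairwise_modeled": self.pairwise_modeled,
        }
        if self.subreports:
            d["subreports"] = [r.to_dict() for r in self.subreports]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _round(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(float(x), 9)


# ---------------------------------------------------------------------------


def site_prevalence(tree: CloneTree, site_of: Mapping[str, str]) -> pd.DataFrame:
    """Clone-by-site prevalence: mean over the samples of each site."""
    if tree.prevalence is None:
        raise ValueError("tree has no prevalence matrix")
    cols = pd.Series({s: site_of[s] for s in tree.prevalence.columns})
    return tree.prevalence.T.groupby(cols).mean().T


def designate_clones(
    tree: CloneTree,
    site_of: Mapping[str, str],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> CloneDesignation:
    """Split clones into initial / disseminated / local by site presence."""
    sp = site_prevalence(tree, site_of)
    n_sites = sp.shape[1]
    present = sp >= presence_threshold
    n_present = present.sum(axis=1)

    disseminated = {
        u for u in tree.nodes if u != tree.root and n_present[u] >= 2
    }
    local = {
        u for u in tree.nodes if u != tree.root and n_present[u] == 1
    }
    if not disseminated and n_sites >= 2:
        # Seeding predated subclonal development: the initial clone is the
        # (only) clone shared across sites.
        disseminated = {tree.root}
    return CloneDesignation(
        initial=tree.root,
        disseminated=frozenset(disseminated),
        local=frozenset(local),
    )


def classify_mode(tree: CloneTree, disseminated: frozenset) -> Optional[str]:
    """One of the three dissemination modes, or None when nothing seeded."""
    if not disseminated:
        return None
    if len(disseminated) == 1:
        return MONOCLONAL
    pairs = itertools.combinations(sorted(disseminated, key=str), 2)
    if all(tree.on_one_lineage(a, b) for a, b in pairs):
        return MONOPHYLETIC
    return POLYPHYLETIC


def detect_polyclonal_origin(
    site_mutations: Mapping[str, set],
) -> tuple[str, list[list[str]]]:
    """Polyclonal origin when some site pair shares zero somatic mutations.

    Returns the origin model and the groups of sites connected by shared
    mutations (singletons count as their own group).  Site groups with no
    shared mutations are modeled as separate cancers downstream.
    """
    sites = sorted(site_mutations)
    g = nx.Graph()
    g.add_nodes_from(sites)
    for a, b in itertools.combinations(sites, 2):
        if site_mutations[a] & site_mutations[b]:
            g.add_edge(a, b)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort()
    model = POLYCLONAL_ORIGIN if len(components) > 1 and len(sites) > 1 \
        else MONOCLONAL_ORIGIN
    return model, components


def infer_direction(
    clone,
    tree: CloneTree,
    site_of: Mapping[str, str],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    direction_margin: float = DEFAULT_DIRECTION_MARGIN,
) -> str:
    """Origin site of a disseminated clone (smallest prevalence), if unique."""
    sp = site_prevalence(tree, site_of).loc[clone]
    present = sp[sp >= presence_threshold]
    if len(present) < 2:
        return UNDETERMINED
    # The initial clone at ~1 everywhere carries no direction signal.
    if clone == tree.root and (present >= 1.0 - direction_margin).all():
        return UNDETERMINED
    ordered = present.sort_values(kind="mergesort")
    if ordered.iloc[1] - ordered.iloc[0] < direction_margin:
        return UNDETERMINED
    return str(ordered.index[0])


def mutation_time_of_clone(clone, tree: CloneTree) -> float:
    """Cumulative mutation count of the clone over that of the most-mutated
    clone in the model (the latest developed subclone defines time 1)."""
    latest = max(tree.cumulative_count(u) for u in tree.nodes)
    if latest == 0:
        return 0.0
    return tree.cumulative_count(clone) / latest


def dissemination_interval(
    tree: CloneTree, disseminated: frozenset, mode: Optional[str]
) -> tuple[Optional[float], Optional[str]]:
    """Evolutionary span of the seeding process, per mode."""
    if mode is None:
        return None, None
    if mode == MONOCLONAL:
        return 0.0, "monophyletic_span"
    times = sorted(mutation_time_of_clone(u, tree) for u in disseminated)
    if mode == MONOPHYLETIC:
        return times[-1] - times[0], "monophyletic_span"
    # Polyphyletic: unique mutations of the two most divergent disseminated
    # clones (symmetric difference of their root lineages), over the model.
    total = tree.total_mutations
    best = 0.0
    for a, b in itertools.combinations(sorted(disseminated, key=str), 2):
        if tree.on_one_lineage(a, b):
            continue
        unique = len(tree.lineage_mutations(a) ^ tree.lineage_mutations(b))
        best = max(best, unique / total if total else 0.0)
    return best, "polyphyletic_unique_fraction"


def compare_site_complexity(
    tree: CloneTree,
    site_of: Mapping[str, str],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> dict[str, int]:
    """Per-site count of clones unique to that site (absent elsewhere)."""
    sp = site_prevalence(tree, site_of)
    present = sp >= presence_threshold
    out = {str(site): 0 for site in sp.columns}
    for u in tree.nodes:
        row = present.loc[u]
        if row.sum() == 1:
            out[str(row.idxmax())] += 1
    return out


def build_report(
    patient_id: str,
    tree: CloneTree,
    site_of: Mapping[str, str],
    origin_model: str = MONOCLONAL_ORIGIN,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    direction_margin: float = DEFAULT_DIRECTION_MARGIN,
    pairwise_modeled: bool = False,
) -> DisseminationReport:
    """Assemble the full per-patient dissemination report from one tree."""
    desig = designate_clones(tree, site_of, presence_threshold)
    mode = classify_mode(tree, desig.disseminated)
    times = {str(u): mutation_time_of_clone(u, tree) for u in tree.nodes}
    dtimes = sorted(times[str(u)] for u in desig.disseminated)
    interval, method = dissemination_interval(tree, desig.disseminated, mode)
    directions = {
        str(u): infer_direction(u, tree, site_of, presence_threshold,
                                direction_margin)
        for u in sorted(desig.disseminated, key=str)
    }
    return DisseminationReport(
        patient_id=patient_id,
        mode=mode,
        origin_model=origin_model,
        initial_clone=str(desig.initial),
        disseminated=[str(u) for u in sorted(desig.disseminated, key=str)],
        local=[str(u) for u in sorted(desig.local, key=str)],
        n_clones=len(tree),
        directions=directions,
        mutation_times=times,
        first_dissemination_time=dtimes[0] if dtimes else None,
        last_dissemination_time=dtimes[-1] if dtimes else None,
        interval=interval,
        interval_method=method,
        site_unique_clones=compare_site_complexity(
            tree, site_of, presence_threshold),
        pairwise_modeled=pairwise_modeled,
    )
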