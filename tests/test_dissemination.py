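"""Clone designation, mode classification, direction, timing, intervals."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonedisperse import dissemination as dis
from clonedisperse import simdata
from clonedisperse.core import CloneTree


def tree_with_prev(parent, prev_dict, mutations=None):
    samples = sorted({s for row in prev_dict.values() for s in row})
    prev = pd.DataFrame(
        {s: {u: prev_dict[u].get(s, 0.0) for u in parent} for s in samples})
    return CloneTree(parent, mutations or {}, prev)


SITE_OF = {"ov1": "ovary", "ov2": "ovary", "om1": "omentum"}


class TestDesignation:
    def test_disseminated_vs_local(self):
        t = tree_with_prev(
            {"r": None, "d": "r", "l": "r"},
            {"r": {"ov1": 1, "ov2": 1, "om1": 1},
             "d": {"ov1": 0.4, "ov2": 0.45, "om1": 0.9},
             "l": {"ov1": 0.3, "ov2": 0.25, "om1": 0.0}})
        out = dis.designate_clones(t, SITE_OF)
        assert out.initial == "r"
        assert out.disseminated == frozenset({"d"})
        assert out.local == frozenset({"l"})

    def test_root_seeds_when_no_shared_subclone(self):
        t = tree_with_prev(
            {"r": None, "a": "r", "b": "r"},
            {"r": {"ov1": 1, "om1": 1},
             "a": {"ov1": 0.5, "om1": 0.0},
             "b": {"ov1": 0.0, "om1": 0.6}})
        out = dis.designate_clones(t, {"ov1": "ovary", "om1": "omentum"})
        assert out.disseminated == frozenset({"r"})

    def test_single_site_no_dissemination(self):
        t = tree_with_prev({"r": None, "a": "r"},
                           {"r": {"ov1": 1}, "a": {"ov1": 0.5}})
        out = dis.designate_clones(t, {"ov1": "ovary"})
        assert out.no_dissemination


class TestMode:
    def _tree(self):
        return tree_with_prev(
            {"r": None, "a": "r", "b": "a", "c": "r"},
            {u: {"ov1": 1.0} for u in "rabc"})

    def test_partition(self):
        t = self._tree()
        assert dis.classify_mode(t, frozenset({"r"})) == dis.MONOCLONAL
        assert dis.classify_mode(t, frozenset({"a", "b"})) == dis.MONOPHYLETIC
        assert dis.classify_mode(t, frozenset({"a", "c"})) == dis.POLYPHYLETIC
        assert dis.classify_mode(t, frozenset()) is None

    def test_every_nonempty_set_maps_to_exactly_one_mode(self):
        t = self._tree()
        for n in (1, 2, 3):
            for combo in itertools.combinations("rabc", n):
                mode = dis.classify_mode(t, frozenset(combo))
                assert mode in (dis.MONOCLONAL, dis.MONOPHYLETIC,
                                dis.POLYPHYLETIC)


class TestPolyclonalOrigin:
    def test_shared_truncal_is_monoclonal(self):
        model, groups = dis.detect_polyclonal_origin(
            {"ovary": {"m1", "m2"}, "omentum": {"m1"}})
        assert model == dis.MONOCLONAL_ORIGIN
        assert groups == [["omentum", "ovary"]]

    def test_disjoint_sites_polyclonal(self):
        model, groups = dis.detect_polyclonal_origin(
            {"ovary": {"m1"}, "omentum": {"m2", "m3"}, "ascites": {"m3"}})
        assert model == dis.POLYCLONAL_ORIGIN
        assert groups == [["ascites", "omentum"], ["ovary"]]

    def test_single_site_monoclonal_by_convention(self):
        model, _ = dis.detect_polyclonal_origin({"ovary": {"m1"}})
        assert model == dis.MONOCLONAL_ORIGIN


class TestDirection:
    def _tree(self, ov, om, asc=None):
        prev = {"r": {"ov1": 1, "om1": 1}, "d": {"ov1": ov, "om1": om}}
        site_of = {"ov1": "ovary", "om1": "omentum"}
        if asc is not None:
            prev["r"]["as1"] = 1
            prev["d"]["as1"] = asc
            site_of["as1"] = "ascites"
        return tree_with_prev({"r": None, "d": "r"}, prev), site_of

    def test_smallest_prevalence_is_origin(self):
        t, site_of = self._tree(0.2, 0.9)
        assert dis.infer_direction("d", t, site_of) == "ovary"

    def test_tie_undetermined(self):
        t, site_of = self._tree(0.5, 0.5)
        assert dis.infer_direction("d", t, site_of) == dis.UNDETERMINED

    def test_initial_clone_everywhere_undetermined(self):
        t, site_of = self._tree(0.2, 0.9)
        assert dis.infer_direction("r", t, site_of) == dis.UNDETERMINED

    def test_never_returns_absent_site(self):
        t, site_of = self._tree(0.4, 0.9, asc=0.0)
        for _ in range(3):
            assert dis.infer_direction("d", t, site_of) != "ascites"

    def test_site_label_permutation_invariant(self):
        t, site_of = self._tree(0.2, 0.9)
        swapped = {"ov1": "omentum", "om1": "ovary"}
        assert dis.infer_direction("d", t, swapped) == "omentum"


def chain_tree(counts, parent=None):
    muts = {}
    parent = parent or {}
    prev_node = None
    for i, n in enumerate(counts):
        u = f"c{i}"
        parent.setdefault(u, prev_node)
        muts[u] = {f"{u}:{j}" for j in range(n)}
        prev_node = u
    return CloneTree(parent, muts)


class TestMutationTime:
    def test_deepest_clone_is_one(self):
        t = chain_tree([50, 30, 20])
        assert dis.mutation_time_of_clone("c2", t) == 1.0
        assert dis.mutation_time_of_clone("c1", t) == pytest.approx(0.8)
        assert dis.mutation_time_of_clone("c0", t) == pytest.approx(0.5)

    def test_monotone_along_lineages(self):
        for seed in range(20):
            mode = [simdata.MONOCLONAL, simdata.MONOPHYLETIC,
                    simdata.POLYPHYLETIC][seed % 3]
            cfg = simdata.SimulationConfig(
                mode=mode,
                n_disseminated=1 if mode == simdata.MONOCLONAL else 2,
                n_clones=3 + seed % 6, seed=seed)
            t = simdata.simulate_clone_tree(cfg)
            times = {u: dis.mutation_time_of_clone(u, t) for u in t.nodes}
            assert max(times.values()) == 1.0
            for u in t.nodes:
                p = t.parent[u]
                if p is not None:
                    assert times[u] >= times[p]


def lca_interval_oracle(tree, a, b):
    """Independent interval computation via the lowest common ancestor."""
    anc_a, anc_b = tree.ancestors(a), tree.ancestors(b)
    common = [u for u, v in zip(anc_a, anc_b) if u == v]
    lca = common[-1]
    unique = (tree.cumulative_count(a) + tree.cumulative_count(b)
              - 2 * tree.cumulative_count(lca))
    return unique / tree.total_mutations


class TestInterval:
    def test_monoclonal_zero(self):
        t = chain_tree([10])
        interval, method = dis.dissemination_interval(
            t, frozenset({"c0"}), dis.MONOCLONAL)
        assert interval == 0.0

    def test_monophyletic_span(self):
        t = chain_tree([60, 10, 30])  # times 0.6, 0.7, 1.0
        interval, method = dis.dissemination_interval(
            t, frozenset({"c0", "c1"}), dis.MONOPHYLETIC)
        assert method == "monophyletic_span"
        assert interval == pytest.approx(0.1)

    def test_polyphyletic_unique_fraction(self):
        muts = {"r": {f"r{i}" for i in range(60)},
                "a": {f"a{i}" for i in range(15)},
                "b": {f"b{i}" for i in range(25)}}
        t = CloneTree({"r": None, "a": "r", "b": "r"}, muts)
        interval, method = dis.dissemination_interval(
            t, frozenset({"a", "b"}), dis.POLYPHYLETIC)
        assert method == "polyphyletic_unique_fraction"
        assert interval == pytest.approx(0.40)
        assert interval == pytest.approx(lca_interval_oracle(t, "a", "b"))

    def test_polyphyletic_matches_lca_oracle_on_random_trees(self):
        for seed in range(30):
            cfg = simdata.SimulationConfig(
                mode=simdata.POLYPHYLETIC, n_clones=4 + seed % 5,
                n_disseminated=2 + seed % 2, seed=seed)
            t = simdata.simulate_clone_tree(cfg)
            diss = frozenset(t.meta["disseminated"])
            interval, _ = dis.dissemination_interval(t, diss, dis.POLYPHYLETIC)
            want = max(
                (lca_interval_oracle(t, a, b)
                 for a, b in itertools.combinations(sorted(diss, key=str), 2)
                 if not t.on_one_lineage(a, b)),
                default=0.0)
            assert interval == pytest.approx(want, abs=1e-12)


class TestSiteComplexity:
    def test_counts(self):
        t = tree_with_prev(
            {"r": None, "c1": "r", "c2": "r", "c3": "c1", "c4": "r"},
            {"r": {"ov1": 1, "om1": 1},
             "c1": {"ov1": 0.5, "om1": 0.0},
             "c2": {"ov1": 0.2, "om1": 0.0},
             "c3": {"ov1": 0.1, "om1": 0.0},
             "c4": {"ov1": 0.0, "om1": 0.4}})
        out = dis.compare_site_complexity(
            t, {"ov1": "ovary", "om1": "omentum"})
        assert out == {"ovary": 3, "omentum": 1}

    def test_all_shared_zero(self):
        t = tree_with_prev(
            {"r": None, "a": "r"},
            {"r": {"ov1": 1, "om1": 1}, "a": {"ov1": 0.5, "om1": 0.5}})
        out = dis.compare_site_complexity(
            t, {"ov1": "ovary", "om1": "omentum"})
        assert out == {"ovary": 0, "omentum": 0}


def test_report_roundtrips_to_json():
    t = tree_with_prev(
        {"r": None, "d": "r"},
        {"r": {"ov1": 1, "om1": 1}, "d": {"ov1": 0.2, "om1": 0.8}},
        mutations={"r": {f"r{i}" for i in range(10)},
                   "d": {f"d{i}" for i in range(5)}})
    rep = dis.build_report("P01", t, {"ov1": "ovary", "om1": "omentum"})
    assert rep.mode == dis.MONOCLONAL
    assert rep.directions["d"] == "ovary"
    import json
    parsed = json.loads(rep.to_json())
    assert parsed["patient_id"] == "P01"
    assert parsed["mode"] == "monoclonal"
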