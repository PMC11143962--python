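"""Generator properties: topology, sum rule, determinism, read model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from clonedisperse import simdata
from clonedisperse.core import ConfigurationError
from clonedisperse.simdata import (
    MONOCLONAL, MONOPHYLETIC, POLYPHYLETIC, SimulationConfig,
)


class TestConfigValidation:
    def test_rejects_impossible_combinations(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(mode=POLYPHYLETIC, n_clones=2, n_disseminated=2)
        with pytest.raises(ConfigurationError):
            SimulationConfig(mode=MONOPHYLETIC, n_disseminated=1)
        with pytest.raises(ConfigurationError):
            SimulationConfig(mode=MONOCLONAL, n_disseminated=2)
        with pytest.raises(ConfigurationError):
            SimulationConfig(purity_range=(0.0, 0.5))
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_sites=1, n_disseminated=1)

    def test_single_clone_degenerate(self):
        cfg = SimulationConfig(mode=MONOCLONAL, n_clones=1, n_disseminated=1,
                               seed=0)
        tree = simdata.simulate_clone_tree(cfg)
        assert len(tree) == 1
        assert tree.meta["root_disseminated"]


class TestTopology:
    def test_polyphyletic_has_sibling_disseminated_clones(self):
        cfg = SimulationConfig(mode=POLYPHYLETIC, n_clones=6,
                               n_disseminated=2, seed=7)
        tree = simdata.simulate_clone_tree(cfg)
        diss = [u for u in tree.meta["disseminated"] if u != tree.root]
        assert len(diss) >= 2
        assert any(
            not tree.on_one_lineage(a, b)
            for i, a in enumerate(diss) for b in diss[i + 1:]
        )

    def test_monophyletic_chain(self):
        cfg = SimulationConfig(mode=MONOPHYLETIC, n_clones=6,
                               n_disseminated=3, seed=3)
        tree = simdata.simulate_clone_tree(cfg)
        diss = [u for u in tree.meta["disseminated"]]
        for i, a in enumerate(diss):
            for b in diss[i + 1:]:
                assert tree.on_one_lineage(a, b)

    def test_minimum_private_mutations(self):
        cfg = SimulationConfig(mutations_per_clone_mean=0.5, seed=2)
        tree = simdata.simulate_clone_tree(cfg)
        assert all(tree.private_count(u) >= 3 for u in tree.nodes)

    def test_poisson_mean_of_private_counts(self):
        """Monte-Carlo: mean total mutations ~ n_clones * lambda, and the
        per-clone counts fit the Poisson law (chi-square GOF)."""
        lam, n_clones, reps = 50.0, 5, 1000
        counts = []
        for seed in range(reps):
            cfg = SimulationConfig(n_clones=n_clones,
                                   mutations_per_clone_mean=lam, seed=seed)
            tree = simdata.simulate_clone_tree(cfg)
            counts.extend(tree.private_count(u) for u in tree.nodes)
        counts = np.asarray(counts)
        se = np.sqrt(n_clones * lam / reps)
        assert abs(counts.sum() / reps - n_clones * lam) < 3 * se

        # chi-square against Poisson(lam), tails pooled
        edges = np.arange(int(lam - 20), int(lam + 21))
        observed, _ = np.histogram(counts, bins=np.r_[-np.inf, edges, np.inf])
        pmf = np.diff(stats.poisson.cdf(np.r_[-np.inf, edges, np.inf] - 0.5,
                                        lam))
        expected = pmf * len(counts)
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01


class TestPrevalences:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        mode=st.sampled_from([MONOCLONAL, MONOPHYLETIC, POLYPHYLETIC]),
        n_clones=st.integers(3, 9),
        n_sites=st.integers(2, 3),
    )
    def test_sum_rule_exact(self, seed, mode, n_clones, n_sites):
        k = 1 if mode == MONOCLONAL else 2
        cfg = SimulationConfig(mode=mode, n_clones=n_clones, n_sites=n_sites,
                               n_disseminated=k, seed=seed)
        tree = simdata.assign_prevalences(simdata.simulate_clone_tree(cfg), cfg)
        assert tree.sum_rule_violations(tolerance=1e-9) == []
        assert (tree.prevalence.loc[tree.root] == 1.0).all()

    def test_disseminated_at_two_sites_origin_smallest(self):
        cfg = SimulationConfig(mode=MONOPHYLETIC, n_disseminated=2, seed=5)
        p = simdata.simulate_patient(cfg)
        tree = p.truth.tree
        site_prev = tree.prevalence.T.groupby(
            tree.prevalence.columns.map(p.panel.site_of)).mean().T
        for u in p.truth.disseminated:
            origin = p.truth.origin_site[u]
            row = site_prev.loc[u]
            present = row[row > 0.01]
            assert len(present) >= 2
            assert row.idxmin() == origin

    def test_local_clones_single_site(self):
        cfg = SimulationConfig(mode=MONOCLONAL, n_disseminated=1,
                               n_clones=6, seed=9)
        p = simdata.simulate_patient(cfg)
        tree = p.truth.tree
        site_prev = tree.prevalence.T.groupby(
            tree.prevalence.columns.map(p.panel.site_of)).mean().T
        locals_ = [u for u in tree.nodes
                   if u != tree.root and u not in p.truth.disseminated]
        for u in locals_:
            assert (site_prev.loc[u] > 1e-9).sum() == 1

    def test_determinism(self):
        cfg = SimulationConfig(seed=21)
        a = simdata.assign_prevalences(simdata.simulate_clone_tree(cfg), cfg)
        b = simdata.assign_prevalences(simdata.simulate_clone_tree(cfg), cfg)
        pd.testing.assert_frame_equal(a.prevalence, b.prevalence)
        assert a.parent_map_key() == b.parent_map_key()


class TestReadEmission:
    def test_expected_vaf_formula(self):
        # diploid heterozygous truncal in a pure sample
        assert simdata.expected_vaf(1.0, 1.0, 2, 1) == pytest.approx(0.5)
        # direct evaluation at half purity, prevalence 0.4
        assert simdata.expected_vaf(0.4, 0.5, 2, 1) == pytest.approx(0.10)

    def test_noise_free_counts_are_exact_expectations(self):
        cfg = SimulationConfig(noise="none", seed=8)
        p = simdata.simulate_patient(cfg)
        clone_of = p.truth.tree.clone_of_mutation()
        for row in p.mutations.sample(50, random_state=0).itertuples():
            prev = float(p.truth.tree.prevalence.loc[clone_of[
                f"{row.chrom}:{row.pos}:{row.ref}:{row.alt}"], row.sample])
            vaf = simdata.expected_vaf(prev, p.panel.purity[row.sample], 2, 1)
            assert row.t_alt == pytest.approx(row.t_depth * vaf, abs=1e-9)
        assert (p.mutations["n_alt"] == 0).all()

    def test_binomial_mode_integer_counts(self):
        cfg = SimulationConfig(noise="binomial", seed=8)
        p = simdata.simulate_patient(cfg)
        assert (p.mutations["t_alt"] == p.mutations["t_alt"].round()).all()
        assert (p.mutations["t_alt"] <= p.mutations["t_depth"]).all()

    def test_gain_segments_and_multiplicity(self):
        cfg = SimulationConfig(noise="none", seed=8, gain_chroms=("1",))
        p = simdata.simulate_patient(cfg)
        seg1 = p.segments[p.segments["chrom"] == "1"]
        assert (seg1["cn_total"] == 3.0).all()
        # truncal mutation on the gained chromosome has multiplicity 2:
        # VAF exceeds the single-copy expectation
        clone_of = p.truth.tree.clone_of_mutation()
        sub = p.mutations[p.mutations["chrom"] == "1"]
        trunk = sub[[clone_of[f"1:{r.pos}:{r.ref}:{r.alt}"] == p.truth.tree.root
                     for r in sub.itertuples()]]
        s = trunk.iloc[0]
        purity = p.panel.purity[s["sample"]]
        assert s["t_alt"] / s["t_depth"] == pytest.approx(
            simdata.expected_vaf(1.0, purity, 3, 2), abs=1e-9)


def test_patient_fixed_seed_files_identical(tmp_path):
    cfg = SimulationConfig(seed=33)
    for d in ("a", "b"):
        simdata.write_patient(simdata.simulate_patient(cfg), tmp_path / d)
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


def test_polyclonal_origin_patient_disjoint_sites():
    p = simdata.simulate_polyclonal_origin_patient(seed=2, noise="none")
    keys_by_site = {}
    for site in p.panel.sites:
        samples = p.panel.samples_of_site(site)
        sub = p.mutations[p.mutations["sample"].isin(samples)]
        sub = sub[sub["t_alt"] > 0]
        keys_by_site[site] = set(
            sub["chrom"].astype(str) + ":" + sub["pos"].astype(str))
    assert not (keys_by_site["ovary"] & keys_by_site["omentum"])
    assert keys_by_site["omentum"] & keys_by_site["ascites"]
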