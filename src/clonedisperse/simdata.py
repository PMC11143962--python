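"""Synthetic multi-site tumor generator with known clonal ground truth.

Emulates the sampling design of a deep whole-exome study of disseminated
high-grade serous carcinoma: 3-7 tumor samples per patient spread over 2-3
anatomical sites, tumor purity 0.40-0.90, roughly 670x sequencing depth,
and clone trees of 3-9 clones whose per-site cellular prevalences obey the
sum rule exactly.  Each simulated patient carries a declared dissemination
mode (monoclonal, monophyletic polyclonal, or polyphyletic polyclonal) and
per-clone seeding directions, so every downstream inference stage can be
scored against truth.

Prevalences are constructed top-down so that the sum rule holds by
construction, and the patterns are arranged so that the declared mode is
identifiable from prevalences alone:

* a monophyletic chain keeps consecutive prevalence ratios high enough that
  no sibling arrangement of the chain satisfies the sum rule;
* polyphyletic siblings either occupy non-nested site sets or have
  prevalence orders that cross between sites, which rules out any chain.

Read counts follow the standard allele-fraction model
``VAF = purity * prevalence * multiplicity / (purity * CN_total + (1 - purity) * 2)``
with binomial sampling at the configured depth, or exact expectations in
noise-free mode (fractional alt counts, so prevalences round-trip exactly).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import CloneTree, ConfigurationError, SamplePanel

MONOCLONAL = "monoclonal"
MONOPHYLETIC = "monophyletic_polyclonal"
POLYPHYLETIC = "polyphyletic_polyclonal"
MODES = (MONOCLONAL, MONOPHYLETIC, POLYPHYLETIC)

SITE_POOL = ("ovary", "omentum", "ascites")

_EFFECTS = ("missense", "synonymous", "nonsense", "frameshift_indel",
            "splice_site", "inframe_indel", "other")
_EFFECT_WEIGHTS = (0.52, 0.25, 0.05, 0.06, 0.04, 0.03, 0.05)


@dataclass
class SimulationConfig:
    """Study-condition parameters for one synthetic patient.

    Defaults reflect the cohort being emulated: ~670x depth, purity drawn
    uniformly from 0.40-0.90, two anatomical sites with two samples each,
    and ~50 private mutations per clone (desk-scale exome territory).
    """

    n_clones: int = 5
    mutations_per_clone_mean: float = 50.0
    n_sites: int = 2
    samples_per_site: int = 2
    depth_mean: float = 670.0
    purity_range: tuple[float, float] = (0.40, 0.90)
    mode: str = MONOPHYLETIC
    n_disseminated: int = 2
    noise: str = "binomial"
    seed: int = 0
    min_mutations_per_clone: int = 3
    normal_error_rate: float = 1e-3
    region_jitter: float = 0.0
    min_clone_separation: float = 0.12
    gain_chroms: tuple[str, ...] = ()
    site_labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.noise not in ("none", "binomial"):
            raise ConfigurationError(f"unknown noise model {self.noise!r}")
        if not 1 <= self.n_sites <= len(SITE_POOL):
            raise ConfigurationError("n_sites must be 1-3")
        if self.samples_per_site < 1:
            raise ConfigurationError("samples_per_site must be >= 1")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("purity_range must lie within (0, 1]")
        if self.n_clones < 1:
            raise ConfigurationError("n_clones must be >= 1")
        if self.n_disseminated < 0 or self.n_disseminated > self.n_clones:
            raise ConfigurationError("n_disseminated must be in [0, n_clones]")
        if self.n_disseminated == 0 and self.n_sites > 1:
            raise ConfigurationError(
                "n_disseminated = 0 is only meaningful for single-site patients"
            )
        if self.n_sites == 1 and self.n_disseminated > 0:
            raise ConfigurationError("dissemination requires >= 2 sites")
        if self.mode == MONOCLONAL:
            if self.n_disseminated > 1:
                raise ConfigurationError("monoclonal mode seeds exactly one clone")
        else:
            if self.n_disseminated < 2:
                raise ConfigurationError(f"{self.mode} requires n_disseminated >= 2")
            if self.n_clones < self.n_disseminated + 1:
                raise ConfigurationError(
                    f"{self.mode} with {self.n_disseminated} disseminated clones "
                    f"requires at least {self.n_disseminated + 1} clones"
                )
        if self.site_labels is not None and len(self.site_labels) != self.n_sites:
            raise ConfigurationError("site_labels length must equal n_sites")
        if self.mutations_per_clone_mean <= 0 or self.depth_mean <= 0:
            raise ConfigurationError("rates and depths must be positive")

    @property
    def sites(self) -> tuple[str, ...]:
        return self.site_labels or SITE_POOL[: self.n_sites]


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated patient."""

    tree: CloneTree
    mode: Optional[str]
    disseminated: frozenset
    origin_site: dict
    purity: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "disseminated": sorted(str(u) for u in self.disseminated),
            "origin_site": {str(u): s for u, s in sorted(
                self.origin_site.items(), key=lambda x: str(x[0]))},
            "purity": {s: round(p, 6) for s, p in sorted(self.purity.items())},
            "tree": self.tree.to_dict(),
        }


@dataclass
class SimulatedPatient:
    patient_id: str
    panel: SamplePanel
    mutations: pd.DataFrame
    segments: pd.DataFrame
    truth: SyntheticTruth
    component_truths: list[SyntheticTruth] = field(default_factory=list)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # Fixed sub-stream offsets keep the stages independently reproducible.
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# topology


def simulate_clone_tree(config: SimulationConfig) -> CloneTree:
    """Draw a clone tree whose topology matches the configured mode.

    Non-root clones are planned as either *disseminated* (assigned a set of
    >= 2 sites plus an origin site) or *local* (a single site nested within
    the parent's site set).  Private mutation counts are Poisson with the
    configured mean, floored at the minimum detectable cluster size.
    """
    rng = _rng(config.seed, 1)
    sites = list(config.sites)

    parent: dict[int, Optional[int]] = {0: None}
    site_set: dict[int, tuple[str, ...]] = {0: tuple(sites)}
    origin: dict[int, Optional[str]] = {}
    disseminated: list[int] = []
    root_disseminated = False
    crossing_pair: Optional[tuple[int, int]] = None

    next_id = 1
    k = config.n_disseminated

    if k >= 1 and config.mode == MONOCLONAL:
        # Either the initial clone seeds before any subclone exists, or a
        # single subclone seeds between two sites.
        if config.n_clones == 1 or rng.random() < 0.5:
            root_disseminated = True
            disseminated = [0]
            origin[0] = None
        else:
            d = next_id
            next_id += 1
            pair = tuple(sorted(rng.choice(len(sites), size=2, replace=False)))
            pair_sites = tuple(sites[i] for i in pair)
            parent[d] = 0
            site_set[d] = pair_sites
            origin[d] = pair_sites[int(rng.integers(2))]
            disseminated = [d]
    elif config.mode == MONOPHYLETIC:
        pair = tuple(sorted(rng.choice(len(sites), size=2, replace=False)))
        pair_sites = tuple(sites[i] for i in pair)
        o = pair_sites[int(rng.integers(2))]
        prev = 0
        for _ in range(k):
            d = next_id
            next_id += 1
            parent[d] = prev
            site_set[d] = pair_sites
            origin[d] = o
            disseminated.append(d)
            prev = d
    elif config.mode == POLYPHYLETIC:
        if len(sites) >= 3:
            shared = sites[int(rng.integers(len(sites)))]
            rest = [s for s in sites if s != shared]
            pair_a = tuple(sorted((shared, rest[0])))
            pair_b = tuple(sorted((shared, rest[1])))
            d1, d2 = next_id, next_id + 1
            next_id += 2
            parent[d1], parent[d2] = 0, 0
            site_set[d1], site_set[d2] = pair_a, pair_b
            # The shared site is the origin of the first sibling so that the
            # two destination loads never land on the same site together.
            origin[d1] = shared
            origin[d2] = rest[1] if rng.random() < 0.5 else shared
        else:
            d1, d2 = next_id, next_id + 1
            next_id += 2
            parent[d1], parent[d2] = 0, 0
            site_set[d1] = site_set[d2] = tuple(sites)
            origin[d1], origin[d2] = sites[0], sites[1]
            crossing_pair = (d1, d2)
        disseminated = [d1, d2]
        anchors = [d1, d2]
        for j in range(k - 2):
            d = next_id
            next_id += 1
            anchor = anchors[j % 2]
            # Extend alternating chains below the two founding siblings.
            while True:
                kids = [c for c in disseminated if parent.get(c) == anchor]
                if not kids:
                    break
                anchor = kids[0]
            parent[d] = anchor
            site_set[d] = site_set[anchor]
            origin[d] = origin[anchor]
            disseminated.append(d)

    # Local clones fill the remaining budget, attached site-consistently.
    n_local = config.n_clones - next_id
    for _ in range(n_local):
        u = next_id
        next_id += 1
        existing = sorted(parent)
        if rng.random() < 0.5:
            p = 0
        else:
            p = int(existing[int(rng.integers(len(existing)))])
        parent[u] = p
        s = site_set[p][int(rng.integers(len(site_set[p])))]
        site_set[u] = (s,)
        origin[u] = None

    # Private mutations: Poisson-drawn, floored at the minimum cluster size.
    mutations: dict[int, set[str]] = {}
    counts = {
        u: max(config.min_mutations_per_clone,
               int(rng.poisson(config.mutations_per_clone_mean)))
        for u in sorted(parent)
    }
    idx = 0
    bases = np.array(list("ACGT"))
    for u in sorted(parent):
        keys = set()
        for _ in range(counts[u]):
            chrom = str(idx % 22 + 1)
            pos = 10_000 + (idx // 22) * 211
            ref, alt = rng.choice(4, size=2, replace=False)
            keys.add(f"{chrom}:{pos}:{bases[ref]}:{bases[alt]}")
            idx += 1
        mutations[u] = keys

    meta = {
        "mode": config.mode if config.n_disseminated > 0 else None,
        "site_set": site_set,
        "origin_site": origin,
        "disseminated": tuple(disseminated),
        "root_disseminated": root_disseminated,
        "crossing_pair": crossing_pair,
    }
    return CloneTree(parent, mutations, meta=meta)


# ---------------------------------------------------------------------------
# prevalences


def _allocate_site_matrix(
    tree: CloneTree, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """One draw of the clone-by-site prevalence matrix (sum rule exact)."""
    sites = list(config.sites)
    site_set = tree.meta["site_set"]
    origin = tree.meta["origin_site"]
    disseminated = [u for u in tree.meta["disseminated"] if u != tree.root]
    crossing = tree.meta["crossing_pair"]

    P = pd.DataFrame(0.0, index=tree.nodes, columns=sites)
    P.loc[tree.root] = 1.0

    # Disseminated clones first, in ancestor order.  Chains use a high
    # parent-child ratio so sibling rearrangements violate the sum rule;
    # origins get a damped share so the seeding direction is recoverable.
    by_depth = sorted(disseminated, key=lambda u: len(tree.ancestors(u)))
    for u in by_depth:
        p = tree.parent[u]
        if p == tree.root or p not in disseminated:
            if crossing is not None and u in crossing:
                o = origin[u]
                for s in site_set[u]:
                    if s == o:
                        P.loc[u, s] = rng.uniform(0.15, 0.25)
                    else:
                        P.loc[u, s] = rng.uniform(0.52, 0.62)
            elif tree.meta["mode"] == POLYPHYLETIC:
                # Founding siblings share the root's budget at their common
                # site, so destinations stay moderate to keep the sum < 1.
                dest = rng.uniform(0.52, 0.62)
                damp = rng.uniform(0.28, 0.45)
                for s in site_set[u]:
                    P.loc[u, s] = dest * damp if s == origin[u] else dest
            else:
                dest = rng.uniform(0.75, 0.82)
                damp = rng.uniform(0.25, 0.45)
                for s in site_set[u]:
                    P.loc[u, s] = dest * damp if s == origin[u] else dest
        else:
            r = rng.uniform(0.72, 0.78)
            for s in site_set[u]:
                P.loc[u, s] = float(P.loc[p, s]) * r

    # Local clones from remaining headroom, root-to-leaf.
    order = sorted(tree.nodes, key=lambda u: len(tree.ancestors(u)))
    for u in order:
        if u == tree.root or u in disseminated:
            continue
        (s,) = site_set[u]
        p = tree.parent[u]
        used = sum(float(P.loc[v, s]) for v in tree.children(p) if v != u)
        headroom = float(P.loc[p, s]) - used
        if headroom <= 0.02:
            P.loc[u, s] = max(headroom * 0.5, 0.0)
            continue
        frac = rng.uniform(0.35, 0.8)
        P.loc[u, s] = min(headroom * frac, 0.85)
    return P


def _min_pairwise_separation(P: pd.DataFrame) -> float:
    X = P.to_numpy()
    if len(X) < 2:
        return np.inf
    d = np.abs(X[:, None, :] - X[None, :, :]).max(axis=2)
    iu = np.triu_indices(len(X), k=1)
    return float(d[iu].min())


def assign_prevalences(tree: CloneTree, config: SimulationConfig) -> CloneTree:
    """Attach a per-sample prevalence matrix satisfying the sum rule.

    Draws site-level prevalences repeatedly (deterministically, from the
    configured seed) and keeps the first draw whose clones are pairwise
    separated by at least ``config.min_clone_separation`` in max-norm, or
    the best-separated draw after 60 attempts.  Samples of one site share
    the site's vector, optionally perturbed by a small multiplicative
    jitter (children are rescaled if the jitter breaks the sum rule).
    """
    rng = _rng(config.seed, 2)
    best, best_sep = None, -1.0
    for _ in range(60):
        P = _allocate_site_matrix(tree, config, rng)
        sep = _min_pairwise_separation(P)
        if sep >= config.min_clone_separation:
            best, best_sep = P, sep
            break
        if sep > best_sep:
            best, best_sep = P, sep
    assert best is not None
    site_P = best

    samples: list[str] = []
    sample_site: dict[str, str] = {}
    for site in config.sites:
        for j in range(config.samples_per_site):
            name = f"{site}_{j + 1}"
            samples.append(name)
            sample_site[name] = site

    prev = pd.DataFrame(
        {s: site_P[sample_site[s]] for s in samples}, index=tree.nodes
    )
    if config.region_jitter > 0:
        for s in samples:
            factor = np.exp(rng.normal(0.0, config.region_jitter, size=len(prev)))
            col = prev[s] * factor
            col.loc[tree.root] = 1.0
            # Restore the sum rule top-down after jittering.
            for u in sorted(tree.nodes, key=lambda u: len(tree.ancestors(u))):
                kids = tree.children(u)
                if not kids:
                    continue
                total = col.loc[kids].sum()
                if total > col.loc[u]:
                    col.loc[kids] *= col.loc[u] / total * 0.999
            prev[s] = col

    out = tree.copy()
    out.prevalence = prev.loc[out.nodes]
    out.meta["sample_site"] = sample_site
    return out


# ---------------------------------------------------------------------------
# read emission


def _segment_table(config: SimulationConfig, samples: list[str]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for c in range(1, 23):
            chrom = str(c)
            gained = chrom in config.gain_chroms
            rows.append({
                "chrom": chrom, "start": 1, "end": 250_000_000,
                "cn_total": 3.0 if gained else 2.0,
                "cn_minor": 1.0,
                "sample": s,
            })
    return pd.DataFrame(rows)


def expected_vaf(prevalence, purity, cn_total, multiplicity):
    """Allele fraction implied by clone prevalence under the purity model."""
    prevalence = np.asarray(prevalence, dtype=float)
    return (purity * prevalence * multiplicity
            / (purity * cn_total + (1.0 - purity) * 2.0))


def emit_reads(
    tree: CloneTree, config: SimulationConfig, panel: SamplePanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit per-sample mutation tables and copy-number segments.

    Returns a long-format mutation table (one row per mutation per sample,
    including zero-support rows, as produced by joint multi-sample calling)
    and a FACETS-style segment table.  In noise-free mode alt counts are the
    exact binomial expectations (fractional), so allele fractions
    back-transform to clone prevalences without rounding error.
    """
    if tree.prevalence is None:
        raise ValueError("assign_prevalences must run before emit_reads")
    rng = _rng(config.seed, 4)
    samples = panel.samples
    segs = _segment_table(config, samples)

    clone_of = tree.clone_of_mutation()
    keys = sorted(clone_of)
    chroms = [k.split(":")[0] for k in keys]
    poss = [int(k.split(":")[1]) for k in keys]
    refs = [k.split(":")[2] for k in keys]
    alts = [k.split(":")[3] for k in keys]
    effects = rng.choice(_EFFECTS, size=len(keys), p=_EFFECT_WEIGHTS)

    cn_tot = np.array([3.0 if c in config.gain_chroms else 2.0 for c in chroms])
    mult = np.array([
        2.0 if (c in config.gain_chroms and clone_of[k] == tree.root) else 1.0
        for c, k in zip(chroms, keys)
    ])
    prev = np.array([[float(tree.prevalence.loc[clone_of[k], s]) for s in samples]
                     for k in keys])

    frames = []
    for j, s in enumerate(samples):
        purity = panel.purity[s]
        vaf = expected_vaf(prev[:, j], purity, cn_tot, mult)
        if config.noise == "none":
            t_depth = np.full(len(keys), round(config.depth_mean), dtype=float)
            t_alt = t_depth * vaf
            n_depth = np.full(len(keys), round(config.depth_mean), dtype=float)
            n_alt = np.zeros(len(keys))
        else:
            t_depth = np.maximum(1, rng.poisson(config.depth_mean, len(keys)))
            t_alt = rng.binomial(t_depth.astype(int), vaf).astype(float)
            t_depth = t_depth.astype(float)
            n_depth = np.maximum(
                1, rng.poisson(config.depth_mean, len(keys))).astype(float)
            n_alt = rng.binomial(
                n_depth.astype(int), config.normal_error_rate).astype(float)
        frames.append(pd.DataFrame({
            "chrom": chroms, "pos": poss, "ref": refs, "alt": alts,
            "sample": s, "t_depth": t_depth, "t_alt": t_alt,
            "n_depth": n_depth, "n_alt": n_alt, "effect": effects,
        }))
    muts = pd.concat(frames, ignore_index=True)
    muts = muts.sort_values(
        ["sample", "chrom", "pos", "ref", "alt"], kind="mergesort"
    ).reset_index(drop=True)
    return muts, segs


def simulate_patient(
    config: SimulationConfig, patient_id: str = "P01"
) -> SimulatedPatient:
    """Run the full generator for one patient: tree, prevalences, reads."""
    tree = simulate_clone_tree(config)
    tree = assign_prevalences(tree, config)
    rng = _rng(config.seed, 3)
    samples = list(tree.prevalence.columns)
    sample_site = tree.meta["sample_site"]
    purity = {s: float(rng.uniform(*config.purity_range)) for s in samples}
    panel = SamplePanel(patient_id, samples, dict(sample_site), purity)
    muts, segs = emit_reads(tree, config, panel)
    disseminated = frozenset(tree.meta["disseminated"])
    truth = SyntheticTruth(
        tree=tree,
        mode=tree.meta["mode"],
        disseminated=disseminated,
        origin_site={u: tree.meta["origin_site"].get(u) for u in disseminated},
        purity=purity,
    )
    return SimulatedPatient(patient_id, panel, muts, segs, truth)


def simulate_polyclonal_origin_patient(
    seed: int, patient_id: str = "P01", noise: str = "binomial"
) -> SimulatedPatient:
    """Two independent cancers in one patient, with zero shared mutations.

    Mirrors the design of a synchronous polyclonal case: one cancer confined
    to the ovary, a second disseminating between two extraovarian sites.
    """
    cfg_a = SimulationConfig(
        n_clones=3, n_sites=1, samples_per_site=2, mode=MONOCLONAL,
        n_disseminated=0, noise=noise, seed=seed,
        site_labels=("ovary",),
    )
    cfg_b = SimulationConfig(
        n_clones=4, n_sites=2, samples_per_site=1, mode=MONOCLONAL,
        n_disseminated=1, noise=noise, seed=seed + 101,
        site_labels=("omentum", "ascites"),
    )
    pa = simulate_patient(cfg_a, patient_id)
    pb = simulate_patient(cfg_b, patient_id)

    # Shift the second cancer's loci so the mutation sets are disjoint.
    offset = 50_000_000
    mb = pb.mutations.copy()
    mb["pos"] = mb["pos"] + offset

    def _shift(truth: SyntheticTruth) -> SyntheticTruth:
        t = truth.tree.copy()
        t.mutations = {
            u: frozenset(
                f"{k.split(':')[0]}:{int(k.split(':')[1]) + offset}:"
                f"{k.split(':')[2]}:{k.split(':')[3]}" for k in ms)
            for u, ms in t.mutations.items()
        }
        return SyntheticTruth(t, truth.mode, truth.disseminated,
                              truth.origin_site, truth.purity)

    truth_b = _shift(pb.truth)
    panel = SamplePanel(
        patient_id,
        pa.panel.samples + pb.panel.samples,
        {**pa.panel.site_of, **pb.panel.site_of},
        {**pa.panel.purity, **pb.panel.purity},
    )
    muts = pd.concat([pa.mutations, mb], ignore_index=True).sort_values(
        ["sample", "chrom", "pos", "ref", "alt"], kind="mergesort"
    ).reset_index(drop=True)
    segs = pd.concat([pa.segments, pb.segments], ignore_index=True)
    return SimulatedPatient(
        patient_id, panel, muts, segs, truth_b,
        component_truths=[pa.truth, truth_b],
    )


def simulate_cohort(
    n_patients: int = 23,
    seed: int = 0,
    noise: str = "binomial",
    include_polyclonal_origin: bool = True,
    mutations_per_clone_mean: float = 50.0,
) -> list[SimulatedPatient]:
    """Generate a cohort matching the emulated study's composition.

    Modes are drawn in roughly the observed 6:12:5 proportions
    (monoclonal : monophyletic polyclonal : polyphyletic polyclonal),
    clone counts uniformly from 3-9, and 3 sites for roughly 7/23 of
    patients; one patient (optionally) has a polyclonal cancer origin.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    patients = []
    mode_pool = [MONOCLONAL] * 6 + [MONOPHYLETIC] * 12 + [POLYPHYLETIC] * 5
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        sub_seed = int(rng.integers(2**31 - 1))
        if include_polyclonal_origin and i == n_patients - 1:
            patients.append(
                simulate_polyclonal_origin_patient(sub_seed, pid, noise))
            continue
        mode = mode_pool[int(rng.integers(len(mode_pool)))]
        n_sites = 3 if rng.random() < 7 / 23 else 2
        total_samples = int(rng.integers(3, 8))
        samples_per_site = max(1, round(total_samples / n_sites))
        n_clones = int(rng.integers(3, 10))
        if mode == MONOCLONAL:
            n_diss = 1
        else:
            n_diss = int(rng.choice([2, 2, 2, 3, 3, 5]))
            n_diss = min(n_diss, n_clones - 1)
            n_diss = max(n_diss, 2)
            if n_clones < 3:
                n_clones = 3
        cfg = SimulationConfig(
            n_clones=n_clones,
            mutations_per_clone_mean=mutations_per_clone_mean,
            n_sites=n_sites,
            samples_per_site=samples_per_site,
            mode=mode,
            n_disseminated=n_diss,
            noise=noise,
            seed=sub_seed,
        )
        patients.append(simulate_patient(cfg, pid))
    return patients


def write_patient(patient: SimulatedPatient, outdir: str | Path) -> None:
    """Write mutation/segment TSVs, per-sample VCFs, and the truth JSON."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_mutation_tsv(patient.mutations, outdir / "mutations.tsv")
    _io.write_segment_tsv(patient.segments, outdir / "segments.tsv")
    _io.write_panel_tsv(patient.panel, outdir / "samples.tsv")
    for s in patient.panel.samples:
        sub = patient.mutations[patient.mutations["sample"] == s]
        _io.write_vcf(sub, outdir / f"{s}.vcf")
    truths = patient.component_truths or [patient.truth]
    payload = {
        "patient_id": patient.patient_id,
        "components": [t.to_dict() for t in truths],
    }
    (outdir / "truth.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n")
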