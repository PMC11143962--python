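"""End-to-end orchestration: filter -> CCF -> cluster -> tree -> disseminate.

``run_patient`` is a pure function of its inputs and parameters: rerunning
with the same configuration reproduces byte-identical reports.  Mutations
are discovered per sample with the somatic filters, unioned across the
patient's samples (joint-calling semantics), and genotyped everywhere from
the raw read counts so that presence at low prevalence still informs the
CCF matrix.  When the full multi-sample tree enumeration fails, the
pipeline retries with polyclonal-origin handling (splitting site groups
that share no mutations), then falls back to per-site-pair models and a
greedy tree, flagging the patient as pairwise-modeled.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clustering, dissemination, phylogeny, prevalence, simdata, variants
from .core import CloneTree, ModelFailureError, SamplePanel
from .dissemination import DisseminationReport

logger = logging.getLogger("clonedisperse")


@dataclass
class PipelineParams:
    """Every tunable of the analysis stages, with defaults."""

    target_megabases: float = 50.0
    ccf_cap: float = 1.5
    clonal_threshold: float = 0.9
    min_cluster_size: int = 3
    k_max: int = 12
    merge_distance: float = 0.10
    duplicate_merge_distance: float = 0.06
    tree_tolerance: float = 0.05
    root_threshold: float = 0.9
    presence_threshold: float = 0.02
    direction_margin: float = 0.05
    rescue_min_alt: float = 2.0
    rescue_min_vaf: float = 0.01
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PatientResult:
    report: DisseminationReport
    tree: Optional[CloneTree]
    clusters: list
    dropped: list[str]
    ccf_table: pd.DataFrame
    clonality: pd.DataFrame
    tmb: list[variants.TmbSummary]


def run_patient(
    mutations: pd.DataFrame,
    segments: pd.DataFrame,
    panel: SamplePanel,
    params: Optional[PipelineParams] = None,
) -> PatientResult:
    """Run the six analysis stages for one patient."""
    params = params or PipelineParams()
    logger.info("patient %s: %d samples, params %s",
                panel.patient_id, len(panel.samples), params)

    # 1. Somatic discovery per sample; union across the patient.
    ccf_table = prevalence.build_ccf_table(
        mutations, segments, panel.purity,
        ccf_cap=params.ccf_cap,
        clonal_threshold=params.clonal_threshold,
        rescue_min_alt=params.rescue_min_alt,
        rescue_min_vaf=params.rescue_min_vaf,
    )
    discovered = set(ccf_table.loc[ccf_table["passed"], "key"])
    logger.info("patient %s: %d discovered mutations", panel.patient_id,
                len(discovered))
    if not discovered:
        raise ModelFailureError(
            f"patient {panel.patient_id}: no somatic mutation passed filtering")
    ccf_table = ccf_table[ccf_table["key"].isin(discovered)].reset_index(drop=True)

    # Per-sample mutation burden of discovery-grade calls.
    tmb = [
        variants.compute_tmb(
            ccf_table[(ccf_table["sample"] == s) & ccf_table["passed"]],
            params.target_megabases, sample_id=s)
        for s in panel.samples
    ]

    # 2. Sample-wise clonality states summarized patient-wise.
    clonality = prevalence.summarize_patient_clonality(ccf_table)

    # 3. Polyclonal-origin screen on filtered calls.
    site_muts = {
        site: set(ccf_table[(ccf_table["sample"].isin(panel.samples_of_site(site)))
                            & ccf_table["passed"]]["key"])
        for site in panel.sites
    }
    origin_model, site_groups = dissemination.detect_polyclonal_origin(site_muts)

    if origin_model == dissemination.POLYCLONAL_ORIGIN:
        return _run_polyclonal(ccf_table, panel, params, site_groups,
                               clonality, tmb)

    report, tree, clusters, dropped = _model_component(
        ccf_table, panel, panel.samples, params, origin_model)
    return PatientResult(report, tree, clusters, dropped, ccf_table,
                         clonality, tmb)


def _model_component(
    ccf_table: pd.DataFrame,
    panel: SamplePanel,
    samples: list[str],
    params: PipelineParams,
    origin_model: str,
):
    """Cluster, build the clone tree, and classify one cancer component."""
    sub = ccf_table[ccf_table["sample"].isin(samples)]
    present_keys = set(sub.loc[sub["present"], "key"])
    sub = sub[sub["key"].isin(present_keys)]
    matrix = clustering.ccf_matrix_from_table(sub)[samples]

    clusters, dropped = clustering.cluster_mutations(
        matrix,
        k_max=params.k_max,
        seed=params.seed,
        min_cluster_size=params.min_cluster_size,
        merge_distance=params.merge_distance,
        duplicate_merge_distance=params.duplicate_merge_distance,
    )
    prev = pd.DataFrame(
        {c.cluster_id: clustering.mean_cluster_prevalence(c) for c in clusters}
    ).T
    muts = {c.cluster_id: c.members for c in clusters}
    site_of = {s: panel.site_of[s] for s in samples}

    pairwise = False
    try:
        trees = phylogeny.enumerate_trees(
            prev, muts, tolerance=params.tree_tolerance,
            root_threshold=params.root_threshold)
        if not trees:
            raise ModelFailureError("no sum-rule-consistent tree")
        tree, _ = phylogeny.select_model(
            trees, dissemination_count=lambda t: len(
                dissemination.designate_clones(
                    t, site_of, params.presence_threshold).disseminated))
    except ModelFailureError as err:
        logger.warning("patient %s: full model failed (%s); "
                       "falling back to pairwise/greedy modeling",
                       panel.patient_id, err)
        tree = phylogeny.greedy_tree(
            prev, muts, tolerance=params.tree_tolerance,
            root_threshold=params.root_threshold)
        pairwise = True

    report = dissemination.build_report(
        panel.patient_id, tree, site_of,
        origin_model=origin_model,
        presence_threshold=params.presence_threshold,
        direction_margin=params.direction_margin,
        pairwise_modeled=pairwise,
    )
    return report, tree, clusters, dropped


def _run_polyclonal(
    ccf_table: pd.DataFrame,
    panel: SamplePanel,
    params: PipelineParams,
    site_groups: list[list[str]],
    clonality: pd.DataFrame,
    tmb: list,
) -> PatientResult:
    """Model each mutation-sharing site group as its own cancer."""
    subreports, best = [], None
    for group in site_groups:
        samples = [s for s in panel.samples if panel.site_of[s] in group]
        rep, tree, clusters, dropped = _model_component(
            ccf_table, panel, samples, params,
            dissemination.POLYCLONAL_ORIGIN)
        subreports.append(rep)
        if best is None or len(group) > best[0]:
            best = (len(group), rep, tree, clusters, dropped)
    _, head, tree, clusters, dropped = best
    report = dataclasses.replace(
        head,
        origin_model=dissemination.POLYCLONAL_ORIGIN,
        subreports=subreports,
    )
    return PatientResult(report, tree, clusters, dropped, ccf_table,
                         clonality, tmb)


def run_simulated_patient(
    patient: simdata.SimulatedPatient, params: Optional[PipelineParams] = None
) -> PatientResult:
    return run_patient(patient.mutations, patient.segments, patient.panel,
                       params)


# ---------------------------------------------------------------------------
# cohort


def summarize_cohort(
    reports: list[DisseminationReport],
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort medians with bootstrap percentile 95% CIs.

    Patients without the relevant quantity (e.g. no dissemination, or no
    monophyletic interval) are excluded from that row's median; the ``n``
    column records how many contributed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))

    def stat(name, values):
        values = np.asarray([v for v in values if v is not None], dtype=float)
        if len(values) == 0:
            return {"statistic": name, "n": 0, "median": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan}
        boots = np.median(
            rng.choice(values, size=(n_boot, len(values)), replace=True), axis=1)
        return {
            "statistic": name, "n": len(values),
            "median": float(np.median(values)),
            "ci_low": float(np.percentile(boots, 2.5)),
            "ci_high": float(np.percentile(boots, 97.5)),
        }

    frac_diss = [
        len(r.disseminated) / r.n_clones if r.n_clones else None
        for r in reports
    ]
    rows = [
        stat("clones_per_cancer", [r.n_clones for r in reports]),
        stat("fraction_clones_disseminated", frac_diss),
        stat("first_dissemination_mutation_time",
             [r.first_dissemination_time for r in reports]),
        stat("monophyletic_interval",
             [r.interval for r in reports
              if r.interval_method == "monophyletic_span"
              and r.mode == dissemination.MONOPHYLETIC]),
        stat("polyphyletic_interval",
             [r.interval for r in reports
              if r.interval_method == "polyphyletic_unique_fraction"]),
    ]
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Cohort run configuration (simulation settings plus all parameters)."""

    n_patients: int = 23
    seed: int = 0
    noise: str = "binomial"
    include_polyclonal_origin: bool = True
    mutations_per_clone_mean: float = 50.0
    params: PipelineParams = field(default_factory=PipelineParams)
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        params = PipelineParams.from_dict(data.pop("params", {}))
        return cls(params=params, **data)


def run_cohort(config: RunConfig) -> tuple[list[PatientResult], pd.DataFrame]:
    """Simulate and analyze a cohort, writing reports under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = dataclasses.replace(config.params, seed=config.seed)
    patients = simdata.simulate_cohort(
        n_patients=config.n_patients,
        seed=config.seed,
        noise=config.noise,
        include_polyclonal_origin=config.include_polyclonal_origin,
        mutations_per_clone_mean=config.mutations_per_clone_mean,
    )
    results = []
    for p in patients:
        res = run_simulated_patient(p, params)
        results.append(res)
        (outdir / f"{p.patient_id}.report.json").write_text(
            res.report.to_json() + "\n")
    table = pd.DataFrame([_flat_report(r.report) for r in results])
    table.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    summary = summarize_cohort([r.report for r in results], seed=config.seed)
    summary.to_csv(outdir / "cohort_summary.tsv", sep="\t", index=False)
    return results, summary


def _flat_report(r: DisseminationReport) -> dict:
    return {
        "patient_id": r.patient_id,
        "mode": r.mode,
        "origin_model": r.origin_model,
        "n_clones": r.n_clones,
        "n_disseminated": len(r.disseminated),
        "n_local": len(r.local),
        "first_dissemination_time": r.first_dissemination_time,
        "last_dissemination_time": r.last_dissemination_time,
        "interval": r.interval,
        "interval_method": r.interval_method,
        "directions": ";".join(
            f"{k}:{v}" for k, v in sorted(r.directions.items())),
        "pairwise_modeled": r.pairwise_modeled,
    }
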