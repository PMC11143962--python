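"""Cancer-cell-fraction estimation and sample-wise clonality states.

The cancer cell fraction (CCF) of a mutation is its allele fraction
corrected for tumor purity and the local copy-number state:

    ccf = vaf * (purity * CN_total + (1 - purity) * 2) / (purity * m)

where ``m`` is the multiplicity, the number of mutated allele copies per
cancer cell.  Multiplicity is estimated deterministically as the value in
``1..CN_major`` whose expected clonal allele fraction lies nearest the
observed one (falling back to 1 outside a tolerance band).

Timing states follow the usual copy-gain logic: a clonal mutation on a
gained segment with multiplicity >= 2 predates the gain (clonal_early), one
with multiplicity 1 postdates it (clonal_late); without a gain the gain
clock is uninformative (clonal_NA).  Mutations below the clonal CCF
threshold are subclonal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import ConfigurationError
from .variants import somatic_pass_mask

DEFAULT_CCF_CAP = 1.5
DEFAULT_CLONAL_THRESHOLD = 0.9
DEFAULT_MULTIPLICITY_TOL = 0.15
LOH_TOLERANCE = 0.01

CLONAL_EARLY = "clonal_early"
CLONAL_LATE = "clonal_late"
CLONAL_NA = "clonal_NA"
SUBCLONAL = "subclonal"


def compute_ccf(vaf, purity, cn_total, multiplicity, cap: float = DEFAULT_CCF_CAP):
    """Purity- and copy-number-adjusted cancer cell fraction, capped."""
    purity = np.asarray(purity, dtype=float)
    if np.any(purity <= 0) or np.any(purity > 1):
        raise ValueError("purity must lie in (0, 1]")
    vaf = np.asarray(vaf, dtype=float)
    cn_total = np.asarray(cn_total, dtype=float)
    multiplicity = np.asarray(multiplicity, dtype=float)
    ccf = vaf * (purity * cn_total + (1.0 - purity) * 2.0) / (purity * multiplicity)
    out = np.minimum(ccf, cap)
    return float(out) if out.ndim == 0 else out


def expected_clonal_vaf(purity, cn_total, multiplicity):
    """Allele fraction expected for a fully clonal mutation (CCF = 1)."""
    purity = np.asarray(purity, dtype=float)
    cn_total = np.asarray(cn_total, dtype=float)
    multiplicity = np.asarray(multiplicity, dtype=float)
    out = purity * multiplicity / (purity * cn_total + (1.0 - purity) * 2.0)
    return float(out) if out.ndim == 0 else out


def estimate_multiplicity(
    vaf: float,
    purity: float,
    cn_total: float,
    cn_major: float,
    tolerance: float = DEFAULT_MULTIPLICITY_TOL,
) -> int:
    """Nearest-expectation multiplicity estimate (ties favor the smaller m)."""
    m_max = max(1, int(round(cn_major)))
    candidates = np.arange(1, m_max + 1)
    exp = expected_clonal_vaf(purity, cn_total, candidates)
    dist = np.abs(np.asarray(exp) - vaf)
    best = int(candidates[int(np.argmin(dist))])  # argmin takes the first tie
    if dist.min() > tolerance:
        return 1
    return best


def estimate_multiplicity_array(vaf, purity, cn_total, cn_major,
                                tolerance: float = DEFAULT_MULTIPLICITY_TOL):
    vaf = np.asarray(vaf, dtype=float)
    out = np.ones(vaf.shape, dtype=int)
    purity = np.broadcast_to(np.asarray(purity, dtype=float), vaf.shape)
    cn_total = np.broadcast_to(np.asarray(cn_total, dtype=float), vaf.shape)
    cn_major = np.broadcast_to(np.asarray(cn_major, dtype=float), vaf.shape)
    for i in range(vaf.size):
        out.flat[i] = estimate_multiplicity(
            vaf.flat[i], purity.flat[i], cn_total.flat[i], cn_major.flat[i],
            tolerance)
    return out


# ---------------------------------------------------------------------------
# copy-number calls


def weighted_median_cn(segments: pd.DataFrame) -> float:
    """Length-weighted median total copy number of one sample's segments."""
    lengths = (segments["end"] - segments["start"] + 1).to_numpy(float)
    cn = segments["cn_total"].to_numpy(float)
    order = np.argsort(cn)
    cn, lengths = cn[order], lengths[order]
    cum = np.cumsum(lengths)
    return float(cn[np.searchsorted(cum, cum[-1] / 2.0)])


def call_aberrations(cn_total, sample_median: float):
    """Median-centered aberration call: gain above, loss below the median."""
    cn = np.asarray(cn_total, dtype=float)
    centered = cn - sample_median
    out = np.where(centered > 0, "gain", np.where(centered < 0, "loss", "neutral"))
    return str(out) if out.ndim == 0 else out


def call_loh(cn_minor, tolerance: float = LOH_TOLERANCE):
    """LOH when the minor allele copy number is zero (within rounding)."""
    out = np.abs(np.asarray(cn_minor, dtype=float)) <= tolerance
    return bool(out) if out.ndim == 0 else out


def assign_timing(
    ccf: float,
    multiplicity: int,
    cn_major: float,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
) -> str:
    """Clonal(early/late/NA) vs subclonal state for one mutation-sample."""
    if ccf < clonal_threshold:
        return SUBCLONAL
    if cn_major >= 2:
        return CLONAL_EARLY if multiplicity >= 2 else CLONAL_LATE
    return CLONAL_NA


# ---------------------------------------------------------------------------
# segment lookup and table construction


class SegmentIndex:
    """Locus -> segment lookup per (sample, chromosome)."""

    def __init__(self, segments: pd.DataFrame) -> None:
        self._by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, pd.DataFrame]] = {}
        for (sample, chrom), grp in segments.groupby(["sample", "chrom"], sort=False):
            grp = grp.sort_values("start")
            self._by_key[(str(sample), str(chrom))] = (
                grp["start"].to_numpy(int), grp["end"].to_numpy(int), grp
            )

    def lookup(self, sample: str, chrom: str, pos: int) -> Optional[pd.Series]:
        entry = self._by_key.get((str(sample), str(chrom)))
        if entry is None:
            return None
        starts, ends, grp = entry
        i = np.searchsorted(starts, pos, side="right") - 1
        if i < 0 or pos > ends[i]:
            return None
        return grp.iloc[i]


def build_ccf_table(
    mutations: pd.DataFrame,
    segments: pd.DataFrame,
    purity: Mapping[str, float],
    ccf_cap: float = DEFAULT_CCF_CAP,
    clonal_threshold: float = DEFAULT_CLONAL_THRESHOLD,
    rescue_min_alt: float = 2.0,
    rescue_min_vaf: float = 0.01,
) -> pd.DataFrame:
    """Per-(mutation, sample) CCF estimates with timing and presence flags.

    ``passed`` marks discovery-grade somatic calls; ``present`` is the more
    sensitive rescue rule used for presence/absence testing across samples
    (>= ``rescue_min_alt`` supporting reads at VAF >= ``rescue_min_vaf``).
    Loci outside all segments get a diploid 2:1 no-call default.
    """
    idx = SegmentIndex(segments)
    df = mutations.copy()
    df["key"] = (df["chrom"].astype(str) + ":" + df["pos"].astype(str)
                 + ":" + df["ref"] + ":" + df["alt"])
    with np.errstate(divide="ignore", invalid="ignore"):
        df["vaf"] = np.where(df["t_depth"] > 0,
                             df["t_alt"] / df["t_depth"].clip(lower=1e-300), 0.0)
    cn_total = np.full(len(df), 2.0)
    cn_minor = np.full(len(df), 1.0)
    covered = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        seg = idx.lookup(row.sample, str(row.chrom), int(row.pos))
        if seg is None:
            covered[i] = False
            continue
        cn_total[i] = float(seg["cn_total"])
        cn_minor[i] = float(seg["cn_minor"])
    df["cn_total"] = cn_total
    df["cn_minor"] = cn_minor
    df["cn_major"] = cn_total - cn_minor
    df["segment_covered"] = covered

    pur = df["sample"].map(dict(purity)).to_numpy(float)
    if np.isnan(pur).any():
        missing = sorted(df.loc[np.isnan(pur), "sample"].unique())
        raise ConfigurationError(f"no purity for samples: {missing}")
    df["purity"] = pur
    df["multiplicity"] = estimate_multiplicity_array(
        df["vaf"], pur, df["cn_total"], df["cn_major"])
    df["ccf"] = compute_ccf(df["vaf"], pur, df["cn_total"], df["multiplicity"],
                            cap=ccf_cap)
    df["timing"] = [
        assign_timing(c, m, mj, clonal_threshold)
        for c, m, mj in zip(df["ccf"], df["multiplicity"], df["cn_major"])
    ]
    mq = df["mapping_quality_ok"] if "mapping_quality_ok" in df else True
    df["passed"] = somatic_pass_mask(
        df["t_depth"], df["t_alt"], df["n_depth"], df["n_alt"], mq)
    df["present"] = df["passed"] | (
        (df["t_alt"] >= rescue_min_alt) & (df["vaf"] >= rescue_min_vaf))
    return df


def summarize_patient_clonality(ccf_table: pd.DataFrame) -> pd.DataFrame:
    """Patient-level clonal/subclonal call per mutation.

    A mutation is *clonal* when it is clonal in at least one sample and
    detected (present) in every sample of the patient; anything else is
    subclonal.  The result is invariant to sample ordering.
    """
    clonal_states = {CLONAL_EARLY, CLONAL_LATE, CLONAL_NA}
    n_samples = ccf_table["sample"].nunique()
    rows = []
    for key, grp in ccf_table.groupby("key", sort=True):
        clonal_any = grp["timing"].isin(clonal_states).any()
        present_all = (grp["present"].sum() == n_samples
                       and grp["sample"].nunique() == n_samples)
        rows.append({
            "key": key,
            "patient_state": "clonal" if (clonal_any and present_all) else "subclonal",
            "n_samples_present": int(grp["present"].sum()),
            "n_samples_clonal": int(grp["timing"].isin(clonal_states).sum()),
        })
    return pd.DataFrame(rows).set_index("key")


def gene_category_counts(
    ccf_table: pd.DataFrame, gene_of: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene tallies of clonality categories, counted once per sample.

    Genes with several nonsilent mutations contribute one count per
    category per sample, matching how recurrence is usually tabulated.
    """
    df = ccf_table.copy()
    df["gene"] = df["key"].map(dict(gene_of))
    df = df.dropna(subset=["gene"])
    dedup = df.drop_duplicates(subset=["gene", "sample", "timing"])
    return (dedup.groupby(["gene", "timing"]).size()
            .unstack(fill_value=0))
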