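"""Tumor-normal somatic filtering, germline filtering, and mutation burden.

Somatic candidates pass through one of two acceptance routes:

* the standard rule: >= 15x coverage in both tumor and matched normal,
  tumor allele fraction >= 5%, normal allele fraction < 1%;
* a relaxed high-depth rule that accommodates deep sequencing (and possible
  circulating tumor cells in blood): tumor fraction >= 15% at >= 100x in
  both samples, normal fraction up to 5% (inclusive), and a tumor fraction
  at least 4x (inclusive) the normal fraction.

Zero-depth loci never pass.  Tumor mutation burden (TMB) is the count of
nonsilent passing mutations per megabase of target territory; samples above
12 mutations per megabase are flagged as hypermutated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .core import KNOWN_EFFECTS, NONSILENT_EFFECTS, ConfigurationError, MutationCall

HYPERMUTATION_TMB = 12.0
DEFAULT_TARGET_MEGABASES = 50.0


@dataclass(frozen=True)
class TmbSummary:
    sample_id: str
    nonsilent_count: int
    target_megabases: float
    tmb: float
    hypermutated: bool


def somatic_pass_mask(
    t_depth, t_alt, n_depth, n_alt, mapping_quality_ok=True
) -> np.ndarray:
    """Vectorized somatic filter; returns a boolean pass mask."""
    t_depth = np.asarray(t_depth, dtype=float)
    t_alt = np.asarray(t_alt, dtype=float)
    n_depth = np.asarray(n_depth, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    mq = np.broadcast_to(np.asarray(mapping_quality_ok, dtype=bool), t_depth.shape)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_vaf = np.where(t_depth > 0, t_alt / np.maximum(t_depth, 1e-300), 0.0)
        n_vaf = np.where(n_depth > 0, n_alt / np.maximum(n_depth, 1e-300), 0.0)

    standard = (
        (t_depth >= 15) & (n_depth >= 15) & (t_vaf >= 0.05) & (n_vaf < 0.01)
    )
    relaxed = (
        (t_depth >= 100) & (n_depth >= 100) & (t_vaf >= 0.15)
        & (n_vaf <= 0.05) & (t_vaf >= 4.0 * n_vaf)
    )
    return mq & (t_depth > 0) & (n_depth > 0) & (standard | relaxed)


def apply_somatic_filters(
    calls: Union[Sequence[MutationCall], pd.DataFrame],
) -> Union[list[MutationCall], pd.DataFrame]:
    """Return the calls passing the somatic filter (same container kind)."""
    if isinstance(calls, pd.DataFrame):
        mq = calls["mapping_quality_ok"] if "mapping_quality_ok" in calls else True
        mask = somatic_pass_mask(
            calls["t_depth"], calls["t_alt"], calls["n_depth"], calls["n_alt"], mq
        )
        return calls.loc[mask]
    mask = [
        bool(somatic_pass_mask(c.t_depth, c.t_alt, c.n_depth, c.n_alt,
                               c.mapping_quality_ok))
        for c in calls
    ]
    return [c for c, ok in zip(calls, mask) if ok]


def germline_pass_mask(depth, alt) -> np.ndarray:
    """Germline filter: >= 10x coverage, >= 5 variant reads, VAF >= 5%."""
    depth = np.asarray(depth, dtype=float)
    alt = np.asarray(alt, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1e-300), 0.0)
    return (depth >= 10) & (alt >= 5) & (vaf >= 0.05)


def apply_germline_filters(
    calls: Union[Sequence[tuple], pd.DataFrame],
    depth_col: str = "depth",
    alt_col: str = "alt_reads",
):
    """Filter normal-sample variant records ((depth, alt) pairs or a frame)."""
    if isinstance(calls, pd.DataFrame):
        return calls.loc[germline_pass_mask(calls[depth_col], calls[alt_col])]
    return [c for c in calls if bool(germline_pass_mask(c[0], c[1]))]


def classify_nonsilent(effect: str) -> bool:
    """True for effects that alter the protein product or splicing."""
    if effect is None or (isinstance(effect, float) and np.isnan(effect)):
        raise ValueError("mutation has no functional annotation")
    if effect not in KNOWN_EFFECTS:
        raise ValueError(f"unknown effect annotation {effect!r}")
    return effect in NONSILENT_EFFECTS


def compute_tmb(
    calls: Union[Iterable[MutationCall], pd.DataFrame],
    target_megabases: float = DEFAULT_TARGET_MEGABASES,
    sample_id: str = "",
) -> TmbSummary:
    """Mutation burden of an already-filtered call set."""
    if target_megabases <= 0:
        raise ConfigurationError("target_megabases must be positive")
    if isinstance(calls, pd.DataFrame):
        effects = calls["effect"]
        n = int(effects.isin(NONSILENT_EFFECTS).sum())
        if not sample_id and "sample" in calls and len(calls):
            uniq = calls["sample"].unique()
            sample_id = uniq[0] if len(uniq) == 1 else ""
    else:
        calls = list(calls)
        n = sum(classify_nonsilent(c.effect) for c in calls)
        if not sample_id and calls:
            ids = {c.sample_id for c in calls}
            sample_id = ids.pop() if len(ids) == 1 else ""
    tmb = n / target_megabases
    return TmbSummary(sample_id, n, target_megabases, tmb,
                      hypermutated=tmb > HYPERMUTATION_TMB)
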