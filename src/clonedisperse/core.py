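"""Core data containers shared across the pipeline.

The central object is :class:`CloneTree`, a rooted tree of tumor clones in
which every node carries a private somatic-mutation set and, once assigned,
a cellular-prevalence vector over the sequenced samples.  Cellular prevalence
is *inclusive*: the prevalence of a clone counts every cell belonging to the
clone or any of its descendants, so along every branch the prevalences of a
node's children can never add up to more than the node's own prevalence (the
sum, or pigeonhole, rule of clonal ordering).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from typing import Any, Optional

import pandas as pd

#: Functional annotations counted as nonsilent when computing mutation burden.
NONSILENT_EFFECTS = frozenset(
    {"missense", "nonsense", "stoploss", "frameshift_indel", "splice_site"}
)

#: All recognised functional annotations.
KNOWN_EFFECTS = NONSILENT_EFFECTS | {"synonymous", "inframe_indel", "other"}


class ConfigurationError(ValueError):
    """Raised for invalid or contradictory configuration values."""


class ModelFailureError(RuntimeError):
    """Raised when no clonality model consistent with the data exists."""


@dataclass(frozen=True)
class MutationCall:
    """One somatic candidate at a locus in one tumor sample.

    Read counts are stored for the tumor sample and the patient-matched
    normal (blood) sample.  Counts may be fractional: the noise-free
    simulator emits exact expected counts so that allele fractions
    back-transform to clone prevalences without rounding error.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    t_depth: float
    t_alt: float
    n_depth: float
    n_alt: float
    effect: str = "other"
    mapping_quality_ok: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.t_alt > self.t_depth or self.n_alt > self.n_depth:
            raise ValueError("alt count exceeds depth")
        if min(self.t_depth, self.t_alt, self.n_depth, self.n_alt) < 0:
            raise ValueError("negative read count")

    @property
    def key(self) -> str:
        """Locus identifier shared by the same variant across samples."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def t_vaf(self) -> float:
        return self.t_alt / self.t_depth if self.t_depth > 0 else 0.0

    @property
    def n_vaf(self) -> float:
        return self.n_alt / self.n_depth if self.n_depth > 0 else 0.0


@dataclass(frozen=True)
class CopyNumberSegment:
    """Allele-specific copy-number call over a 1-based inclusive interval."""

    chrom: str
    start: int
    end: int
    cn_total: float
    cn_minor: float
    sample_id: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end precedes start")
        if self.cn_minor > self.cn_total / 2 + 0.01:
            raise ValueError("minor copy number exceeds half the total")

    @property
    def cn_major(self) -> float:
        return self.cn_total - self.cn_minor


@dataclass
class SamplePanel:
    """A patient's sequenced samples with site labels and purity estimates.

    Bilateral ovarian tumors and ascites count as separate anatomical sites.
    """

    patient_id: str
    samples: list[str]
    site_of: dict[str, str]
    purity: dict[str, float]

    def __post_init__(self) -> None:
        for s in self.samples:
            if s not in self.site_of:
                raise ConfigurationError(f"sample {s!r} has no site label")
            if s not in self.purity:
                raise ConfigurationError(f"sample {s!r} has no purity estimate")
            if not 0 < self.purity[s] <= 1:
                raise ConfigurationError(
                    f"purity of {s!r} must be in (0, 1], got {self.purity[s]}"
                )

    @property
    def sites(self) -> list[str]:
        """Unique site labels in first-appearance order."""
        seen: list[str] = []
        for s in self.samples:
            site = self.site_of[s]
            if site not in seen:
                seen.append(site)
        return seen

    def samples_of_site(self, site: str) -> list[str]:
        return [s for s in self.samples if self.site_of[s] == site]


class CloneTree:
    """Rooted tree of clones with private mutation sets and prevalences.

    Parameters
    ----------
    parent
        Mapping from clone id to parent id; exactly one clone (the root)
        maps to ``None``.
    mutations
        Mapping from clone id to the clone's *private* mutation keys.
    prevalence
        Optional cellular-prevalence matrix (rows: clone ids, columns:
        sample ids) in [0, 1].
    meta
        Free-form annotations (e.g. simulation ground-truth bookkeeping).
    """

    def __init__(
        self,
        parent: Mapping[Any, Any],
        mutations: Optional[Mapping[Any, Iterable[str]]] = None,
        prevalence: Optional[pd.DataFrame] = None,
        meta: Optional[dict] = None,
    ) -> None:
        self.parent: dict[Any, Any] = dict(parent)
        roots = [u for u, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for u, p in self.parent.items():
            if p is not None and p not in self.parent:
                raise ValueError(f"parent {p!r} of {u!r} is not a node")
        self._root = roots[0]
        self._check_acyclic()
        mutations = mutations or {}
        self.mutations: dict[Any, frozenset[str]] = {
            u: frozenset(mutations.get(u, ())) for u in self.parent
        }
        if prevalence is not None:
            missing = set(self.parent) - set(prevalence.index)
            if missing:
                raise ValueError(f"prevalence missing clones: {sorted(missing)}")
            prevalence = prevalence.loc[sorted(self.parent, key=str)]
        self.prevalence = prevalence
        self.meta: dict = dict(meta or {})

    # -- topology ---------------------------------------------------------

    def _check_acyclic(self) -> None:
        for u in self.parent:
            seen = {u}
            v = self.parent[u]
            while v is not None:
                if v in seen:
                    raise ValueError(f"cycle through node {u!r}")
                seen.add(v)
                v = self.parent[v]

    @property
    def root(self) -> Any:
        return self._root

    @property
    def nodes(self) -> list[Any]:
        return sorted(self.parent, key=str)

    def __len__(self) -> int:
        return len(self.parent)

    def children(self, u: Any) -> list[Any]:
        return [v for v in self.nodes if self.parent[v] == u]

    def ancestors(self, u: Any) -> list[Any]:
        """Path from the root down to ``u``, inclusive."""
        path = [u]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def is_ancestor(self, a: Any, b: Any) -> bool:
        """True when ``a`` is a strict ancestor of ``b``."""
        v = self.parent[b]
        while v is not None:
            if v == a:
                return True
            v = self.parent[v]
        return False

    def on_one_lineage(self, a: Any, b: Any) -> bool:
        return a == b or self.is_ancestor(a, b) or self.is_ancestor(b, a)

    @property
    def n_branching(self) -> int:
        """Number of nodes with two or more children."""
        return sum(1 for u in self.nodes if len(self.children(u)) >= 2)

    def parent_map_key(self) -> tuple:
        """Canonical, hashable representation of the topology."""
        return tuple(sorted((str(u), str(p)) for u, p in self.parent.items()))

    # -- mutation accounting ---------------------------------------------

    def private_count(self, u: Any) -> int:
        return len(self.mutations[u])

    def cumulative_count(self, u: Any) -> int:
        """Mutations accumulated along the lineage from the root to ``u``."""
        return sum(len(self.mutations[v]) for v in self.ancestors(u))

    def lineage_mutations(self, u: Any) -> frozenset[str]:
        out: set[str] = set()
        for v in self.ancestors(u):
            out |= self.mutations[v]
        return frozenset(out)

    @property
    def total_mutations(self) -> int:
        return sum(len(m) for m in self.mutations.values())

    def clone_of_mutation(self) -> dict[str, Any]:
        return {k: u for u, ms in self.mutations.items() for k in ms}

    # -- constraints ------------------------------------------------------

    def sum_rule_violations(self, tolerance: float = 0.0) -> list[tuple]:
        """Return (clone, sample, excess) triples violating the sum rule."""
        if self.prevalence is None:
            raise ValueError("tree has no prevalence matrix")
        out = []
        for u in self.nodes:
            kids = self.children(u)
            if not kids:
                continue
            total = self.prevalence.loc[kids].sum(axis=0)
            excess = total - self.prevalence.loc[u]
            for sample, e in excess.items():
                if e > tolerance + 1e-12:
                    out.append((u, sample, float(e)))
        return out

    # -- export -----------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "root": str(self.root),
            "parent": {str(u): (None if p is None else str(p))
                       for u, p in sorted(self.parent.items(), key=lambda x: str(x[0]))},
            "n_private_mutations": {str(u): len(self.mutations[u]) for u in self.nodes},
        }
        if self.prevalence is not None:
            d["prevalence"] = {
                str(u): {str(s): round(float(v), 6)
                         for s, v in self.prevalence.loc[u].items()}
                for u in self.nodes
            }
        return d

    def to_newick(self) -> str:
        def fmt(u: Any) -> str:
            kids = self.children(u)
            label = f"{u}[&&n_mut={len(self.mutations[u])}]"
            if not kids:
                return str(label)
            return "(" + ",".join(fmt(v) for v in kids) + ")" + str(label)

        return fmt(self.root) + ";"

    def copy(self) -> "CloneTree":
        return CloneTree(
            dict(self.parent),
            {u: set(m) for u, m in self.mutations.items()},
            None if self.prevalence is None else self.prevalence.copy(),
            dict(self.meta),
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"CloneTree(n={len(self)}, root={self.root!r}, "
                f"mutations={self.total_mutations})")
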