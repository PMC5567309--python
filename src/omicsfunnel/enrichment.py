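"""Pathway over-representation analysis of an integrated protein set.

For a universe of N genes, a pathway with K members and an input set of n
genes, the overlap count k is scored with the exact hypergeometric upper
tail P(X >= k) — the probability of seeing at least as many pathway members
in a random n-subset.  Raw p-values are Bonferroni-corrected over the
pathways actually tested (those reaching the minimum overlap).  A two-sided
Fisher exact option is provided for parity with tools that report a
"two-sided hypergeometric" statistic; retention semantics here are always
enrichment, so the upper tail is the default.

Downstream utilities: coverage percentages (100·k/K, the per-pathway
statistic of enrichment reports), removal of pathways judged irrelevant to
the disease under study, collapsing of pathways that share an ultimate
parent term into one group, and overlap comparison between two analysis
arms (e.g. with and without plasma-protein exclusion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .integration import IntegratedProteinSet, integrate


@dataclass(frozen=True)
class PathwayGeneSet:
    pathway_id: str
    name: str
    members: frozenset[str]
    parent_id: Optional[str] = None

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")
        if self.parent_id == self.pathway_id:
            raise ValueError(f"pathway {self.pathway_id!r} is its own parent")

    @property
    def size(self) -> int:
        return len(self.members)


def pathways_from_gmt(sets: Iterable[tuple[str, str, list[str]]], hierarchy: dict[str, str] | None = None):
    hierarchy = hierarchy or {}
    return [
        PathwayGeneSet(pathway_id=pid, name=desc, members=frozenset(members), parent_id=hierarchy.get(pid))
        for pid, desc, members in sets
    ]


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    Evaluated through the log-space survival function, so deep tails do not
    underflow to zero prematurely.
    """
    _check_margins(k, K, n, N)
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); exact and stable for these integer margins
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def fisher_two_sided(k: int, K: int, n: int, N: int) -> float:
    """Two-sided Fisher exact p for the same margins (parity option)."""
    _check_margins(k, K, n, N)
    table = [[k, n - k], [K - k, N - K - (n - k)]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _check_margins(k, K, n, N):
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"impossible margins: K={K}, n={n}, N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}, N={N}")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as used in printed coverage columns."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EnrichmentResult:
    pathway: PathwayGeneSet
    k: int
    n: int
    N: int
    overlap_up: set[str]
    overlap_down: set[str]
    p_raw: float
    p_adj: float = 1.0
    significant: bool = False
    m_tested: int = 0

    @property
    def pathway_id(self) -> str:
        return self.pathway.pathway_id

    @property
    def K(self) -> int:
        return self.pathway.size

    @property
    def coverage_pct(self) -> float:
        """Raw 100·k/K; use :func:`round_half_up` for report formatting."""
        return 100.0 * self.k / self.K

    @property
    def overlap_genes(self) -> set[str]:
        return self.overlap_up | self.overlap_down


def enrich_pathways(
    input_set: IntegratedProteinSet,
    db: Sequence[PathwayGeneSet],
    universe: set[str] | None = None,
    min_overlap: int = 3,
    alpha: float = 0.05,
    laterality: str = "upper",
) -> list[EnrichmentResult]:
    """Test every pathway with at least ``min_overlap`` input hits.

    The universe defaults to all genes appearing in at least one pathway of
    the database; input genes outside the universe are dropped from n (and
    counted via a warning) as in standard over-representation practice.
    Bonferroni correction multiplies by the number of pathways actually
    tested, recorded on each result as ``m_tested``.
    """
    if not input_set.members:
        raise ValueError("input set is empty")
    if not db:
        raise ValueError("pathway database is empty")
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    if laterality not in ("upper", "two-sided"):
        raise ValueError(f"laterality must be 'upper' or 'two-sided', got {laterality!r}")

    if universe is None:
        universe = set().union(*(p.members for p in db))
    else:
        universe = set(universe)
        outside = [p.pathway_id for p in db if not p.members <= universe]
        if outside:
            raise ValueError(f"pathways with members outside the universe: {outside[:5]}")

    in_universe = {g: d for g, d in input_set.members.items() if g in universe}
    dropped = len(input_set.members) - len(in_universe)
    if dropped:
        warnings.warn(f"{dropped} input genes outside the universe were excluded from testing")
    if not in_universe:
        raise ValueError("no input genes lie in the analysis universe")

    n, N = len(in_universe), len(universe)
    test = hypergeometric_upper_tail if laterality == "upper" else fisher_two_sided

    results = []
    for pw in db:
        overlap = pw.members & in_universe.keys()
        if len(overlap) < min_overlap:
            continue
        up = {g for g in overlap if in_universe[g] == "up"}
        results.append(
            EnrichmentResult(
                pathway=pw,
                k=len(overlap),
                n=n,
                N=N,
                overlap_up=up,
                overlap_down=set(overlap) - up,
                p_raw=test(len(overlap), pw.size, n, N),
            )
        )
    m = len(results)
    for r in results:
        r.m_tested = m
        r.p_adj = min(1.0, r.p_raw * m)
        r.significant = r.p_adj < alpha
    results.sort(key=lambda r: (r.p_raw, r.pathway_id))
    return results


def apply_relevance_exclusion(
    results: Sequence[EnrichmentResult], excluded_ids: set[str]
) -> list[EnrichmentResult]:
    """Drop pathways judged irrelevant to the disease; order preserved."""
    known = {r.pathway_id for r in results}
    unknown = set(excluded_ids) - known
    if unknown:
        warnings.warn(f"exclusion ids not among tested pathways: {sorted(unknown)[:5]}")
    return [r for r in results if r.pathway_id not in excluded_ids]


@dataclass
class PathwayGroup:
    """Pathways collapsed onto their ultimate parent term."""

    group_id: str
    name: str
    pathway_ids: set[str]
    members: set[str]
    overlap_up: set[str]
    overlap_down: set[str]
    best_p_adj: float

    @property
    def overlap_genes(self) -> set[str]:
        return self.overlap_up | self.overlap_down


def resolve_root(pathway_id: str, hierarchy: dict[str, str]) -> str:
    """Follow child→parent links to the ultimate ancestor; reject cycles."""
    seen = {pathway_id}
    node = pathway_id
    while node in hierarchy:
        node = hierarchy[node]
        if node in seen:
            raise ValueError(f"cycle in pathway hierarchy at {node!r}")
        seen.add(node)
    return node


def merge_parent_groups(
    results: Sequence[EnrichmentResult], hierarchy: dict[str, str]
) -> list[PathwayGroup]:
    """Combine pathways sharing the same ultimate parent into one group.

    Group membership and overlaps are unions over the collapsed pathways;
    the group keeps the smallest adjusted p among them.  With an empty
    hierarchy every pathway is its own group.
    """
    groups: dict[str, PathwayGroup] = {}
    order: list[str] = []
    names = {r.pathway_id: r.pathway.name for r in results}
    for r in results:
        root = resolve_root(r.pathway_id, hierarchy)
        if root not in groups:
            groups[root] = PathwayGroup(
                group_id=root,
                name=names.get(root, root),
                pathway_ids=set(),
                members=set(),
                overlap_up=set(),
                overlap_down=set(),
                best_p_adj=1.0,
            )
            order.append(root)
        g = groups[root]
        g.pathway_ids.add(r.pathway_id)
        g.members |= r.pathway.members
        g.overlap_up |= r.overlap_up
        g.overlap_down |= r.overlap_down
        g.best_p_adj = min(g.best_p_adj, r.p_adj)
    return [groups[root] for root in order]


@dataclass
class ApproachComparison:
    pathways_a: set[str]
    pathways_b: set[str]

    @property
    def shared(self) -> set[str]:
        return self.pathways_a & self.pathways_b

    @property
    def union_size(self) -> int:
        return len(self.pathways_a | self.pathways_b)

    @property
    def overlap_pct(self) -> float:
        return 100.0 * len(self.shared) / self.union_size

    def to_json(self) -> dict:
        return {
            "n_a": len(self.pathways_a),
            "n_b": len(self.pathways_b),
            "shared": sorted(self.shared),
            "union_size": self.union_size,
            "overlap_pct": round_half_up(self.overlap_pct, 2),
        }


def compare_approaches(a: set[str], b: set[str]) -> ApproachComparison:
    """Jaccard-style overlap percentage between two retained-pathway sets."""
    if not a and not b:
        raise ValueError("both approaches retained nothing; overlap undefined")
    return ApproachComparison(pathways_a=set(a), pathways_b=set(b))


def enrich_single_datasets(
    study_records: dict[str, list],
    db: Sequence[PathwayGeneSet],
    integrated_significant: set[str],
    universe: set[str] | None = None,
    min_overlap: int = 3,
    alpha: float = 0.05,
    laterality: str = "upper",
) -> tuple[dict[str, list[EnrichmentResult]], dict]:
    """Enrich each study on its own and diff against the integrated run.

    Studies whose lists are too small for any pathway to reach the minimum
    overlap yield empty result lists and are flagged as having insufficient
    identifications rather than raising.
    """
    per_study: dict[str, list[EnrichmentResult]] = {}
    insufficient: list[str] = []
    for sid in sorted(study_records):
        recs = study_records[sid]
        if not recs:
            per_study[sid] = []
            insufficient.append(sid)
            continue
        single = integrate(recs)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = enrich_pathways(single, db, universe, min_overlap, alpha, laterality)
        except ValueError:
            # nothing testable (e.g. no study gene inside the universe)
            results = []
        per_study[sid] = results
        if not results:
            insufficient.append(sid)

    significant_by_study = {
        sid: {r.pathway_id for r in res if r.significant} for sid, res in per_study.items()
    }
    any_single = set().union(*significant_by_study.values()) if significant_by_study else set()
    report = {
        "insufficient_identifications": insufficient,
        "integration_only": sorted(set(integrated_significant) - any_single),
        "single_only": sorted(any_single - set(integrated_significant)),
        "significant_per_study": {sid: sorted(v) for sid, v in significant_by_study.items()},
    }
    return per_study, report


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Report table: one row per pathway, coverage rounded half-up."""
    rows = [
        (
            r.pathway_id,
            r.pathway.name,
            r.k,
            r.K,
            f"{round_half_up(r.coverage_pct, 2):.2f}",
            r.p_raw,
            r.p_adj,
            r.significant,
            ",".join(sorted(r.overlap_up)),
            ",".join(sorted(r.overlap_down)),
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id",
            "name",
            "n_genes",
            "pathway_size",
            "coverage_pct",
            "p_raw",
            "p_adj",
            "significant",
            "genes_up",
            "genes_down",
        ],
    )
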