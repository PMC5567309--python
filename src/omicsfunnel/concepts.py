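"""Concept-association analysis.

A "concept" is a precomputed gene signature — the top 1, 5 or 10 percent of
over- or under-expressed genes from a differential-expression comparison.
The pathway-expanded protein set is tested against each concept through a
2×2 contingency table over the analysis universe:

    a = predicted ∩ concept      b = predicted \\ concept
    c = concept \\ predicted      d = neither

scored by the cross-product odds ratio (Haldane-corrected when a cell is
zero) and a two-sided Fisher exact p-value.  Concepts pass when the odds
ratio and both p thresholds are met and at least ``min_overlap`` genes are
shared; genes in any retained concept form the next funnel stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

TIERS = (1, 5, 10)


@dataclass(frozen=True)
class Concept:
    concept_id: str
    description: str
    members: frozenset[str]
    tier: Optional[int] = None
    direction: Optional[str] = None

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"concept {self.concept_id!r} has no members")
        if self.tier is not None and self.tier not in TIERS:
            raise ValueError(f"concept tier must be one of {TIERS}, got {self.tier!r}")


def parse_concept_metadata(description: str) -> tuple[Optional[int], Optional[str]]:
    """Parse ``tier=<1|5|10>;direction=<up|down>`` out of a GMT description."""
    tier = direction = None
    for part in description.split(";"):
        key, _, value = part.partition("=")
        if key.strip() == "tier" and value.strip().isdigit():
            tier = int(value.strip())
        elif key.strip() == "direction":
            direction = value.strip() or None
    return tier, direction


def concepts_from_gmt(sets: Iterable[tuple[str, str, list[str]]]) -> list[Concept]:
    out = []
    for cid, desc, members in sets:
        tier, direction = parse_concept_metadata(desc)
        if tier is None or direction is None:
            warnings.warn(f"concept {cid!r} lacks tier/direction metadata; accepted as provenance-only")
        out.append(Concept(concept_id=cid, description=desc, members=frozenset(members), tier=tier, direction=direction))
    return out


def build_contingency(predicted: set[str], concept: Concept, universe: set[str]) -> tuple[int, int, int, int]:
    """2×2 cells over the universe; concept members outside it are dropped."""
    if not universe:
        raise ValueError("universe is empty")
    predicted = set(predicted)
    if not predicted <= universe:
        raise ValueError("predicted set contains genes outside the universe")
    concept_in = set(concept.members) & universe
    outside = len(concept.members) - len(concept_in)
    if outside:
        warnings.warn(f"concept {concept.concept_id!r}: {outside} members outside the universe were dropped")
    a = len(predicted & concept_in)
    b = len(predicted) - a
    c = len(concept_in) - a
    d = len(universe) - a - b - c
    return a, b, c, d


def odds_ratio(a: int, b: int, c: int, d: int, correction: str = "haldane") -> float:
    """Cross-product ratio (a·d)/(b·c).

    With ``correction='haldane'`` 0.5 is added to every cell whenever any
    cell is zero.  Without correction a zero denominator yields ``inf``
    (or ``nan`` when the numerator is zero too), with a warning.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be nonnegative")
    if correction not in ("haldane", "none"):
        raise ValueError(f"correction must be 'haldane' or 'none', got {correction!r}")
    if correction == "haldane" and 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    if b * c == 0:
        warnings.warn("odds ratio denominator is zero; result is not finite")
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: total probability of tables with the same
    margins at most as likely as the observed one."""
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("contingency table is all zeros")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def hypergeom_upper_tail_table(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail alternative P(X >= a) for the same table (parity option)."""
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be nonnegative")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


@dataclass
class ConceptAssociationResult:
    concept: Concept
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    overlap_genes: set[str]
    passes: bool = False

    @property
    def concept_id(self) -> str:
        return self.concept.concept_id


def associate_concepts(
    predicted: set[str],
    concepts: Sequence[Concept],
    universe: set[str],
    statistic: str = "fisher",
) -> list[ConceptAssociationResult]:
    """Score every concept against the predicted set (no selection yet)."""
    if statistic not in ("fisher", "upper"):
        raise ValueError(f"statistic must be 'fisher' or 'upper', got {statistic!r}")
    test = fisher_exact_two_sided if statistic == "fisher" else hypergeom_upper_tail_table
    results = []
    for concept in concepts:
        a, b, c, d = build_contingency(predicted, concept, universe)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            orr = odds_ratio(a, b, c, d, correction="haldane")
        results.append(
            ConceptAssociationResult(
                concept=concept,
                a=a,
                b=b,
                c=c,
                d=d,
                odds_ratio=orr,
                p_value=test(a, b, c, d),
                overlap_genes=set(predicted) & set(concept.members),
            )
        )
    return results


def select_concepts(
    results: Sequence[ConceptAssociationResult],
    or_min: float = 2.0,
    p_run: float = 1e-4,
    p_retain: float = 0.05,
    min_overlap: int = 3,
) -> list[ConceptAssociationResult]:
    """Apply the association thresholds conjunctively; sort retained by p.

    ``p_run`` is the analysis-setting threshold and ``p_retain`` the
    retention threshold; both are applied (the stricter binds) since their
    interplay is configurable.
    """
    if min(or_min, p_run, p_retain) <= 0 or min_overlap < 0:
        raise ValueError("thresholds must be positive")
    retained = []
    for r in results:
        r.passes = (
            r.odds_ratio >= or_min and r.p_value <= p_run and r.p_value < p_retain and r.a >= min_overlap
        )
        if r.passes:
            retained.append(r)
    return sorted(retained, key=lambda r: (r.p_value, r.concept_id))


def concept_hit_union(retained: Sequence[ConceptAssociationResult], predicted: set[str]) -> set[str]:
    """Genes of the predicted set appearing in any retained concept."""
    hits: set[str] = set()
    for r in retained:
        hits |= r.overlap_genes
    return hits & set(predicted)


def results_to_frame(results: Sequence[ConceptAssociationResult]) -> pd.DataFrame:
    rows = [
        (
            r.concept_id,
            r.concept.tier if r.concept.tier is not None else "",
            r.concept.direction or "",
            r.a,
            r.b,
            r.c,
            r.d,
            r.odds_ratio,
            r.p_value,
            ",".join(sorted(r.overlap_genes)),
            r.passes,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["concept_id", "tier", "direction", "a", "b", "c", "d", "odds_ratio", "p_value", "overlap_genes", "passes"],
    )
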