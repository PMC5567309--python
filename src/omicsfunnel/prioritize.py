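"""Candidate shortlisting: pathway expansion and the filter cascade.

Significant pathway groups are expanded to their member proteins that were
NOT part of the analysis input — these "predicted" proteins are the
candidate pool.  Each then passes through an ordered cascade of per-gene
predicates, mirroring a classification tree for validation-candidate
selection:

1. concept hit        — appears in a retained transcriptomics concept;
2. tissue expression  — immunohistochemistry-style evidence in the target
                        tissue (genes without any table row are dropped);
3. structural         — more than one high-confidence protein interaction
                        with co-members of its own pathway group(s), and/or
                        membership in more than one group;
4. functional keyword — annotation text matches at least one of the
                        configured functional categories.

Every gene keeps a full trace of each stage's decision, and the funnel
report records survivor counts per stage (non-increasing by construction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .enrichment import PathwayGroup
from .integration import IntegratedProteinSet
from .keywords import DEFAULT_KEYWORDS

logger = logging.getLogger(__name__)

STAGES = ("predicted", "concept_hit", "kidney_expressed", "structural", "functional")


@dataclass(frozen=True)
class PPIEdge:
    """Undirected scored interaction, stored with endpoints in sorted order."""

    gene_a: str
    gene_b: str
    score: float

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-interaction {self.gene_a!r} is not allowed")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score!r}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


@dataclass
class CandidateTrace:
    gene: str
    source_pathways: set[str]
    in_input: bool = False
    concept_hit: bool = False
    kidney_expressed: bool = False
    ppi_degree: int = 0
    pathway_count: int = 0
    structural_pass: bool = False
    keyword_categories: set[str] = field(default_factory=set)
    final_candidate: bool = False


def edges_from_frame(df: pd.DataFrame) -> list[PPIEdge]:
    return [PPIEdge(str(r.gene_a), str(r.gene_b), float(r.score)) for r in df.itertuples(index=False)]


def expand_pathway_members(
    groups: Sequence[PathwayGroup], input_set: IntegratedProteinSet
) -> dict[str, set[str]]:
    """Predicted genes: union of group members minus the analysis input.

    Returns gene → set of source group ids.
    """
    if not groups:
        raise ValueError("no retained pathway groups to expand")
    predicted: dict[str, set[str]] = {}
    input_genes = input_set.genes
    for g in groups:
        for gene in g.members:
            if gene not in input_genes:
                predicted.setdefault(gene, set()).add(g.group_id)
    return predicted


def expression_filter(genes: set[str], expression: pd.DataFrame, tissue: str = "kidney") -> set[str]:
    """Keep genes with detected evidence in ``tissue``.

    Genes absent from the table count as having no evidence and are dropped
    (logged), never imputed.
    """
    tissues = set(expression["tissue"])
    if tissue not in tissues:
        raise ValueError(f"tissue {tissue!r} not present in expression table (has {sorted(tissues)})")
    sub = expression[expression["tissue"] == tissue]
    detected = set(sub.loc[sub["detected"].astype(int) == 1, "gene"])
    covered = set(sub["gene"])
    for gene in sorted(set(genes) - covered):
        logger.info("expression: gene %s has no evidence in %s; dropped", gene, tissue)
    return set(genes) & detected


def build_ppi_graph(edges: Sequence[PPIEdge], min_score: float = 0.9) -> nx.Graph:
    """Graph of interactions at or above the confidence cutoff."""
    if not (0.0 <= min_score <= 1.0):
        raise ValueError(f"min_score must lie in [0, 1], got {min_score!r}")
    graph = nx.Graph()
    for e in edges:
        if e.score >= min_score:
            if graph.has_edge(e.gene_a, e.gene_b):
                graph[e.gene_a][e.gene_b]["score"] = max(graph[e.gene_a][e.gene_b]["score"], e.score)
            else:
                graph.add_edge(e.gene_a, e.gene_b, score=e.score)
    return graph


def ppi_degree_in_pathways(
    gene: str,
    graph: nx.Graph,
    pathway_comembers: set[str],
    global_degree: bool = False,
) -> int:
    """Distinct high-confidence partners of ``gene``.

    By default only partners co-occurring in one of the gene's own pathway
    groups count ("pertinent" interactions); ``global_degree=True`` counts
    all partners in the network instead.
    """
    if gene not in graph:
        return 0
    partners = set(graph.neighbors(gene))
    if not global_degree:
        partners &= pathway_comembers
    partners.discard(gene)
    return len(partners)


def structural_filter(ppi_degree: int, pathway_count: int) -> bool:
    """Pass when the gene forms >1 pertinent interaction and/or sits in >1
    pathway group (inclusive or)."""
    return ppi_degree > 1 or pathway_count > 1


def keyword_screen(
    genes: set[str],
    annotations: Mapping[str, str],
    categories: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, set[str]]:
    """Case-insensitive substring match of category keywords against each
    gene's annotation text; unannotated genes match nothing (logged)."""
    if categories is None:
        categories = DEFAULT_KEYWORDS
    if not categories:
        raise ValueError("keyword category map is empty")
    matched: dict[str, set[str]] = {}
    for gene in sorted(genes):
        text = annotations.get(gene)
        if text is None:
            logger.info("keywords: gene %s has no annotation; treated as no match", gene)
            matched[gene] = set()
            continue
        low = text.lower()
        matched[gene] = {
            cat for cat, words in categories.items() if any(w.lower() in low for w in words)
        }
    return matched


@dataclass
class FunnelReport:
    stage_counts: dict[str, int]
    drop_reasons: dict[str, str]
    parameters: dict

    def to_json(self) -> dict:
        return {
            "stages": [{"stage": s, "count": self.stage_counts[s]} for s in STAGES],
            "drop_reasons": self.drop_reasons,
            "parameters": self.parameters,
        }


def run_funnel(
    groups: Sequence[PathwayGroup],
    input_set: IntegratedProteinSet,
    concept_hits: set[str],
    expression: pd.DataFrame,
    edges: Sequence[PPIEdge],
    annotations: Mapping[str, str],
    tissue: str = "kidney",
    min_score: float = 0.9,
    categories: Mapping[str, Sequence[str]] | None = None,
    global_degree: bool = False,
) -> tuple[list[CandidateTrace], FunnelReport]:
    """Run the full cascade and emit per-gene traces plus the funnel report.

    ``concept_hits`` is the union of overlap genes of retained concepts
    (already restricted to the predicted set by the concepts stage).
    """
    predicted = expand_pathway_members(groups, input_set)
    members_by_group = {g.group_id: g.members for g in groups}
    graph = build_ppi_graph(edges, min_score)

    expressed = expression_filter(set(predicted), expression, tissue)
    keyword_matches = keyword_screen(set(predicted), annotations, categories)

    traces: list[CandidateTrace] = []
    for gene in sorted(predicted):
        source = predicted[gene]
        comembers = set().union(*(members_by_group[gid] for gid in source)) - {gene}
        degree = ppi_degree_in_pathways(gene, graph, comembers, global_degree)
        trace = CandidateTrace(
            gene=gene,
            source_pathways=source,
            in_input=False,
            concept_hit=gene in concept_hits,
            kidney_expressed=gene in expressed,
            ppi_degree=degree,
            pathway_count=len(source),
            structural_pass=structural_filter(degree, len(source)),
            keyword_categories=keyword_matches[gene],
        )
        trace.final_candidate = (
            trace.concept_hit
            and trace.kidney_expressed
            and trace.structural_pass
            and bool(trace.keyword_categories)
        )
        traces.append(trace)

    s0 = set(predicted)
    s1 = {t.gene for t in traces if t.concept_hit}
    s2 = {t.gene for t in traces if t.gene in s1 and t.kidney_expressed}
    s3 = {t.gene for t in traces if t.gene in s2 and t.structural_pass}
    s4 = {t.gene for t in traces if t.gene in s3 and t.keyword_categories}
    report = FunnelReport(
        stage_counts=dict(zip(STAGES, (len(s0), len(s1), len(s2), len(s3), len(s4)))),
        drop_reasons={
            "concept_hit": "not in any retained concept signature",
            "kidney_expressed": "no detected expression evidence in target tissue",
            "structural": "<=1 pertinent interaction and <=1 pathway group",
            "functional": "no functional-category keyword matched",
        },
        parameters={"tissue": tissue, "min_score": min_score, "global_degree": global_degree},
    )
    return traces, report


def traces_to_frame(traces: Sequence[CandidateTrace]) -> pd.DataFrame:
    rows = [
        (
            t.gene,
            ",".join(sorted(t.source_pathways)),
            t.in_input,
            t.concept_hit,
            t.kidney_expressed,
            t.ppi_degree,
            t.pathway_count,
            t.structural_pass,
            ",".join(sorted(t.keyword_categories)),
            t.final_candidate,
        )
        for t in traces
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "source_pathways",
            "in_input",
            "concept_hit",
            "kidney_expressed",
            "ppi_degree",
            "pathway_count",
            "structural_pass",
            "keyword_categories",
            "final_candidate",
        ],
    )
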