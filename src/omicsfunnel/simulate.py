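"""Synthetic input bundles with planted ground truth.

The generator emulates the statistical shape of a multi-study urinary
proteomics integration exercise: several study lists drawn from a common
gene universe with a controlled direction-conflict rate, a pathway database
with a handful of "disease" pathways whose members are over-represented in
the study lists, transcriptomics concepts overlapping those pathways, a
sparse confidence-scored protein interaction network that is denser inside
the planted pathways, a tissue-expression table and free-text functional
annotations.  Every file is derived from one seeded generator, so a fixed
:class:`SimulationConfig` reproduces the bundle byte for byte.

A :class:`GroundTruthManifest` records what was planted, so downstream
recovery (enrichment, concept retention, funnel survival) can be scored
without any external database.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .keywords import DEFAULT_KEYWORDS, NEUTRAL_PHRASES

BUNDLE_FILES = {
    "studies": "studies.tsv",
    "universe": "universe.txt",
    "pathways": "pathways.gmt",
    "hierarchy": "hierarchy.tsv",
    "concepts": "concepts.gmt",
    "ppi": "ppi.tsv",
    "expression": "expression.tsv",
    "annotations": "annotations.tsv",
    "plasma": "plasma_exclusion.txt",
    "irrelevant": "irrelevant_pathways.txt",
    "manifest": "manifest.json",
}

#: fraction of the universe present in the expression / annotation tables;
#: the shortfall exercises the "no evidence -> dropped" path downstream.
EXPRESSION_TABLE_PRESENCE = 0.97
ANNOTATION_TABLE_PRESENCE = 0.95
#: background genes occasionally carry a relevant-sounding phrase (decoys).
DECOY_KEYWORD_RATE = 0.05
#: planted relevant genes chosen per planted pathway.
RELEVANT_PER_PATHWAY = 3


class ConfigError(ValueError):
    """A SimulationConfig field failed validation; the message names it."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate a nine-study integration at a reduced universe of
    2000 genes: a 70/30 down/up regulation skew, an exclusion list covering
    roughly a fifth of the input, and a conflict rate that flips a handful
    of the genes shared between studies (a few per bundle, as in small
    multi-study panels).
    """

    universe_size: int = 2000
    n_studies: int = 9
    study_detection_rate: float = 0.015
    conflict_rate: float = 0.2
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 60)
    n_planted_pathways: int = 5
    planting_strength: float = 0.6
    n_concepts: int = 12
    n_disease_concepts: int = 5
    concept_overlap_strength: float = 0.5
    ppi_within_density: float = 0.25
    ppi_background_density: float = 0.001
    ppi_score_range: tuple[float, float] = (0.4, 1.0)
    expression_coverage: float = 0.7
    keyword_hit_rate: float = 0.9
    down_fraction: float = 0.7
    plasma_rate: float = 0.18
    seed: int = 0

    def validate(self) -> None:
        def _fraction(name: str) -> None:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")

        for name in (
            "study_detection_rate",
            "conflict_rate",
            "planting_strength",
            "concept_overlap_strength",
            "ppi_within_density",
            "ppi_background_density",
            "expression_coverage",
            "keyword_hit_rate",
            "down_fraction",
            "plasma_rate",
        ):
            _fraction(name)
        if self.universe_size < 10:
            raise ConfigError(f"universe_size must be >= 10, got {self.universe_size!r}")
        if self.n_studies < 2:
            raise ConfigError(
                f"n_studies must be >= 2 (direction conflicts are undefined otherwise), got {self.n_studies!r}"
            )
        lo, hi = self.pathway_size_range
        if lo < 3:
            raise ConfigError(f"pathway_size_range minimum must be >= 3, got {lo!r}")
        if lo > hi:
            raise ConfigError(f"pathway_size_range must be (min, max) with min <= max, got {self.pathway_size_range!r}")
        if hi > self.universe_size:
            raise ConfigError(f"pathway_size_range maximum {hi!r} exceeds universe_size {self.universe_size!r}")
        if self.n_pathways < 1:
            raise ConfigError(f"n_pathways must be >= 1, got {self.n_pathways!r}")
        if not (0 <= self.n_planted_pathways <= self.n_pathways):
            raise ConfigError(
                f"n_planted_pathways must lie in [0, n_pathways], got {self.n_planted_pathways!r}"
            )
        if not (0 <= self.n_disease_concepts <= self.n_concepts):
            raise ConfigError(
                f"n_disease_concepts must lie in [0, n_concepts], got {self.n_disease_concepts!r}"
            )
        slo, shi = self.ppi_score_range
        if not (0.0 <= slo <= shi <= 1.0):
            raise ConfigError(f"ppi_score_range must satisfy 0 <= min <= max <= 1, got {self.ppi_score_range!r}")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigError(f"seed must be a nonnegative integer, got {self.seed!r}")


@dataclass
class GroundTruthManifest:
    planted_pathway_ids: set[str] = field(default_factory=set)
    planted_relevant_genes: set[str] = field(default_factory=set)
    conflict_genes: set[str] = field(default_factory=set)
    plasma_like_genes: set[str] = field(default_factory=set)
    disease_concept_ids: set[str] = field(default_factory=set)

    def to_json(self) -> dict:
        return {k: sorted(v) for k, v in dataclasses.asdict(self).items()}

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruthManifest":
        return cls(**{f.name: set(obj.get(f.name, [])) for f in dataclasses.fields(cls)})


def gene_universe(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _sample(rng: np.random.Generator, pool: list[str], size: int) -> list[str]:
    """Deterministic sample without replacement from an ordered pool."""
    size = min(size, len(pool))
    if size == 0:
        return []
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[i] for i in sorted(idx)]


def generate_pathway_db(
    config: SimulationConfig, universe: list[str], rng: np.random.Generator
) -> tuple[list[tuple[str, str, list[str]]], dict[str, str], list[str]]:
    """Draw the pathway collection, its parent hierarchy and the planted ids.

    Planted pathways each receive 0–2 child pathways sharing at least half
    of their members, so parent-node merging has something to chew on.
    """
    lo, hi = config.pathway_size_range
    sets: list[tuple[str, str, list[str]]] = []
    for j in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = _sample(rng, universe, size)
        sets.append((f"P{j + 1:04d}", f"synthetic pathway {j + 1}", members))
    planted_idx = sorted(rng.choice(config.n_pathways, size=config.n_planted_pathways, replace=False))
    planted_ids = [sets[i][0] for i in planted_idx]

    hierarchy: dict[str, str] = {}
    for pid in planted_ids:
        parent_members = next(m for p, _, m in sets if p == pid)
        n_children = int(rng.integers(0, 3))
        for c in range(n_children):
            share = 0.5 + 0.4 * rng.random()
            child = _sample(rng, parent_members, max(3, round(share * len(parent_members))))
            extra = _sample(rng, [g for g in universe if g not in set(child)], int(rng.integers(0, 3)))
            cid = f"{pid}C{c + 1}"
            sets.append((cid, f"child of {pid}", sorted(set(child) | set(extra))))
            hierarchy[cid] = pid
    return sets, hierarchy, planted_ids


@dataclass
class StudyData:
    """Output of study-list generation: the tables plus bookkeeping."""

    tables: list[pd.DataFrame]
    conflict_genes: set[str]
    injected_genes: set[str]
    directions: dict[str, str]

    @property
    def all_genes(self) -> set[str]:
        return set().union(*(set(t["gene"]) for t in self.tables)) if self.tables else set()


def generate_study_datasets(
    config: SimulationConfig,
    universe: list[str],
    planted_members: set[str] | frozenset[str] = frozenset(),
    rng: np.random.Generator | None = None,
    excluded_genes: frozenset[str] = frozenset(),
) -> StudyData:
    """Draw per-study differential-protein tables.

    Each study detects a Bernoulli(study_detection_rate) subset of the
    universe; a planting_strength fraction of ``planted_members`` is then
    injected into one to three studies each.  A conflict_rate fraction of
    the non-planted genes shared by at least two studies is flipped to the
    opposite direction in one of its studies.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    if config.n_studies < 2:
        raise ConfigError(f"n_studies must be >= 2, got {config.n_studies!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    base_direction = {
        g: ("down" if u < config.down_fraction else "up")
        for g, u in zip(universe, rng.random(len(universe)))
    }

    eligible = [g for g in universe if g not in excluded_genes]
    study_sets: list[set[str]] = []
    for _ in range(config.n_studies):
        mask = rng.random(len(eligible)) < config.study_detection_rate
        study_sets.append({g for g, hit in zip(eligible, mask) if hit})

    planted_sorted = sorted(set(planted_members) - set(excluded_genes))
    injected = set(_sample(rng, planted_sorted, round(config.planting_strength * len(planted_sorted))))
    for g in sorted(injected):
        n_hits = int(rng.integers(1, min(3, config.n_studies) + 1))
        for s in rng.choice(config.n_studies, size=n_hits, replace=False):
            study_sets[int(s)].add(g)

    membership: dict[str, list[int]] = {}
    for s, genes in enumerate(study_sets):
        for g in genes:
            membership.setdefault(g, []).append(s)
    shared = sorted(g for g, ss in membership.items() if len(ss) >= 2 and g not in set(planted_sorted))
    conflict_genes = set(_sample(rng, shared, round(config.conflict_rate * len(shared))))
    flip_study = {
        g: int(membership[g][int(rng.integers(0, len(membership[g])))]) for g in sorted(conflict_genes)
    }

    opposite = {"up": "down", "down": "up"}
    tables = []
    for s, genes in enumerate(study_sets):
        rows = []
        for g in sorted(genes):
            direction = base_direction[g]
            if g in conflict_genes and flip_study[g] == s:
                direction = opposite[direction]
            log2fc = float(rng.uniform(0.5, 3.0))
            fc = round(2.0**log2fc if direction == "up" else 2.0**-log2fc, 4)
            pval = float(10.0 ** -rng.uniform(1.31, 6.0))
            rows.append((f"S{s + 1:02d}", g, direction, fc, round(pval, 8)))
        tables.append(pd.DataFrame(rows, columns=io.STUDY_COLUMNS))
    return StudyData(tables, conflict_genes, injected, base_direction)


def generate_bundle(config: SimulationConfig, out_dir) -> GroundTruthManifest:
    """Write a complete self-consistent input bundle and its ground truth.

    Files written (all plain text, names in :data:`BUNDLE_FILES`): the
    combined study table, the gene universe, pathway GMT plus hierarchy,
    concept GMT, scored PPI edge list, kidney expression table, functional
    annotations, the plasma-like exclusion list, an "irrelevant pathway"
    list, and the manifest JSON.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    universe = gene_universe(config.universe_size)
    pathway_sets, hierarchy, planted_ids = generate_pathway_db(config, universe, rng)
    members_by_id = {pid: set(m) for pid, _, m in pathway_sets}
    planted_union = sorted(set().union(*(members_by_id[p] for p in planted_ids)) if planted_ids else set())

    study = generate_study_datasets(config, universe, planted_members=set(planted_union), rng=rng)
    input_genes = study.all_genes

    # Relevant genes live in planted pathways but outside every study list,
    # so they can only surface through pathway expansion.
    relevant: set[str] = set()
    for pid in planted_ids:
        candidates = sorted(members_by_id[pid] - input_genes - relevant)
        relevant.update(_sample(rng, candidates, RELEVANT_PER_PATHWAY))

    plasma_pool = sorted(input_genes - set(planted_union) - study.conflict_genes)
    plasma = set(_sample(rng, plasma_pool, round(config.plasma_rate * len(input_genes))))

    concepts, disease_ids = _generate_concepts(config, universe, planted_union, relevant, rng)
    edges = _generate_ppi(config, universe, members_by_id, planted_ids, relevant, rng)
    expression = _generate_expression(config, universe, relevant, rng)
    annotations = _generate_annotations(config, universe, relevant, rng)

    nonplanted = [pid for pid, _, _ in pathway_sets if pid not in set(planted_ids) and pid not in hierarchy]
    irrelevant = _sample(rng, sorted(nonplanted), min(2, len(nonplanted)))

    io.write_study_table(out / BUNDLE_FILES["studies"], pd.concat(study.tables, ignore_index=True))
    io.write_gene_list(out / BUNDLE_FILES["universe"], universe)
    io.write_gmt(out / BUNDLE_FILES["pathways"], pathway_sets)
    io.write_hierarchy(out / BUNDLE_FILES["hierarchy"], hierarchy)
    io.write_gmt(out / BUNDLE_FILES["concepts"], concepts)
    edges_df = pd.DataFrame(
        [(a, b, round(sc, 4)) for (a, b), sc in sorted(edges.items())],
        columns=["gene_a", "gene_b", "score"],
    )
    edges_df.to_csv(out / BUNDLE_FILES["ppi"], sep="\t", index=False)
    expression.to_csv(out / BUNDLE_FILES["expression"], sep="\t", index=False)
    annotations.to_csv(out / BUNDLE_FILES["annotations"], sep="\t", index=False)
    io.write_gene_list(out / BUNDLE_FILES["plasma"], plasma)
    io.write_gene_list(out / BUNDLE_FILES["irrelevant"], irrelevant)

    manifest = GroundTruthManifest(
        planted_pathway_ids=set(planted_ids),
        planted_relevant_genes=relevant,
        conflict_genes=study.conflict_genes,
        plasma_like_genes=plasma,
        disease_concept_ids=set(disease_ids),
    )
    io.write_json(out / BUNDLE_FILES["manifest"], manifest.to_json())
    return manifest


def _generate_concepts(config, universe, planted_union, relevant, rng):
    """Disease concepts copy planted-pathway members (always including the
    planted relevant genes); background concepts are random draws sized by
    their tier (top 1/5/10% of a differential-expression comparison)."""
    concepts = []
    disease_ids = []
    tiers = (1, 5, 10)
    for i in range(config.n_concepts):
        tier = int(tiers[int(rng.integers(0, 3))])
        direction = "up" if rng.random() < 0.5 else "down"
        nominal = max(5, round(tier / 100 * config.universe_size))
        cid = f"C{i + 1:03d}"
        if i < config.n_disease_concepts:
            forced = set(
                _sample(rng, list(planted_union), round(config.concept_overlap_strength * len(planted_union)))
            )
            forced |= set(relevant)
            fill_pool = [g for g in universe if g not in forced]
            members = sorted(forced | set(_sample(rng, fill_pool, max(0, nominal - len(forced)))))
            disease_ids.append(cid)
            desc = f"tier={tier};direction={direction};cohort=disease-vs-control"
        else:
            members = _sample(rng, universe, nominal)
            desc = f"tier={tier};direction={direction};cohort=background"
        concepts.append((cid, desc, list(members)))
    return concepts, disease_ids


def _generate_ppi(config, universe, members_by_id, planted_ids, relevant, rng):
    """Edges dense inside planted pathways, sparse elsewhere; every planted
    relevant gene is wired to >=2 co-members at highest confidence."""
    lo, hi = config.ppi_score_range
    edges: dict[tuple[str, str], float] = {}

    def add(a: str, b: str, score: float) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        edges[key] = max(edges.get(key, 0.0), score)

    for pid in planted_ids:
        members = sorted(members_by_id[pid])
        n = len(members)
        for i in range(n):
            hits = rng.random(n - i - 1) < config.ppi_within_density
            scores = rng.uniform(lo, hi, n - i - 1)
            for j, (hit, sc) in enumerate(zip(hits, scores), start=i + 1):
                if hit:
                    add(members[i], members[j], float(sc))

    n_bg = round(config.ppi_background_density * config.universe_size * (config.universe_size - 1) / 2)
    if n_bg:
        ia = rng.integers(0, config.universe_size, size=n_bg)
        ib = rng.integers(0, config.universe_size, size=n_bg)
        scores = rng.uniform(lo, hi, n_bg)
        for a, b, sc in zip(ia, ib, scores):
            add(universe[int(a)], universe[int(b)], float(sc))

    gene_pathway = {}
    for pid in planted_ids:
        for g in members_by_id[pid]:
            gene_pathway.setdefault(g, pid)
    for g in sorted(relevant):
        partners = _sample(rng, sorted(members_by_id[gene_pathway[g]] - {g}), 2)
        for p in partners:
            add(g, p, float(rng.uniform(max(0.9, lo), 1.0)))
    return edges


def _generate_expression(config, universe, relevant, rng):
    rows = []
    present = rng.random(len(universe)) < EXPRESSION_TABLE_PRESENCE
    detected = rng.random(len(universe)) < config.expression_coverage
    for g, pres, det in zip(universe, present, detected):
        if g in relevant:
            rows.append((g, "kidney", 1))
        elif pres:
            rows.append((g, "kidney", int(det)))
    return pd.DataFrame(rows, columns=["gene", "tissue", "detected"])


def _generate_annotations(config, universe, relevant, rng):
    categories = sorted(DEFAULT_KEYWORDS)
    rows = []
    present = rng.random(len(universe)) < ANNOTATION_TABLE_PRESENCE
    for g, pres in zip(universe, present):
        draw = rng.random()
        neutral = NEUTRAL_PHRASES[int(rng.integers(0, len(NEUTRAL_PHRASES)))]
        cat = categories[int(rng.integers(0, len(categories)))]
        phrase = DEFAULT_KEYWORDS[cat][int(rng.integers(0, len(DEFAULT_KEYWORDS[cat])))]
        if g in relevant:
            if draw < config.keyword_hit_rate:
                text = f"Putative role in {phrase}; also linked to {neutral}."
            else:
                text = f"Uncharacterised protein linked to {neutral}."
            rows.append((g, text))
        elif pres:
            if draw < DECOY_KEYWORD_RATE:
                text = f"Reported association with {phrase}."
            else:
                text = f"Involved in {neutral}."
            rows.append((g, text))
    return pd.DataFrame(rows, columns=["gene", "text"])
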