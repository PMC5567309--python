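"""End-to-end orchestration of the prioritization workflow.

The pipeline chains: study-list integration (optionally a second arm with
plasma-like proteins excluded) → pathway over-representation in each arm →
relevance exclusion and arm comparison → parent-term grouping → pathway
expansion → concept association → the multi-step filter funnel.  Every
stage after the synthetic-data generator is deterministic, so repeated runs
on the same inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import concepts as concepts_mod
from . import enrichment, io, prioritize
from . import integration as integrate_mod
from .keywords import DEFAULT_KEYWORDS

APPROACHES = ("full", "no_plasma", "both")

OUTPUT_FILES = {
    "integrated": "integrated.tsv",
    "conflicts": "conflicts.tsv",
    "integrated_no_plasma": "integrated_no_plasma.tsv",
    "enrichment_full": "enrichment_full.tsv",
    "enrichment_no_plasma": "enrichment_no_plasma.tsv",
    "comparison": "approach_comparison.json",
    "groups": "pathway_groups.json",
    "single_dataset": "single_dataset_report.json",
    "concept_report": "concept_report.tsv",
    "concept_hits": "concept_hits.txt",
    "traces": "traces.tsv",
    "funnel": "funnel.json",
    "summary": "summary.json",
}


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths to the input bundle plus all stage parameters."""

    studies: str
    pathways: str
    concepts: str
    ppi: str
    expression: str
    annotations: str
    hierarchy: Optional[str] = None
    plasma_exclusion: Optional[str] = None
    pathway_exclusion: Optional[str] = None
    universe: Optional[str] = None
    # enrichment
    alpha: float = 0.05
    min_overlap: int = 3
    laterality: str = "upper"
    # concept association
    or_min: float = 2.0
    p_run: float = 1e-4
    p_retain: float = 0.05
    min_overlap_genes: int = 3
    # prioritization
    min_score: float = 0.9
    tissue: str = "kidney"
    keyword_config: Optional[str] = None
    global_degree: bool = False
    approach: str = "both"
    single_dataset_comparison: bool = True

    def validate(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}, got {self.approach!r}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        if self.min_overlap < 1 or self.min_overlap_genes < 1:
            raise ValueError("min_overlap / min_overlap_genes must be >= 1")
        if not (0.0 <= self.min_score <= 1.0):
            raise ValueError(f"min_score must lie in [0, 1], got {self.min_score!r}")
        for name in ("studies", "pathways", "concepts", "ppi", "expression", "annotations"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} input not found: {path}")

    @classmethod
    def from_bundle(cls, bundle_dir, **overrides) -> "PipelineConfig":
        """Point every path at a simulator bundle's standard file names."""
        from .simulate import BUNDLE_FILES

        b = Path(bundle_dir)
        cfg = cls(
            studies=str(b / BUNDLE_FILES["studies"]),
            pathways=str(b / BUNDLE_FILES["pathways"]),
            hierarchy=str(b / BUNDLE_FILES["hierarchy"]),
            concepts=str(b / BUNDLE_FILES["concepts"]),
            ppi=str(b / BUNDLE_FILES["ppi"]),
            expression=str(b / BUNDLE_FILES["expression"]),
            annotations=str(b / BUNDLE_FILES["annotations"]),
            plasma_exclusion=str(b / BUNDLE_FILES["plasma"]),
            pathway_exclusion=str(b / BUNDLE_FILES["irrelevant"]),
        )
        for key, value in overrides.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown pipeline option {key!r}")
            setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def load_keyword_config(path) -> dict[str, list[str]]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or not all(isinstance(v, list) for v in data.values()):
        raise ValueError(f"{path}: keyword config must map category -> list of phrases")
    return {str(k): [str(w) for w in v] for k, v in data.items()}


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage, write all reports under ``out_dir``, and return
    the summary dictionary (also written as ``summary.json``)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": _public_params(config)}

    # -- integration ------------------------------------------------------
    try:
        records = integrate_mod.read_study_records(config.studies)
        integrated = integrate_mod.integrate(records)
        integrated.write(out / OUTPUT_FILES["integrated"], out / OUTPUT_FILES["conflicts"])
        arm_inputs: dict[str, integrate_mod.IntegratedProteinSet] = {}
        if config.approach in ("full", "both"):
            arm_inputs["full"] = integrated
        if config.approach in ("no_plasma", "both"):
            if not config.plasma_exclusion or not Path(config.plasma_exclusion).exists():
                raise ValueError("approach 'no_plasma' requires a plasma exclusion list")
            plasma = io.read_gene_list(config.plasma_exclusion)
            no_plasma = integrate_mod.exclude_genes(integrated, plasma)
            no_plasma.write(out / OUTPUT_FILES["integrated_no_plasma"])
            arm_inputs["no_plasma"] = no_plasma
        n_total, n_up, n_down = integrated.counts
        summary["integration"] = {
            "n_records": len(records),
            "n_distinct_genes": n_total + len(integrated.conflicts),
            "n_members": n_total,
            "n_up": n_up,
            "n_down": n_down,
            "n_conflicts": len(integrated.conflicts),
        }
        if "no_plasma" in arm_inputs:
            np_total, np_up, np_down = arm_inputs["no_plasma"].counts
            summary["integration"]["n_members_no_plasma"] = np_total
            summary["integration"]["n_plasma_excluded"] = len(arm_inputs["no_plasma"].excluded)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("integration", exc) from exc

    # -- enrichment per arm ----------------------------------------------
    try:
        db = enrichment.pathways_from_gmt(
            io.read_gmt(config.pathways),
            io.read_hierarchy(config.hierarchy) if config.hierarchy and Path(config.hierarchy).exists() else {},
        )
        hierarchy = {p.pathway_id: p.parent_id for p in db if p.parent_id}
        universe = io.read_gene_list(config.universe) if config.universe else None
        pathway_excl = (
            io.read_gene_list(config.pathway_exclusion)
            if config.pathway_exclusion and Path(config.pathway_exclusion).exists()
            else set()
        )
        retained_by_arm: dict[str, list[enrichment.EnrichmentResult]] = {}
        significant_by_arm: dict[str, set[str]] = {}
        for arm, arm_input in arm_inputs.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = enrichment.enrich_pathways(
                    arm_input, db, universe, config.min_overlap, config.alpha, config.laterality
                )
                significant = [r for r in results if r.significant]
                retained = enrichment.apply_relevance_exclusion(significant, pathway_excl)
            retained_by_arm[arm] = retained
            significant_by_arm[arm] = {r.pathway_id for r in significant}
            key = "enrichment_full" if arm == "full" else "enrichment_no_plasma"
            enrichment.results_to_frame(results).to_csv(out / OUTPUT_FILES[key], sep="\t", index=False)
            summary[f"enrichment_{arm}"] = {
                "n_tested": len(results),
                "n_significant": len(significant),
                "n_retained": len(retained),
                "retained_ids": sorted(r.pathway_id for r in retained),
            }
        if len(retained_by_arm) == 2:
            comparison = enrichment.compare_approaches(
                {r.pathway_id for r in retained_by_arm["full"]},
                {r.pathway_id for r in retained_by_arm["no_plasma"]},
            )
            io.write_json(out / OUTPUT_FILES["comparison"], comparison.to_json())
            summary["approach_comparison"] = comparison.to_json()

        combined: dict[str, enrichment.EnrichmentResult] = {}
        for retained in retained_by_arm.values():
            for r in retained:
                combined.setdefault(r.pathway_id, r)
        groups = enrichment.merge_parent_groups(
            [combined[pid] for pid in sorted(combined)], hierarchy
        )
        io.write_json(
            out / OUTPUT_FILES["groups"],
            [
                {
                    "group_id": g.group_id,
                    "name": g.name,
                    "pathway_ids": sorted(g.pathway_ids),
                    "members": sorted(g.members),
                    "best_p_adj": g.best_p_adj,
                }
                for g in sorted(groups, key=lambda g: g.group_id)
            ],
        )
        summary["pathway_groups"] = {
            "n_pathways_combined": len(combined),
            "n_groups": len(groups),
            "group_ids": sorted(g.group_id for g in groups),
        }
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("enrichment", exc) from exc

    # -- single-dataset comparison ---------------------------------------
    if config.single_dataset_comparison and "full" in arm_inputs:
        try:
            by_study: dict[str, list] = {}
            for rec in records:
                by_study.setdefault(rec.study_id, []).append(rec)
            _, single_report = enrichment.enrich_single_datasets(
                by_study,
                db,
                significant_by_arm.get("full", set()),
                universe,
                config.min_overlap,
                config.alpha,
                config.laterality,
            )
            io.write_json(out / OUTPUT_FILES["single_dataset"], single_report)
            summary["single_dataset"] = {
                "n_studies": len(by_study),
                "n_insufficient": len(single_report["insufficient_identifications"]),
                "n_integration_only": len(single_report["integration_only"]),
                "n_single_only": len(single_report["single_only"]),
            }
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError("single_dataset", exc) from exc

    # -- expansion + concept association ---------------------------------
    try:
        expansion_input = arm_inputs.get("full", next(iter(arm_inputs.values())))
        predicted_map = prioritize.expand_pathway_members(groups, expansion_input)
        predicted = set(predicted_map)
        concept_sets = concepts_mod.concepts_from_gmt(io.read_gmt(config.concepts))
        concept_universe = universe if universe is not None else set().union(*(p.members for p in db))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assoc = concepts_mod.associate_concepts(predicted, concept_sets, concept_universe)
            retained_concepts = concepts_mod.select_concepts(
                assoc, config.or_min, config.p_run, config.p_retain, config.min_overlap_genes
            )
        hits = concepts_mod.concept_hit_union(retained_concepts, predicted)
        concepts_mod.results_to_frame(assoc).to_csv(out / OUTPUT_FILES["concept_report"], sep="\t", index=False)
        io.write_gene_list(out / OUTPUT_FILES["concept_hits"], hits)
        summary["concepts"] = {
            "n_concepts": len(concept_sets),
            "n_retained": len(retained_concepts),
            "retained_ids": sorted(r.concept_id for r in retained_concepts),
            "n_hit_union": len(hits),
        }
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("concepts", exc) from exc

    # -- funnel -----------------------------------------------------------
    try:
        categories = (
            load_keyword_config(config.keyword_config) if config.keyword_config else DEFAULT_KEYWORDS
        )
        traces, report = prioritize.run_funnel(
            groups,
            expansion_input,
            hits,
            io.read_expression_table(config.expression),
            prioritize.edges_from_frame(io.read_ppi_table(config.ppi)),
            io.read_annotation_table(config.annotations),
            tissue=config.tissue,
            min_score=config.min_score,
            categories=categories,
            global_degree=config.global_degree,
        )
        prioritize.traces_to_frame(traces).to_csv(out / OUTPUT_FILES["traces"], sep="\t", index=False)
        io.write_json(out / OUTPUT_FILES["funnel"], report.to_json())
        summary["funnel"] = {
            "stage_counts": report.stage_counts,
            "n_final": report.stage_counts["functional"],
            "final_candidates": sorted(t.gene for t in traces if t.final_candidate),
        }
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("prioritize", exc) from exc

    io.write_json(out / OUTPUT_FILES["summary"], summary)
    return summary


def _public_params(config: PipelineConfig) -> dict:
    params = dataclasses.asdict(config)
    return {k: v for k, v in sorted(params.items())}
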