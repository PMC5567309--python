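import pytest

from omicsfunnel import (
    DifferentialProteinRecord,
    IntegratedProteinSet,
    PathwayGeneSet,
    SimulationConfig,
    generate_bundle,
)
from omicsfunnel.pipeline import PipelineConfig


def make_records(*triples, **kwargs):
    """Shorthand: triples of (study_id, gene, direction)."""
    return [DifferentialProteinRecord(s, g, d, **kwargs) for s, g, d in triples]


def make_input_set(members: dict[str, str]) -> IntegratedProteinSet:
    return IntegratedProteinSet(members=dict(members), support={g: {"S1"} for g in members})


def make_pathway(pid: str, members, parent=None) -> PathwayGeneSet:
    return PathwayGeneSet(pathway_id=pid, name=pid, members=frozenset(members), parent_id=parent)


def small_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast bundle configuration used across tests."""
    base = dict(
        universe_size=400,
        n_studies=5,
        study_detection_rate=0.02,
        n_pathways=15,
        pathway_size_range=(8, 25),
        n_planted_pathways=3,
        n_concepts=8,
        n_disease_concepts=3,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def strong_effect_config(seed: int) -> SimulationConfig:
    """Fixture with planted signal strong enough for full recovery."""
    return SimulationConfig(
        universe_size=800,
        n_studies=9,
        study_detection_rate=0.01,
        n_pathways=30,
        pathway_size_range=(15, 40),
        n_planted_pathways=4,
        planting_strength=0.8,
        n_concepts=10,
        n_disease_concepts=4,
        concept_overlap_strength=0.6,
        keyword_hit_rate=1.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """One default-size bundle shared by read-only tests."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = generate_bundle(SimulationConfig(seed=11), out)
    return out, manifest


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory):
    """A full run-all pass over the shared bundle."""
    from omicsfunnel import run_all

    bdir, manifest = bundle_dir
    out = tmp_path_factory.mktemp("run")
    summary = run_all(PipelineConfig.from_bundle(bdir), out)
    return bdir, manifest, out, summary
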