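"""Shared fixtures: a small fast dataset for unit tests and the full
default fixture (1 Mb genome, 48 libraries x 50,000 reads) for the
acceptance suite.  Everything is generated programmatically at test time."""

from __future__ import annotations

import pytest

from srna_gxe.pipeline import RunConfig, Workspace, run
from srna_gxe.sequence_io import SampleInfo
from srna_gxe.synthetic_data import GenerationConfig, generate_genome, simulate_libraries


def small_factor_design() -> list[SampleInfo]:
    return [
        SampleInfo(v, c, s, r)
        for v in ("Bol", "Ric")
        for c in ("CS", "SG")
        for s in ("bc", "19")
        for r in (1, 2)
    ]


def small_generation_config(seed: int = 1, **overrides) -> GenerationConfig:
    base = dict(
        seed=seed,
        n_chromosomes=2,
        chrom_length=150_000,
        n_hairpins=6,
        n_hotspots=6,
        n_phas_loci=1,
        n_te_loci=6,
        n_blacklist_loci=4,
        n_genes=10,
        n_background_tags=400,
        library_depth=8_000,
        factor_design=small_factor_design(),
    )
    base.update(overrides)
    return GenerationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_generation_config()
    genome, annotation, manifest = generate_genome(cfg)
    libraries = simulate_libraries(genome, manifest, cfg)
    return cfg, genome, annotation, manifest, libraries


@pytest.fixture(scope="session")
def small_ws(tmp_path_factory):
    """Small end-to-end workspace: all stages run on the small fixture."""
    cfg = RunConfig(
        outdir=str(tmp_path_factory.mktemp("small_ws")),
        seed=1,
        n_chromosomes=2,
        chrom_length=150_000,
        n_hairpins=6,
        n_hotspots=6,
        n_phas_loci=1,
        n_te_loci=6,
        n_blacklist_loci=4,
        n_genes=10,
        n_background_tags=400,
        library_depth=8_000,
    )
    ws = Workspace(cfg)
    ws.stage_simulate()
    ws.stage_map()
    ws.stage_normalize()
    ws.stage_clusters()
    ws.stage_mirna()
    ws.stage_expression()
    return ws


@pytest.fixture(scope="session")
def full_ws(tmp_path_factory):
    """The default study fixture: 1 Mb nuclear genome, 48 libraries of
    50,000 reads, full factorial design."""
    cfg = RunConfig(outdir=str(tmp_path_factory.mktemp("full_ws")), seed=1)
    ws = Workspace(cfg)
    ws.stage_simulate()
    ws.stage_map()
    ws.stage_normalize()
    ws.stage_clusters()
    ws.stage_mirna()
    ws.stage_expression()
    return ws
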