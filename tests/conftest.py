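"""Shared fixtures: simulated datasets at two depths, run once per session."""
from types import SimpleNamespace

import pytest

import mirprof as mp


def run_pipeline(config: mp.SimulationConfig) -> SimpleNamespace:
    ds = mp.simulate_dataset(config)
    tags, stats, unassigned = mp.preprocess_reads(
        ds.reads.reads, ds.reads.index_map, config.adapter3
    )
    ann = mp.annotate_pipeline(
        tags, ds.genome, ds.tracks, ds.known_precursors(), ds.mirna_track()
    )
    return SimpleNamespace(
        dataset=ds, config=config, tags=tags, stats=stats,
        unassigned=unassigned, ann=ann,
    )


@pytest.fixture(scope="session")
def small_pipeline():
    """Default study conditions at reduced depth, for fast structural checks."""
    return run_pipeline(mp.SimulationConfig(seed=7, library_depth=20_000))


@pytest.fixture(scope="session")
def deep_pipeline():
    """Full-depth libraries (1e5 reads each), all precursors annotated."""
    return run_pipeline(mp.SimulationConfig(seed=5, library_depth=100_000))


@pytest.fixture(scope="session")
def novel_discovery_runs():
    """Four full-depth datasets, each with 8 of 16 planted hairpins withheld
    from the annotation, plus their discovery results.  Several datasets are
    pooled so the sensitivity denominator (planted loci with >= 30 true
    reads per library) is large enough for a stable rate estimate."""
    runs = []
    for seed in (11, 12, 13, 14):
        run = run_pipeline(mp.SimulationConfig(seed=seed, library_depth=100_000, n_novel=8))
        novel, evaluations = mp.novel_pipeline(
            run.ann.hits, run.ann.calls, run.tags, run.dataset.genome
        )
        run.novel = novel
        run.evaluations = evaluations
        runs.append(run)
    return runs
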