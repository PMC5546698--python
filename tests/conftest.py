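"""Shared fixtures: a small annotated genome and one full-scale pipeline run.

The full-scale run (2 Mb genome, 500 uniform junctions, PCR-duplicate mean 3,
5% hotspot artifacts, 10% low-quality reads) is computed once per session and
reused by the end-to-end tests.
"""

from __future__ import annotations

import pytest

from tdnajs import (
    CallerParams,
    GenomeConfig,
    LibraryConfig,
    TrackConfig,
    default_tdna,
    generate_genome,
    generate_tracks,
    run_pipeline,
    simulate_junctions,
    simulate_library,
)


@pytest.fixture(scope="session")
def tdna():
    return default_tdna()


@pytest.fixture(scope="session")
def small_world():
    """A 160 kb two-chromosome genome with features and tracks."""
    config = GenomeConfig(lengths=[100_000, 60_000],
                          pericentric=[(35_000, 65_000), (20_000, 40_000)],
                          genes_per_mb=100, tes_per_mb=400,
                          te_length_mean=500, seed=11)
    genome, features = generate_genome(config)
    tracks = generate_tracks(
        genome, features,
        TrackConfig(island_count=8, island_width=2000, seed=12))
    return {"config": config, "genome": genome, "features": features,
            "tracks": tracks}


@pytest.fixture(scope="session")
def big_sim():
    """Full-scale simulated experiment: 2 Mb genome, 500 uniform junctions."""
    genome, features = generate_genome(GenomeConfig(seed=1))
    tracks = generate_tracks(genome, features, TrackConfig(seed=2))
    junctions = simulate_junctions(genome, features, tracks, 500,
                                   bias="uniform", seed=3)
    reads, truth = simulate_library(genome, junctions, default_tdna(),
                                    LibraryConfig(seed=4))
    return {"genome": genome, "features": features, "tracks": tracks,
            "junctions": junctions, "reads": reads, "truth": truth}


@pytest.fixture(scope="session")
def big_run(big_sim):
    """The full pipeline on the full-scale simulation, with accuracy metrics."""
    table, qc = run_pipeline(big_sim["reads"], big_sim["genome"],
                             default_tdna(), CallerParams())
    truth = big_sim["truth"]
    emitted = truth[truth.n_reads > 0]
    recall = match_fraction(
        list(zip(emitted.chrom, emitted.pos0)),
        list(zip(table.chrom, table.pos)))
    precision = match_fraction(
        list(zip(table.chrom, table.pos)),
        list(zip(emitted.chrom, emitted.pos0)))
    return {"table": table, "qc": qc, "recall": recall, "precision": precision,
            "emitted": emitted}


from tdnajs.caller import position_match_fraction as match_fraction  # noqa: E402
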