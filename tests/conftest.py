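from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

import enrichfit as ef

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted_sam_run(tmp_path_factory):
    """Full SAM -> BAM -> pipeline run: 20 sites at factor 50, two replicates.

    Both replicates share the planted sites; each has its own sampling seed.
    """
    base = tmp_path_factory.mktemp("planted")
    truth1 = ef.plant_sites(20, 50.0, seed=101)
    truth2 = replace(truth1, seed=1101)
    genome = ef.make_genome(truth1.genome_length, 101)
    runs = []
    for i, truth in enumerate((truth1, truth2), start=1):
        out = base / f"rep{i}"
        paths = ef.simulate_libraries(genome, truth, out)
        ebam = ef.sam_to_indexed_bam(paths["enriched_sam"])
        cbam = ef.sam_to_indexed_bam(paths["control_sam"])
        result = ef.run_experiment(ebam, cbam)
        runs.append(
            {
                "truth": truth,
                "paths": paths,
                "enriched_bam": ebam,
                "control_bam": cbam,
                "result": result,
            }
        )
    return {"genome": genome, "planted": truth1.planted_positions(), "runs": runs}


@pytest.fixture(scope="session")
def weak_replicate_run():
    """Two weak-signal replicates (factor 1.7) via exact depth tables."""
    truth1 = ef.plant_sites(40, 1.7, seed=5)
    truth2 = replace(truth1, seed=1005)
    results = []
    for truth in (truth1, truth2):
        enriched, control = ef.simulate_depth_tables(truth)
        results.append(ef.run_experiment(enriched, control))
    meta = ef.combine_replicates([r.table for r in results])
    return {"planted": truth1.planted_positions(), "results": results, "meta": meta}


@pytest.fixture(scope="session")
def null_run():
    """No-signal experiment over 50,000 transcribed positions."""
    truth = ef.plant_sites(0, 50.0, seed=11, genome_length=25049)
    enriched, control = ef.simulate_depth_tables(truth)
    return ef.run_experiment(enriched, control)
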