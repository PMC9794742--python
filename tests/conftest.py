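import numpy as np
import pytest

from eprvscan import pipeline, report, syngen


@pytest.fixture(scope="session")
def library():
    return syngen.synthetic_reference_library()


@pytest.fixture(scope="session")
def motifs():
    from eprvscan.refdata import load_motifs

    return load_motifs()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20221214)


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """The standard 2 Mb validation scenario run end to end once per session:
    simulate, search, screen, cluster, classify, age, annotate."""
    bundle = syngen.default_scenario(seed=1)
    cfg = pipeline.PipelineConfig(seed=1)
    outdir = tmp_path_factory.mktemp("sim_run")
    result = pipeline.run_pipeline(
        cfg, bundle.assembly, bundle.taxonomy, bundle.library, bundle.divergence, outdir
    )
    return bundle, result


@pytest.fixture(scope="session")
def sim_recovery(sim_run):
    bundle, result = sim_run
    return report.evaluate_recovery(
        bundle.truth, result.candidates, bundle.library, result.candidate_assignments
    )


@pytest.fixture(scope="session")
def mini_bundle(library):
    """A small, fast scenario: one 120 kb contig, three intact implants and
    one decoy."""
    rng = np.random.default_rng(7)
    background = syngen.generate_background(1, 120_000, 0.40, 0.0, rng)
    caulimo = [r for r in library if r.lineage_class == "caulimoviridae"]
    decoys = [r for r in library if r.lineage_class == "retroelement"]
    specs = [
        syngen.ImplantSpec(caulimo[1].id, 1, 0.0, "intact", strand_policy="plus"),
        syngen.ImplantSpec(caulimo[25].id, 1, 0.05, "intact", strand_policy="minus"),
        syngen.ImplantSpec(caulimo[60].id, 1, 0.02, "intact"),
        syngen.ImplantSpec(decoys[0].id, 1, 0.05, "intact"),
    ]
    assembly, truth = syngen.implant(background, library, specs, rng)
    return syngen.SimulationBundle(
        assembly=assembly,
        truth=truth,
        library=library,
        taxonomy=syngen.simulated_taxonomy(),
        divergence=syngen.DivergenceTable(),
        species=syngen.SIM_SPECIES,
        config={"seed": 7},
    )
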