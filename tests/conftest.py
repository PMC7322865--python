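import pytest

from asmmap.config import PipelineConfig, SimConfig
from asmmap.pipeline import run_pipeline
from asmmap.simulate import (
    make_default_pwms,
    simulate_annotations_and_panel,
    simulate_cohort,
    simulate_motif_landscape,
    simulate_reads,
)

SEED = 1


@pytest.fixture(scope="session")
def sim_bundle():
    """Small simulated cohort with all fixtures, shared across tests."""
    cfg = SimConfig(seed=SEED, n_loci=40, n_normal_samples=10, n_cancer_samples=4)
    cohort, truth = simulate_cohort(cfg)
    pwms = make_default_pwms(2, seed=SEED)
    windows = simulate_motif_landscape(cohort, truth, pwms)
    reads = simulate_reads(cohort, truth)
    bundle = simulate_annotations_and_panel(cohort, truth, pwms)
    return dict(cfg=cfg, cohort=cohort, truth=truth, pwms=pwms,
                windows=windows, reads=reads, bundle=bundle)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """Full pipeline run at the default study conditions (seed fixed)."""
    outdir = tmp_path_factory.mktemp("pipeline")
    res = run_pipeline(
        SimConfig(seed=SEED), PipelineConfig(seed=SEED), str(outdir)
    )
    return res
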