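import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One small full pipeline run shared by read-only assertions."""
    from ovulemeth.pipeline import RunConfig, run_pipeline
    from ovulemeth.simdata import DmrPlanEntry, SimConfig

    plan = [DmrPlanEntry("promoter", "hyper", 2),
            DmrPlanEntry("promoter", "hypo", 2),
            DmrPlanEntry("exon", "hyper", 1),
            DmrPlanEntry("exon", "hypo", 1),
            DmrPlanEntry("intron", "hyper", 1),
            DmrPlanEntry("intron", "hypo", 1),
            DmrPlanEntry("intergenic", "hyper", 1),
            DmrPlanEntry("intergenic", "hypo", 1),
            DmrPlanEntry("mirna_promoter", "hyper", 1),
            DmrPlanEntry("mirna_promoter", "hypo", 1)]
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = RunConfig(
        outdir=str(outdir), seed=11,
        sim=SimConfig(n_chromosomes=2, chrom_length=60_000,
                      n_genes_per_chrom=5, n_mirna_per_chrom=3,
                      n_cgi_per_chrom=2, coverage=12, dmr_plan=plan,
                      control_length=5_000, control_coverage=25))
    return run_pipeline(cfg)
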