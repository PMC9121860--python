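import warnings

import pytest

from cd4time.pipeline import RunConfig, run_pipeline
from cd4time.synthetic import SimConfig, generate_cohort

# lifelines complains about low-variance dummies in small simulated cohorts;
# that is expected at test sizes and not a defect under test
warnings.filterwarnings("ignore", message=".*low variance.*")
warnings.filterwarnings("ignore", message=".*norm\\(delta\\).*")


@pytest.fixture(scope="session")
def small_cohort():
    """A 250-patient synthetic cohort with its truth record."""
    return generate_cohort(SimConfig(n_patients=250, seed=42))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run (simulate + build + fit) on a 400-patient cohort."""
    out = tmp_path_factory.mktemp("pipeline")
    # a reduced adjustment set keeps all twelve fits stable at this size
    config = RunConfig(sim=SimConfig(n_patients=400, seed=7),
                       adjustment=("sex", "age", "baseline_group", "art_year"))
    bundle = run_pipeline(config, out)
    return bundle, out, config
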