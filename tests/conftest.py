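import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mhonet.preprocess import filter_low_expression, log_cpm, normalize  # noqa: E402
from mhonet.simulate import SyntheticConfig, generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def small_cohort():
    """1,000-gene cohort with three planted 40-gene modules (8 MHO vs 21 MAO)."""
    cfg = SyntheticConfig(
        n_genes=1000, module_sizes=(40, 40, 40), assoc_effect=1.5, seed=11
    )
    counts, clinical, truth = generate_cohort(cfg)
    return cfg, counts, clinical, truth


@pytest.fixture(scope="session")
def small_logcpm(small_cohort):
    _, counts, clinical, truth = small_cohort
    filtered = filter_low_expression(counts)
    lcpm = log_cpm(filtered, normalize(filtered))
    truth_labels = np.array(
        [truth.module_labels[truth.gene_ids.index(g)] for g in lcpm.index]
    )
    return lcpm, clinical, truth, truth_labels
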