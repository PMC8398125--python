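import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("det", derandomize=True, deadline=None)
hyp_settings.load_profile("det")

from adlseq.casas_io import segment_activities
from adlseq.features import build_vocabulary
from adlseq.preprocessing import CLASS_ORDER, Dataset, attach_context, clean_events, select_classes
from adlseq.synthetic_data import default_sim_config, simulate_log


@pytest.fixture(scope="session")
def sim_events():
    """A 20-day default-config simulated log, cleaned."""
    return clean_events(simulate_log(default_sim_config(n_days=20, seed=7)))


@pytest.fixture(scope="session")
def sim_pool(sim_events):
    instances = attach_context(segment_activities(sim_events))
    return select_classes(Dataset(instances), CLASS_ORDER)


@pytest.fixture(scope="session")
def sim_vocab(sim_events):
    return build_vocabulary(sim_events)
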