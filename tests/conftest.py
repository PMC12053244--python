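import numpy as np
import pytest

from bgdbs.specs import default_config


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def small_off_run():
    """One small DBS OFF batch of full task runs, shared across tests."""
    from bgdbs.task import run_task_batch

    return run_task_batch(np.arange(6), "off", record_rates=False)


def noise_free(cfg):
    """Copy of a config with all membrane noise switched off."""
    import dataclasses

    cfg = cfg.copy()
    for name, pop in list(cfg.populations.items()):
        cfg.populations[name] = dataclasses.replace(pop, lam=0.0)
    return cfg
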