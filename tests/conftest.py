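import numpy as np
import pytest

from burnmech import mechanics, synthetic


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (seed 1): records, truth and properties.

    Generated once per session; extraction fits all specimens, so several
    modules share this fixture instead of regenerating.
    """
    config = synthetic.default_config(seed=1)
    records, truth = synthetic.generate_study(config)
    props = mechanics.extract_properties(records)
    kept, removed = mechanics.remove_outliers(props)
    return {"config": config, "records": records, "truth": truth,
            "properties": props, "kept": kept, "removed": removed}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
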