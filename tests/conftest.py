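import json

import pytest

from chemrdf.pipeline import convert_records, load_deposition
from chemrdf.synth import SynthConfig, generate_synthetic_deposition
from chemrdf.worked_example import build_worked_example

SYNTH_SEED = 42


@pytest.fixture(scope="session")
def worked_example():
    return build_worked_example()


@pytest.fixture(scope="session")
def synth_deposition():
    """A small multi-source synthetic deposition (seed 42, 12 bases)."""
    config = SynthConfig(seed=SYNTH_SEED, n_base_structures=12)
    sdf_text, metadata = generate_synthetic_deposition(config)
    return config, sdf_text, metadata


@pytest.fixture(scope="session")
def synth_result(synth_deposition):
    _config, sdf_text, metadata = synth_deposition
    records = load_deposition(sdf_text, metadata)
    return records, convert_records(
        records, source_meta=json.loads(metadata)["sources"]
    )
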