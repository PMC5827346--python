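import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from edckit.io_core import ProteinRecord
from edckit.synthetic_locus import SyntheticConfig, generate_edc_locus


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        seed=11, n_sedc=6, n_sftp=2, n_cbp_cluster=4, n_pseudogenes=2
    )


@pytest.fixture(scope="session")
def small_locus(small_config):
    return generate_edc_locus(small_config)


@pytest.fixture(scope="session")
def marker_queries(small_locus):
    _, truth = small_locus
    return [ProteinRecord(mid, truth.proteins[mid]) for mid in truth.marker_ids]
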