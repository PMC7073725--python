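import pytest

import aromix as am
from aromix.io import packaged_path


@pytest.fixture(scope="session")
def compound_records():
    """The packaged reference dataset merged across its three tables."""
    return am.merge_compound_tables(
        am.read_compound_table(packaged_path("gco_fd")),
        am.read_compound_table(packaged_path("quantification")),
        am.read_compound_table(packaged_path("thresholds")),
    )


@pytest.fixture(scope="session")
def omission_pvalues():
    """Omission battery p-values reconstructed from the published star labels."""
    df = am.load_packaged("omission")
    return {r.omitted_compound: am.p_from_stars(r.stars) for r in df.itertuples()}


@pytest.fixture(scope="session")
def mixture_table():
    return am.load_packaged("mixture_oav")
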