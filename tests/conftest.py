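import pytest

from shcqual import TopicSpec, generate_site
from shcqual.webfixtures import fixture_backends

from helpers import chain_site_spec

LARC_KEYWORDS = [
    "IUD",
    "intrauterine device",
    "IUI",
    "intrauterine implant",
    "contraceptive implant",
    "contraceptive shot",
    "contraceptive injection",
    "Depo Provera",
]


@pytest.fixture
def larc_topic() -> TopicSpec:
    return TopicSpec("LARC", LARC_KEYWORDS)


@pytest.fixture
def chain_site(tmp_path):
    """Materialized 12-page chain with the keyword only on the deepest page."""
    return generate_site(chain_site_spec(n_pages=12), tmp_path / "chain")


@pytest.fixture
def chain_backends(chain_site):
    return fixture_backends(chain_site)
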