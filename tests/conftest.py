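import pytest

from rgbarcode import design
from rgbarcode.scenarios import default_templates


@pytest.fixture(scope="session")
def layout():
    return design.BarcodeLayout.default()


@pytest.fixture(scope="session")
def templates():
    """Red/green/blue templates designed at the default min distance."""
    return default_templates(seed=11)


@pytest.fixture(scope="session")
def template_list(templates):
    return list(templates.values())


@pytest.fixture(scope="session")
def red_template(templates):
    return templates["red"]
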