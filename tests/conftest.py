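from pathlib import Path

import pytest

from duc import Registry, default_registry, worked_example

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def registry() -> Registry:
    return default_registry()


@pytest.fixture()
def fig2_profile():
    return worked_example("fig2")


@pytest.fixture()
def fig2_document() -> str:
    return (DATA / "fig2.golden.json").read_text(encoding="utf-8")


#: The worked-example profile rendered as prose, sentence by sentence.
FIG2_SENTENCES = (
    "General research use is permitted for the whole of asset.",
    "The country of the United Kingdom is permitted for the whole of asset.",
    "The time limit on use is 12 months and is obligatory for the whole of asset.",
)
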