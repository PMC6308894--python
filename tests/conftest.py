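from pathlib import Path

import pytest

from ambiprime.fixture import demo_spec, generate_fixture

REPO = Path(__file__).resolve().parents[1]
DEMO_DIR = REPO / "examples" / "data" / "demo"


@pytest.fixture(scope="session")
def demo_fixture():
    """The canonical demo fixture, regenerated in memory."""
    return generate_fixture(demo_spec())


@pytest.fixture(scope="session")
def demo_dir() -> Path:
    """Path to the shipped demo fixture files."""
    assert (DEMO_DIR / "fixture.fasta").exists()
    return DEMO_DIR
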