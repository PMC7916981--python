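import numpy as np
import pytest

from mirprio import MiRNARecord, UTRRecord, load_reference_mirnas


@pytest.fixture(scope="session")
def reference_mirnas() -> list[MiRNARecord]:
    return load_reference_mirnas()


@pytest.fixture()
def mir425(reference_mirnas) -> MiRNARecord:
    return next(m for m in reference_mirnas if m.name == "hsa-miR-425-5p")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210211)


def random_rna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(rng.choice(np.array(list("AUGC")), size=length, p=probs))


@pytest.fixture()
def random_utr(rng) -> UTRRecord:
    return UTRRecord("RAND1", random_rna(rng, 200))
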