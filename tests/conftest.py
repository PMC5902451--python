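import numpy as np
import pytest

from sapnet import (
    BenchmarkConfig,
    InterfaceMap,
    InterfaceRecord,
    PpiNetwork,
    SapRecord,
    generate_benchmark,
)


@pytest.fixture
def path_network():
    """A - B - C path with an isolated node D; cancer node C."""
    return PpiNetwork([("A", "B"), ("B", "C")], cancer_nodes={"C"},
                      extra_nodes=["D"])


@pytest.fixture
def toy_interfaces():
    return InterfaceMap([
        InterfaceRecord("P", "Q", "P", ((10, 20),)),
        InterfaceRecord("P", "R", "P", ((14, 16),)),
        InterfaceRecord("P", "Q", "Q", ((5, 8),)),
    ])


def make_sap(protein="P", position=15, wt="G", mut="D", **kw):
    return SapRecord(protein_id=protein, position=position, wt_aa=wt,
                     mut_aa=mut, **kw)


@pytest.fixture
def small_benchmark():
    """A fast benchmark instance reused across tests (session-scoped below)."""
    return _small_benchmark_cached()


_CACHE = {}


def _small_benchmark_cached():
    if "bench" not in _CACHE:
        _CACHE["bench"] = generate_benchmark(BenchmarkConfig(
            n_nodes=200, n_deleterious=80, n_neutral=240, n_samples=30,
            seed=11,
        ))
    return _CACHE["bench"]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
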