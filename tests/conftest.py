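import pytest
from hypothesis import settings

from polyxnet import Interactome, extract_group_network

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_interactome(pairs, **kwargs):
    edges = frozenset(tuple(sorted(p)) for p in pairs)
    return Interactome(edges=edges, **kwargs)


@pytest.fixture
def toy_interactome():
    """Edges A-B, A-X, B-Y, C-Z, X-Y: for group {A, B, C} exactly one
    within-group edge and three group/outside edges."""
    return make_interactome([("A", "B"), ("A", "X"), ("B", "Y"), ("C", "Z"), ("X", "Y")])


@pytest.fixture
def toy_group_network(toy_interactome):
    return extract_group_network(toy_interactome, {"A", "B", "C"})
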