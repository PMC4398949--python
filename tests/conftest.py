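import itertools

import pytest

from phyloconcord import TaxonUniverse, parse_newick, simulate_yule_tree


def _rooted_shapes(labels):
    """All rooted binary tree shapes (nested 2-tuples) on the given labels."""
    if len(labels) == 1:
        return [labels[0]]
    shapes = []
    for shape in _rooted_shapes(labels[:-1]):
        shapes.extend(_insertions(shape, labels[-1]))
    return shapes


def _insertions(shape, leaf):
    """Insert ``leaf`` on every edge of ``shape`` including above the root."""
    out = [(shape, leaf)]
    if isinstance(shape, tuple):
        left, right = shape
        out += [(new, right) for new in _insertions(left, leaf)]
        out += [(left, new) for new in _insertions(right, leaf)]
    return out


def _render(shape):
    if isinstance(shape, str):
        return shape
    return "({},{})".format(_render(shape[0]), _render(shape[1]))


def enumerate_unrooted_topologies(labels):
    """Every unrooted binary topology on ``labels``, as parsed trees.

    An unrooted tree on n leaves corresponds 1:1 to a rooted binary tree on
    the last n-1 leaves joined to the first leaf at a trifurcation, which
    gives (2n-5)!! distinct topologies.
    """
    first, rest = labels[0], list(labels[1:])
    trees = []
    for shape in _rooted_shapes(rest):
        left, right = shape
        trees.append(
            parse_newick(f"({_render(left)},{_render(right)},{first});")
        )
    return trees


@pytest.fixture(scope="session")
def five_leaf_topologies():
    """All 15 unrooted binary topologies on {A..E}."""
    trees = enumerate_unrooted_topologies(["A", "B", "C", "D", "E"])
    assert len(trees) == 15
    return trees


@pytest.fixture(scope="session")
def yule16():
    return simulate_yule_tree(16, 42)


@pytest.fixture
def quartet_universe():
    return TaxonUniverse.from_iterable(["A", "B", "C", "D"])
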