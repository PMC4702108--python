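import numpy as np
import pytest

from mitoarch import fixtures as fx


@pytest.fixture(scope="session")
def tables():
    return fx.load_tables()


@pytest.fixture(scope="session")
def pt_table(tables):
    return tables[fx.PT]


@pytest.fixture(scope="session")
def es_table(tables):
    return tables[fx.ES]


@pytest.fixture(scope="session")
def arrangements():
    return fx.load_arrangements()


@pytest.fixture(scope="session")
def ancestor(arrangements):
    return arrangements[fx.ANCESTOR]


@pytest.fixture(scope="session")
def pt_order(arrangements):
    return arrangements[fx.PT]


@pytest.fixture(scope="session")
def es_order(arrangements):
    return arrangements[fx.ES]


@pytest.fixture(scope="session")
def screen_orders(arrangements):
    return [arrangements[t] for t in fx.SCREEN_TAXA]


def random_signed_order(rng: np.random.Generator, n: int, taxon: str = "x"):
    """A uniformly shuffled circular signed order over n toy genes."""
    from mitoarch.gene_order import GeneOrder

    names = [f"g{i}" for i in range(n)]
    perm = rng.permutation(n)
    genes = tuple((names[i], int(rng.choice([1, -1]))) for i in perm)
    return GeneOrder(taxon, genes)


def brute_breakpoints(target, reference) -> int:
    """Independent oracle: enumerate every neighbor pair of both circular
    orders in both strand readings and count target junctions missing from
    the reference.  Shares no code with the adjacency-set implementation."""

    def junctions(genes):
        pairs = set()
        readings = [list(genes), [(g, -s) for g, s in reversed(genes)]]
        for reading in readings:
            n = len(reading)
            for i in range(n):
                pairs.add((reading[i], reading[(i + 1) % n]))
        return pairs

    tp = junctions(target.genes)
    rp = junctions(reference.genes)
    # each physical junction was enumerated once per strand reading
    missing = [p for p in tp if p not in rp]
    assert len(missing) % 2 == 0
    return len(missing) // 2
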