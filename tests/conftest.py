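import io

import numpy as np
import pytest

from enrichkit.enrich import InputGeneList
from enrichkit.genesets import GeneSet, GeneSetLibrary, read_gmt
from enrichkit import fixtures as fx


@pytest.fixture
def tiny_library() -> GeneSetLibrary:
    """Three hand-built sets: {A,B}, {B,C}, {C,D,E}."""
    return GeneSetLibrary(
        [
            GeneSet(term="S1", genes=frozenset({"A", "B"})),
            GeneSet(term="S2", genes=frozenset({"B", "C"})),
            GeneSet(term="S3", genes=frozenset({"C", "D", "E"})),
        ],
        name="tiny",
    )


@pytest.fixture
def two_set_gmt() -> str:
    return "T1\tdesc\tA\tB\tb\nT2\t\tC\n"


@pytest.fixture
def small_random_library() -> GeneSetLibrary:
    spec = fx.FixtureSpec(
        seed=7, universe_size=500, n_terms=20, size_min=5, size_max=40
    )
    return fx.random_library(spec)


@pytest.fixture
def medium_random_library() -> GeneSetLibrary:
    spec = fx.FixtureSpec(
        seed=11, universe_size=1000, n_terms=50, size_min=10, size_max=80
    )
    return fx.random_library(spec)


@pytest.fixture
def corpus():
    return fx.toy_corpus(seed=0)


def make_list(*genes: str) -> InputGeneList:
    return InputGeneList(genes=frozenset(genes))


def library_from_gmt(text: str) -> GeneSetLibrary:
    return read_gmt(io.StringIO(text))
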