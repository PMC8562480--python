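import numpy as np
import pandas as pd
import pytest

from gutassembly.containers import OtuTable, PhyloTree, SampleMetadata

ABC_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def abc_tree() -> PhyloTree:
    """Three-tip reference tree: d(A,B)=2, d(A,C)=d(B,C)=4."""
    return PhyloTree.from_newick(ABC_NEWICK)


@pytest.fixture
def star_tree() -> PhyloTree:
    """Four-tip star: every pairwise distance is exactly 2."""
    return PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")


def make_table(rows: dict[str, list[float]], otus: list[str],
               is_relative: bool = False) -> OtuTable:
    return OtuTable(pd.DataFrame.from_dict(rows, orient="index",
                                           columns=otus),
                    is_relative=is_relative)


def make_metadata(dsr: list[int], env: dict[str, list[float]] | None = None,
                  ids: list[str] | None = None) -> SampleMetadata:
    ids = ids or [f"S{i + 1:03d}" for i in range(len(dsr))]
    data = pd.DataFrame({"dsr_level": dsr}, index=ids)
    for name, vals in (env or {}).items():
        data[name] = vals
    return SampleMetadata(data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
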