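import numpy as np
import pandas as pd
import pytest

from pubertome.tables_io import CountTable, RANKS, Taxonomy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts():
    return CountTable(
        pd.DataFrame(
            [[5, 0, 3], [3, 7, 1]],
            index=["s1", "s2"],
            columns=["Faecalibacterium_sp", "Dorea_sp", "Bacteroides_sp"],
        )
    )


@pytest.fixture
def small_taxonomy():
    rows = {
        "Faecalibacterium_sp": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                                "Ruminococcaceae", "Faecalibacterium", "Faecalibacterium_sp"),
        "Dorea_sp": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales",
                     "Lachnospiraceae", "Dorea", "Dorea_sp"),
        "Bacteroides_sp": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
                           "Bacteroidaceae", "Bacteroides", "Bacteroides_sp"),
    }
    return Taxonomy(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))
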