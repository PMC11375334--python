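import numpy as np
import pandas as pd
import pytest

from microsubtype import AbundanceTable

#: published per-cluster (CRC, AA, NC) counts of the nine consensus clusters
CLUSTER_COUNTS = {
    "C1": (166, 162, 79),
    "C2": (25, 27, 5),
    "C3": (39, 31, 16),
    "C4": (21, 20, 16),
    "C5": (59, 81, 17),
    "C6": (7, 0, 4),
    "C7": (18, 4, 4),
    "C8": (35, 22, 28),
    "C9": (6, 16, 6),
}

#: published per-subtype (CRC, AA, NC) counts after merging
SUBTYPE_COUNTS = {
    "A": (223, 197, 99),
    "B": (25, 27, 5),
    "C": (59, 81, 17),
    "D": (69, 58, 54),
}

PAPER_PARTITION = {
    "A": {"C1", "C3", "C7"},
    "B": {"C2"},
    "C": {"C5"},
    "D": {"C4", "C6", "C8", "C9"},
}


@pytest.fixture
def small_table() -> AbundanceTable:
    data = pd.DataFrame(
        [[4.0, 4.0, 2.0], [1.0, 0.0, 3.0], [0.0, 5.0, 5.0]],
        index=["s1", "s2", "s3"],
        columns=["Bacteroides", "Blautia", "Streptococcus"],
    )
    taxonomy = {
        "Bacteroides": {
            "domain": "Bacteria", "phylum": "Bacteroidetes", "class": "Bacteroidia",
            "order": "Bacteroidales", "family": "Bacteroidaceae", "genus": "Bacteroides",
        },
        "Blautia": {
            "domain": "Bacteria", "phylum": "Firmicutes", "class": "Clostridia",
            "order": "Eubacteriales", "family": "Lachnospiraceae", "genus": "Blautia",
        },
        "Streptococcus": {
            "domain": "Bacteria", "phylum": "Firmicutes", "class": "Bacilli",
            "order": "Lactobacillales", "family": "Streptococcaceae", "genus": "Streptococcus",
        },
    }
    return AbundanceTable(data, taxonomy, is_relative=False)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
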