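import numpy as np
import pandas as pd
import pytest

from metaratio.simulate import default_cohort_spec, default_taxonomy, generate_cohort
from metaratio.taxonomy import build_taxonomy


@pytest.fixture(scope="session")
def gut_tree():
    """The default 13-genus, 5-phylum gut taxonomy."""
    return default_taxonomy()


@pytest.fixture(scope="session")
def small_tree():
    """Hand-built fixture tree: two families under one order, two phyla."""
    return build_taxonomy(
        [
            ("p__Firmicutes", "root", "phylum", "Firmicutes"),
            ("p__Bacteroidetes", "root", "phylum", "Bacteroidetes"),
            ("c__Clostridia", "p__Firmicutes", "class", "Clostridia"),
            ("o__Clostridiales", "c__Clostridia", "order", "Clostridiales"),
            ("f__Ruminococcaceae", "o__Clostridiales", "family", "Ruminococcaceae"),
            ("f__Lachnospiraceae", "o__Clostridiales", "family", "Lachnospiraceae"),
            ("g__Faecalibacterium", "f__Ruminococcaceae", "genus", "Faecalibacterium"),
            ("g__Ruminococcus", "f__Ruminococcaceae", "genus", "Ruminococcus"),
            ("g__Coprococcus", "f__Lachnospiraceae", "genus", "Coprococcus"),
            ("g__Bacteroides", "p__Bacteroidetes", "genus", "Bacteroides"),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort(gut_tree):
    """A quick 8-subject cohort at reduced depth, shared across tests."""
    spec = default_cohort_spec(seed=42, n_subjects=8, mg_depth=20_000, mp_depth=2_000)
    return generate_cohort(spec), spec


def make_records(rows):
    """Records DataFrame from (subject, layer, taxon, function, weight) tuples."""
    df = pd.DataFrame(rows, columns=["subject", "layer", "taxon", "function", "weight"])
    df.insert(2, "unit", [f"u{i:04d}" for i in range(len(df))])
    df["weight"] = df["weight"].astype(np.int64)
    return df
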