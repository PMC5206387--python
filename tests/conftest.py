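import numpy as np
import pandas as pd
import pytest

from cardioburden.annotation import DomainBoundaries, annotate
from cardioburden.io import CohortGenotypes, read_variant_table, table1_fixture_path


@pytest.fixture(scope="session")
def table1_records():
    return read_variant_table(table1_fixture_path())


@pytest.fixture(scope="session")
def table1_variants(table1_records):
    return [annotate(r, boundaries=DomainBoundaries()) for r in table1_records]


def make_cohort(counts: dict, labels: dict | None = None, genes: dict | None = None):
    """Small helper: build a CohortGenotypes from {variant_id: {subject: count}}."""
    frame = pd.DataFrame(counts, dtype=float)
    meta = pd.DataFrame(
        {
            "id": list(counts),
            "chrom": ["1"] * len(counts),
            "pos": np.arange(100, 100 + len(counts)),
            "ref": ["A"] * len(counts),
            "alt": ["T"] * len(counts),
        }
    ).set_index("id")
    if genes:
        meta["gene"] = [genes.get(v, "GENE") for v in meta.index]
    label_series = pd.Series(labels) if labels else None
    return CohortGenotypes(allele_counts=frame, variants=meta, labels=label_series)
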