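import numpy as np
import pandas as pd
import pytest

from bacstab.core_data import AbundanceTable, SampleDesign, to_relative
from bacstab.synthcom import GeneratorSpec, generate_community


def make_design(stages=4, replicates=9):
    rows = [
        {"sample_id": f"{site}{stage}R{rep}", "site": site, "stage": stage, "replicate": rep}
        for site in ("A", "B")
        for stage in range(1, stages + 1)
        for rep in range(1, replicates + 1)
    ]
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def full_design():
    return make_design()


@pytest.fixture(scope="session")
def small_spec():
    """Reduced community for fast unit tests (study-scale runs live in the
    acceptance suite)."""
    return GeneratorSpec(n_taxa=60, depth=20_000, seed=11)


@pytest.fixture(scope="session")
def small_community(small_spec):
    table, design, lineage = generate_community(small_spec)
    return table, design, lineage


@pytest.fixture(scope="session")
def default_community():
    spec = GeneratorSpec(seed=1)
    table, design, lineage = generate_community(spec)
    return spec, table, design, lineage


@pytest.fixture()
def tiny_counts(full_design):
    """3 taxa x 4 samples of integer counts bound to the standard design."""
    samples = ["A1R1", "A1R2", "B1R1", "B1R2"]
    data = pd.DataFrame(
        [[4, 6, 2, 8], [1, 3, 5, 7], [5, 1, 3, 5]],
        index=pd.Index(["t1", "t2", "t3"], name="taxon_id"),
        columns=samples,
    )
    return AbundanceTable(data, mode="counts")


def relative(table):
    return to_relative(table)
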