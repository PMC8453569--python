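import numpy as np
import pandas as pd
import pytest

from rhmscan import (
    GenotypeDataset,
    SimulationConfig,
    TestDayTable,
    build_grm,
    build_model_frame,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small complete simulation shared by read-only tests."""
    cfg = SimulationConfig(
        n_animals=40,
        snps_per_chromosome=[80, 60],
        maf_range=(0.15, 0.5),
        parities_per_animal=2,
        testdays_per_lactation=(3, 4),
        seed=7,
    )
    dataset, truth, table = simulate_dataset(cfg)
    return cfg, dataset, truth, table


@pytest.fixture(scope="session")
def small_frame(small_sim):
    cfg, dataset, truth, table = small_sim
    grm = build_grm(dataset)
    return build_model_frame(table, "fpc", {"u": grm})


@pytest.fixture()
def toy_dataset():
    """Hand-built 4-animal x 3-SNP dataset with one missing genotype."""
    dosages = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 1.0, 0.0],
            [2.0, np.nan, 1.0],
            [0.0, 2.0, 1.0],
        ]
    )
    marker_map = pd.DataFrame(
        {
            "chrom": ["1", "1", "2"],
            "snp_id": ["s1", "s2", "s3"],
            "bp": [100, 200, 150],
            "allele_a": ["A", "A", "A"],
            "allele_b": ["B", "B", "B"],
        }
    )
    return GenotypeDataset(dosages, ["a1", "a2", "a3", "a4"], marker_map)


def make_table(rows):
    """Build a TestDayTable from (animal, flock, date, lambing, parity,
    litter, season, dim, traits...) tuples; traits default to 1.0."""
    full = []
    for r in rows:
        r = list(r)
        while len(r) < 13:
            r.append(1.0)
        full.append(r)
    cols = [
        "animal_id", "flock", "test_date", "lambing_date", "parity",
        "litter_size", "season", "dim", "my", "fpc", "fy", "ppc", "py",
    ]
    return TestDayTable(pd.DataFrame(full, columns=cols))
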