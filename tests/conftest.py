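import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import clonetrace as ct

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=30)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """Reduced-size default configuration for fast pipeline tests."""
    return ct.SimulationConfig(
        n_progenitors_per_subtype={"RGC_1": 40, "RGC_2": 40},
        n_genes=60,
        n_marker_genes_per_type=5,
        seed=7,
    )


@pytest.fixture
def small_sim(small_config):
    return ct.simulate_experiment(small_config)


def fifty_triple_fixture():
    """A 50-triple table with hand-enumerated filtering truth.

    Construction (min_reads=10, min_umis=6):
      C1/B1: 6 UMIs at exactly 10 reads          -> pair kept, umi_count=6
      C1/B2: 5 UMIs at 1000 reads                -> dropped (UMI rule binds)
      C2/B1: 8 UMIs at 9 reads                   -> dropped (no triple survives)
      C2/B3: 7 UMIs, 6 at 25 reads + 1 at 9      -> kept, umi_count=6
      C3/B2: 6 UMIs, 5 at 12 reads + 1 at 9      -> dropped (5 surviving UMIs)
      C3/B3: 10 UMIs at 11 reads                 -> kept, umi_count=10
      C4/B4: 8 UMIs, 5 at 10 + 3 at 9            -> dropped (5 surviving UMIs)
    Total triples: 6+5+8+7+6+10+8 = 50.
    """
    rows = []

    def add(cell, bc, read_list):
        for k, r in enumerate(read_list):
            rows.append((cell, f"{cell}-{bc}-u{k:02d}", bc, r))

    add("C1", "B1", [10] * 6)
    add("C1", "B2", [1000] * 5)
    add("C2", "B1", [9] * 8)
    add("C2", "B3", [25] * 6 + [9])
    add("C3", "B2", [12] * 5 + [9])
    add("C3", "B3", [11] * 10)
    add("C4", "B4", [10] * 5 + [9] * 3)
    df = pd.DataFrame(rows, columns=["cell_bc", "umi", "lineage_bc", "reads"])
    expected = pd.DataFrame(
        {
            "cell_bc": ["C1", "C2", "C3"],
            "lineage_bc": ["B1", "B3", "B3"],
            "umi_count": [6, 6, 10],
        }
    )
    return df, expected


def random_small_matrix(rng: np.random.Generator, max_cells: int = 8, max_barcodes: int = 6):
    """Random cell x barcode incidence with >= 1 barcode per cell."""
    n = int(rng.integers(2, max_cells + 1))
    m = int(rng.integers(1, max_barcodes + 1))
    inc = rng.random((n, m)) < 0.35
    for i in range(n):
        if not inc[i].any():
            inc[i, rng.integers(0, m)] = True
    pairs = pd.DataFrame(
        [
            (f"c{i:02d}", f"b{j}")
            for i in range(n)
            for j in range(m)
            if inc[i, j]
        ],
        columns=["cell_bc", "lineage_bc"],
    )
    return ct.build_matrix(pairs)
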