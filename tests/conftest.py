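import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sotp import SampleDesign, SimulationConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=7,
        n_genes=200,
        venn_counts=(30, 10, 5),
        n_cell_lines=12,
        expression_sparsity=0.3,
        n_ortholog_pairs=9,
        category_counts={
            "classical": 8,
            "nonclassical": 6,
            "membrane": 3,
            "exosome": 5,
            "unclassified": 4,
        },
    )


@pytest.fixture
def two_line_design():
    samples = [f"S{i}" for i in range(6)]
    return SampleDesign(
        sample_ids=samples,
        cell_line_of={s: ("A" if i < 3 else "B") for i, s in enumerate(samples)},
    )


@pytest.fixture
def four_line_design():
    samples = [f"S{i:02d}" for i in range(12)]
    return SampleDesign(
        sample_ids=samples,
        cell_line_of={s: f"L{i // 3}" for i, s in enumerate(samples)},
    )


@pytest.fixture
def complete_matrix(four_line_design):
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        rng.normal(25.0, 2.0, (100, 12)),
        index=[f"P{i:03d}" for i in range(100)],
        columns=four_line_design.sample_ids,
    )
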