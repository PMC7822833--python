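import warnings

import numpy as np
import pandas as pd
import pytest

from macrogd.synthetic import SyntheticConfig, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """~150-row synthetic dataset with known ground truth."""
    cfg = SyntheticConfig(n_species=40, pops_per_species=(2, 6), seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data, truth = make_dataset(cfg)
    return data, truth


@pytest.fixture
def raw_records():
    """Hand-written population records exercising every inclusion rule."""
    return pd.DataFrame(
        {
            "population_id": [f"p{i}" for i in range(8)],
            "species": ["sp1"] * 4 + ["sp2"] * 4,
            "phylum": ["mammal"] * 4 + ["eudicot"] * 4,
            "kingdom": ["animal"] * 4 + ["plant"] * 4,
            "latitude": [10.0, 20.0, 30.0, 40.0, -10.0, np.nan, -30.0, -40.0],
            "longitude": [5.0, 15.0, 25.0, 35.0, -5.0, -15.0, -25.0, -35.0],
            "marker_type": ["codominant"] * 4 + ["dominant"] * 4,
            "n_loci": [10, 12, 8, 15, 20, 25, 30, 10],
            "sample_size": [30, 9, 25, 40, 10, 50, 35, 20],
            "he_raw": [0.6, 0.5, 0.7, 0.65, 0.2, 0.25, 0.3, 0.22],
            "habitat": [
                "terrestrial", "terrestrial", "marine", "freshwater",
                "terrestrial", "terrestrial", "freshwater", "terrestrial",
            ],
            "provenance_flags": ["", "", "", "", "", "", "invasive", ""],
        }
    )
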