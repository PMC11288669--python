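import numpy as np
import pandas as pd
import pytest

from eigenchoice import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset with planted modules and a planted interaction."""
    config = SimConfig(
        n_genes=300,
        module_sizes=(50, 50),
        n_per_cell=4,
        within_module_cor=0.7,
        pop_effect_sd=0.5,
        trait_slope={(0, "paxton_limnetic"): 1.5, (0, "paxton_benthic"): -1.5},
        seed=7,
    )
    return config, simulate_dataset(config)


def make_samples(populations, treatments=None, trait=None):
    """Build a minimal sample table from parallel label arrays."""
    n = len(populations)
    ids = [f"s{i}" for i in range(n)]
    table = pd.DataFrame(
        {
            "sample_id": ids,
            "population": list(populations),
            "treatment": list(treatments) if treatments is not None else ["conspecific"] * n,
        }
    )
    if trait is not None:
        table["male_trait"] = np.asarray(trait, dtype=float)
    return table
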