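import numpy as np
import pandas as pd
import pytest

from preterm_maturity import microbiome, simulate


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete cohort configuration."""
    return simulate.SimulationConfig(
        n_infants=16,
        prop_growth_failure=0.5,
        n_taxa=30,
        n_age_taxa=8,
        delay_weeks=3.0,
        library_size_log_mean=np.log(8000.0),
        library_size_log_sd=0.3,
        n_metabolites=20,
        n_age_metabolites=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    metadata, profiles, counts, metabolites, truth = simulate.generate_cohort(
        small_config
    )
    return {
        "config": small_config,
        "metadata": metadata,
        "profiles": profiles,
        "counts": counts,
        "metabolites": metabolites,
        "truth": truth,
    }


@pytest.fixture()
def toy_table():
    counts = pd.DataFrame(
        {"S1": [5, 0, 3], "S2": [1, 2, 0]},
        index=["OTU1", "OTU2", "OTU3"],
    )
    taxonomy = pd.Series(
        {
            "OTU1": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus",
            "OTU2": "Bacteria;Firmicutes;Bacilli;Lactobacillales;Enterococcaceae",
            "OTU3": "Bacteria;Firmicutes;Negativicutes;Veillonellales;Veillonellaceae;Veillonella",
        }
    )
    return microbiome.CountTable(counts, taxonomy)
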