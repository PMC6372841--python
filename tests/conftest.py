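import numpy as np
import pandas as pd
import pytest

from concord.data_model import FeatureTable, SampleMetadata
from concord.synthetic_data import (BiomarkerSimConfig, OmicsSimConfig,
                                    PSMSimConfig, simulate_biomarker_structure,
                                    simulate_paired_omics,
                                    simulate_psm_experiment)


@pytest.fixture(scope="session")
def small_meta() -> SampleMetadata:
    rows = []
    for d, date in enumerate(["2012-01-01", "2012-06-01", "2013-01-01"]):
        for rep in (1, 2, 3):
            rows.append({"sample_id": f"{date}_r{rep}", "date": date,
                         "replicate": rep,
                         "inflammation": "high" if d % 2 else "low"})
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def psm_experiment():
    """Zero-noise, zero-violation TMT experiment with plex scale factors."""
    cfg = PSMSimConfig(n_proteins=60, psms_per_protein=3,
                       plex_scale_range=(0.5, 2.0))
    return simulate_psm_experiment(cfg, seed=11)


@pytest.fixture(scope="session")
def omics_study():
    return simulate_paired_omics(OmicsSimConfig(n_features=400), seed=7)


@pytest.fixture(scope="session")
def biomarker_study():
    base = simulate_paired_omics(OmicsSimConfig(n_features=300), seed=21)
    return simulate_biomarker_structure(
        base, BiomarkerSimConfig(n_strong=200), seed=22)


def random_table(rng: np.random.Generator, n_features: int, n_samples: int,
                 layer: str = "protein", missing: float = 0.0) -> FeatureTable:
    vals = np.exp(rng.normal(0, 1, (n_features, n_samples)))
    if missing:
        vals[rng.random(vals.shape) < missing] = np.nan
    df = pd.DataFrame(vals, index=[f"F{i}" for i in range(n_features)],
                      columns=[f"S{j}" for j in range(n_samples)])
    return FeatureTable(df, layer)
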