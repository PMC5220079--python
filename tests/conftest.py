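import numpy as np
import pandas as pd
import pytest

from spectraqc import (
    ResponseTable,
    SpectralDataset,
    TrialSimConfig,
    simulate_trial,
)


def make_dataset(values, wavelengths=None, k=1, codes=None) -> SpectralDataset:
    """Small hand-built dataset; values is (n_rows, n_wl) with np.nan missing."""
    values = np.asarray(values, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(values.shape[1], dtype=float) + 400.0
    if codes is None:
        codes = [f"S{i}" for i in range(values.shape[0])]
    return SpectralDataset(
        wavelengths=np.asarray(wavelengths, dtype=float),
        codes=codes,
        values=values,
        samples_per_scan=k,
    )


def make_responses(y, name="Yield") -> ResponseTable:
    y = np.asarray(y, dtype=float)
    n = y.size
    return ResponseTable(
        codes=pd.DataFrame(
            {
                "Plot": [str(i + 1) for i in range(n)],
                "Genotype": [f"G{i + 1}" for i in range(n)],
                "Rep": ["1"] * n,
            }
        ),
        variables=pd.DataFrame({name: y}),
    )


@pytest.fixture(scope="session")
def clean_trial():
    """Artifact-free 30-plot trial shared by read-only tests."""
    return simulate_trial(
        TrialSimConfig(n_plots=30, seed=11, within_scan_cv_pct=0.2, sigma=0.1)
    )


@pytest.fixture(scope="session")
def artifact_trial():
    """Trial with a noise band, a drift block and replicate jitter."""
    config = TrialSimConfig(
        n_plots=50,
        seed=7,
        within_scan_cv_pct=0.3,
        noise_bands=((1800.0, 1950.0, 0.5),),
        drift_block=(11, 20, 0.4),
        sigma=0.1,
    )
    return config, simulate_trial(config)
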