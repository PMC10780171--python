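import numpy as np
import pandas as pd
import pytest

import ramanabund as ra


@pytest.fixture(scope="session")
def small_design():
    """Three culture times (one per phase), few cells: fast end-to-end fixture."""
    return ra.GeneratorDesign(cells_per_time=8, culture_times=(1, 5, 16))


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return ra.generate_dataset(small_design, seed=11)


@pytest.fixture(scope="session")
def small_processed(small_dataset):
    sset, truth = small_dataset
    cells = ra.average_replicates(sset, "cell_id")
    proc, report = ra.preprocess_set(cells)
    return proc, report, truth


def make_feature_set(X: np.ndarray, labels: np.ndarray,
                     wavenumbers: np.ndarray | None = None) -> ra.SpectrumSet:
    """Wrap a plain feature matrix + class labels as a SpectrumSet."""
    n, p = X.shape
    w = wavenumbers if wavenumbers is not None else np.arange(400.0, 400.0 + p)
    lab = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "culture_time_h": np.ones(n),
        "phase": labels,
    })
    return ra.SpectrumSet(w, X, lab)
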