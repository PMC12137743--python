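import numpy as np
import pandas as pd
import pytest

import trajphen as tp
from trajphen import synthetic
from trajphen.prep import TrajectoryPanel


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter cohort of 300 patients (seed 1)."""
    return tp.generate_cohort(tp.GeneratorConfig(n_patients=300, seed=1))


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    panel, stats, _ = tp.prepare(small_cohort.raw_vitals, small_cohort.baseline)
    return panel


@pytest.fixture(scope="session")
def small_fit(small_panel):
    """K=4 fit on the small cohort; (model, tau)."""
    return tp.fit_gbmtm(small_panel, K=4, order=3, n_restarts=3, seed=1)


@pytest.fixture(scope="session")
def generator_stats():
    """Z-score stats equal to the generator's natural-unit channel moments.

    Standardizing with these recovers the generator's template scale
    exactly, so fitted coefficients can be compared to templates.
    """
    return pd.DataFrame({
        "channel": list(synthetic.CHANNELS),
        "mean": [synthetic.CHANNEL_STATS[c][0] for c in synthetic.CHANNELS],
        "sd": [synthetic.CHANNEL_STATS[c][1] for c in synthetic.CHANNELS],
    })


def panel_from_values(values, patients=None):
    """Build a TrajectoryPanel directly from a (n, 12, 5) array with NaNs."""
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values).any(axis=2)
    values = values.copy()
    values[~mask] = np.nan
    if patients is None:
        patients = np.array([f"P{i:03d}" for i in range(values.shape[0])])
    return TrajectoryPanel(values=values, mask=mask, patients=patients)
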