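import numpy as np
import pytest

from gazemem import synthetic as syn
from gazemem.geometry import MONITOR_EXP2
from gazemem.types import AOI, AOISet


@pytest.fixture
def clean_cfg():
    """Noise-free simulation: no jitter, no drift, no blinks."""
    return syn.SimConfig(
        fixation_jitter_deg=0.0, drift_step_deg=0.0, blink_prob_per_trial=0.0
    )


@pytest.fixture
def noisy_cfg():
    """Study-condition defaults (jitter, drift, blinks)."""
    return syn.SimConfig()


@pytest.fixture
def layout():
    return syn.generate_aoi_layout("p0", 4, np.random.default_rng(7))


def guided_layout(n_aois: int, seed: int = 0) -> AOISet:
    """An AOI set with interest AOIs plus matching no-interest centroids,
    for scan-path construction on the monitor geometry."""
    rng = np.random.default_rng(seed)
    lay = syn.generate_aoi_layout(
        f"g{seed}", n_aois, rng, geometry=MONITOR_EXP2, min_separation_deg=5.0
    )
    extra = [
        AOI((a.centroid_deg[0] + 2.5, a.centroid_deg[1] - 2.5), 2.0, "no_interest")
        for a in lay.interest
    ]
    return AOISet(lay.picture_id, lay.aois + extra)
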