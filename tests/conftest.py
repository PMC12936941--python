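import numpy as np
import pandas as pd
import pytest

from auxleak.simulate import SyntheticConfig, generate_chamber


def make_track(
    track_id: int,
    lengths,
    frames=None,
    cell_type: str = "WT",
    replicate_id: str = "R1",
    chamber_id: str = "C1",
    x: float = 20.0,
    y: float = 20.0,
    dt_h: float = 5.0 / 60.0,
) -> pd.DataFrame:
    """Hand-built single-track table fragment."""
    lengths = np.asarray(lengths, float)
    frames = np.arange(lengths.size) if frames is None else np.asarray(frames)
    return pd.DataFrame(
        {
            "replicate_id": replicate_id,
            "chamber_id": chamber_id,
            "frame": frames,
            "time_h": frames * dt_h,
            "track_id": track_id,
            "cell_type": cell_type,
            "x_um": x,
            "y_um": y,
            "length_um": lengths,
            "area_um2": lengths * 1.0,
        }
    )


@pytest.fixture(scope="session")
def fast_config() -> SyntheticConfig:
    """Small, quick chamber: 4 h, one chamber's worth of cells."""
    return SyntheticConfig(
        n_initial_cells=40, duration_h=4.0, n_replicates=2, n_chambers=1
    )


@pytest.fixture(scope="session")
def fast_chamber(fast_config):
    tracks, truth = generate_chamber(fast_config, seed=42, return_truth=True)
    return tracks, truth
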