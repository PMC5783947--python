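import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from acescan.simulate import ATP_DNA_APTAMER

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def atp_aptamer():
    """Extended DNA ATP-aptamer construct (coordinates -5..-1, 1..27)."""
    return ATP_DNA_APTAMER


def make_spot_frame(
    median,
    pixel_sd=None,
    background=None,
    subarray_id="s1",
    round_="post_hyb",
    channel="green",
    ace_ids=None,
    replicates=None,
):
    """Minimal valid spot table from parallel arrays."""
    median = np.asarray(median, float)
    n = len(median)
    if pixel_sd is None:
        pixel_sd = 0.05 * median
    if background is None:
        background = np.full(n, 50.0)
    if ace_ids is None:
        ace_ids = [f"ace{i}" for i in range(n)]
    if replicates is None:
        replicates = np.ones(n, int)
    return pd.DataFrame(
        {
            "subarray_id": subarray_id,
            "ace_id": ace_ids,
            "replicate": replicates,
            "round": round_,
            "channel": channel,
            "grid_row": np.arange(n) // 100,
            "grid_col": np.arange(n) % 100,
            "median_signal": median,
            "pixel_sd": np.asarray(pixel_sd, float),
            "background_mean": np.asarray(background, float),
        }
    )
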