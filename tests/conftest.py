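import numpy as np
import pandas as pd
import pytest

from vretvol.controller import ControllerConfig

BASELINE_S = 120


def make_trace(block_hr, block_hmv=None, baseline_seed=0, rest_hr=70.0):
    """Crafted trace: 120-s noisy resting baseline + explicit exposure block.

    ``block_hr`` is the raw HR per second of the exposure block;
    ``block_hmv`` defaults to a constant head velocity (no variability).
    """
    rng = np.random.default_rng(baseline_seed)
    base_hr = rest_hr + rng.normal(0, 1.0, BASELINE_S)
    base_hmv = 40.0 + rng.normal(0, 2.0, BASELINE_S)
    block_hr = np.asarray(block_hr, dtype=float)
    n_block = block_hr.size
    if block_hmv is None:
        block_hmv = np.full(n_block, 40.0)
    else:
        block_hmv = np.asarray(block_hmv, dtype=float)
    n = BASELINE_S + n_block
    return pd.DataFrame(
        {
            "t_s": np.arange(n, dtype=float),
            "hr_bpm": np.concatenate([base_hr, block_hr]),
            "head_vel_dps": np.concatenate([base_hmv, block_hmv]),
            "scene": ["baseline"] * BASELINE_S + ["exposure"] * n_block,
            "difficulty": 1,
        }
    )


def baseline_hr_stats(trace, config=None):
    """Mean/SD of the 5-s-median smoothed HR over the baseline segment."""
    config = config or ControllerConfig()
    hr = pd.Series(trace["hr_bpm"].to_numpy())
    smooth = hr.rolling(config.hr_smooth_window_s, min_periods=1).median().to_numpy()
    base = smooth[:BASELINE_S]
    return float(base.mean()), float(base.std(ddof=1))


@pytest.fixture
def crafted_trace_factory():
    return make_trace
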