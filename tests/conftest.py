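"""Shared fixtures: the two desk-scale recovery experiments.

Both fixtures run the full pipeline in memory — simulate the 13 x 13
factorial (169 sweeps, 501 points each), compress every sweep by greedy
knot elimination, grid-search the network topology (8 hidden sizes x 4
activations x 20 restarts) and evaluate — once per session, under a fixed
seed, in the noise-free and the noisy (sd = 0.02 V) condition.
"""

import hypothesis
import numpy as np
import pandas as pd
import pytest

import thermospline as ts
from thermospline.evaluation import evaluate
from thermospline.pipeline import RunConfig, compress_sweeps

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")

RECOVERY_SEED = 1


def _run_recovery(noise_sd: float) -> dict:
    cfg = RunConfig(noise_sd=noise_sd, seed=RECOVERY_SEED)
    params = cfg.calibrated_params()
    levels = cfg.levels()
    sweeps = ts.generate_dataset(
        levels_eth=levels,
        levels_ace=levels,
        replicates=1,
        noise_sd=noise_sd,
        seed=RECOVERY_SEED,
        params=params,
    )
    table = compress_sweeps(sweeps)
    x = table[[f"f{i}" for i in range(1, 9)]].to_numpy(float)
    c = table[["c_ethanol_pct", "c_acetone_pct"]].to_numpy(float)
    y = np.log2(c)
    split = ts.split_dataset(len(table), seed=RECOVERY_SEED)
    report, model = ts.grid_search(x, y, split, ts.TrainConfig(seed=RECOVERY_SEED))
    eval_report = evaluate(model, x, c, split)
    return {
        "sweeps": sweeps,
        "table": table,
        "x": x,
        "y": y,
        "c": c,
        "split": split,
        "grid_report": report,
        "model": model,
        "eval": eval_report,
    }


@pytest.fixture(scope="session")
def recovery_noise_free() -> dict:
    return _run_recovery(noise_sd=0.0)


@pytest.fixture(scope="session")
def recovery_noisy() -> dict:
    return _run_recovery(noise_sd=0.02)


@pytest.fixture(scope="session")
def calibrated_params():
    return ts.calibrate_amplitudes({"acetone": 4.65, "ethanol": 4.13})
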