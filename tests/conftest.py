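import warnings

import numpy as np
import pandas as pd
import pytest

from decaychase import ChaseDesign, RunConfig, SimConfig, generate_truth, simulate_chase

TIMES = (0.0, 10.0, 50.0, 110.0, 230.0)


@pytest.fixture
def design():
    return ChaseDesign()


@pytest.fixture
def small_truth(design):
    cfg = SimConfig(n_transcripts=60, noise_cv=0.0, seed=5)
    return generate_truth(cfg, design)


def make_matrix(values_by_array, transcripts=None, time_min=0.0, condition="CTRL"):
    """Long expression matrix with one array per replicate at a single time."""
    rows = []
    for rep, values in enumerate(values_by_array, start=1):
        ids = transcripts or [f"T{i:05d}" for i in range(len(values))]
        for tid, v in zip(ids, values):
            rows.append((tid, condition, rep, time_min, float(v), np.nan))
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "condition", "replicate", "time_min", "intensity", "detection_p"],
    )


@pytest.fixture(autouse=True)
def _quiet_zero_variance_warnings():
    # noiseless fixtures legitimately produce zero-variance groups and
    # perfect fits; their RuntimeWarnings are part of the documented contract
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def run_sim(n=300, noise_cv=0.0, beta=1.0, seed=3, **sim_kw):
    from decaychase import run_pipeline

    cfg = RunConfig(
        sim=SimConfig(
            n_transcripts=n,
            noise_cv=noise_cv,
            buffering_exponent_beta=beta,
            seed=seed,
            **sim_kw,
        )
    )
    return run_pipeline(cfg)
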