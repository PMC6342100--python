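import dataclasses
import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from ethotree.preprocess import split_static_dynamic
from ethotree.simulate import generate_trace, scenario_library
from ethotree.tree import classify_hierarchical


@pytest.fixture(scope="session")
def separable_run():
    """A 10-day fully separable deployment, classified end-to-end."""
    cfg = dataclasses.replace(
        scenario_library()["separable"], duration_days=10.0
    )
    trace, truth, obs = generate_trace(cfg, seed=101)
    dyn = split_static_dynamic(trace)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = classify_hierarchical(trace, dyn=dyn)
    return SimpleNamespace(
        cfg=cfg, trace=trace, truth=truth, obs=obs, dyn=dyn, pred=pred
    )


@pytest.fixture(scope="session")
def field_run():
    """A 2-day deployment in the overlapping (field-like) regime."""
    cfg = dataclasses.replace(
        scenario_library()["field_like"], duration_days=2.0
    )
    trace, truth, obs = generate_trace(cfg, seed=202)
    dyn = split_static_dynamic(trace)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = classify_hierarchical(trace, dyn=dyn)
    return SimpleNamespace(
        cfg=cfg, trace=trace, truth=truth, obs=obs, dyn=dyn, pred=pred
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
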