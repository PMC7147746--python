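"""Shared simulation fixtures.

The standard-domain runs are expensive (minutes each), so they are computed
once per session and shared by every test that measures them.
"""

import pytest

from epileptor2d import analysis, config as cfg_mod, engine

MODEL1_SEEDS = (101, 102, 103)
MODEL2_SEEDS = (201, 202, 203)
MODEL1_T = 300.0
MODEL2_T = 550.0


def standard_run(variant: int, seed: int, total_time: float):
    cfg = cfg_mod.load_and_validate({
        "model": {"variant": variant},
        "run": {"seed": seed, "total_time": total_time},
    })
    return engine.run(cfg)


@pytest.fixture(scope="session")
def model1_records():
    """Diffusion-variant standard runs, three seeds."""
    return [standard_run(1, s, MODEL1_T) for s in MODEL1_SEEDS]


@pytest.fixture(scope="session")
def model2_records():
    """Synaptic-variant standard runs, three seeds."""
    return [standard_run(2, s, MODEL2_T) for s in MODEL2_SEEDS]


@pytest.fixture(scope="session")
def model1_summaries(model1_records):
    return [analysis.summarize_record(r) for r in model1_records]


@pytest.fixture(scope="session")
def model2_summaries(model2_records):
    return [analysis.summarize_record(r) for r in model2_records]
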