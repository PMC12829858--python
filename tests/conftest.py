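import numpy as np
import pandas as pd
import pytest

from ffaconcord import (EffectProfile, SampleTable, SimulationConfig,
                        simulate_cohort)


@pytest.fixture(scope="session")
def small_panel():
    return [
        EffectProfile("C6:0", np.log(5.0), 0.5, 0.6),
        EffectProfile("C9:0", np.log(0.2), 0.4, 0.7),
        EffectProfile("C14:0", np.log(40.0), 0.6, 1.0),
        EffectProfile("C16:1", np.log(12.0), 0.5, 0.5),
    ]


@pytest.fixture(scope="session")
def human_table(small_panel):
    cfg = SimulationConfig(panel=small_panel, n_control=30, n_case=40,
                           seed=11, species="human")
    return simulate_cohort(cfg, ("HC", "alMDD"))


@pytest.fixture(scope="session")
def mouse_table(small_panel):
    mouse_panel = [EffectProfile(p.analyte_id, p.log_mean - 0.5,
                                 p.log_sd, p.case_fold_change)
                   for p in small_panel]
    cfg = SimulationConfig(panel=mouse_panel, n_control=6, n_case=6,
                           seed=13, species="mouse")
    return simulate_cohort(cfg, ("saline", "LPS"))


@pytest.fixture
def tiny_table():
    """Hand-written 4-sample, 2-analyte table."""
    df = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "species": "human",
        "group": ["HC", "HC", "alMDD", "alMDD"],
        "C6:0": [2.0, 4.0, 1.0, 3.0],
        "C9:0": [0.1, 0.3, 0.2, 0.4],
    })
    return SampleTable(df, ["C6:0", "C9:0"])
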