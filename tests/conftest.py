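import numpy as np
import pandas as pd
import pytest

from v1phys.synthetic_data import (
    APTemplate,
    CalciumSimConfig,
    EphysSimConfig,
    TuningParams,
    generate_calcium_dataset,
    generate_current_clamp_recording,
    generate_stimulus_schedule,
)


@pytest.fixture(scope="session")
def default_ephys():
    """Noiseless default simulation: (config, sweeps, ground truth)."""
    cfg = EphysSimConfig(seed=0)
    sweeps, truth = generate_current_clamp_recording(cfg)
    return cfg, sweeps, truth


@pytest.fixture(scope="session")
def small_ephys_cfg():
    """Fast 4-sweep protocol for Monte-Carlo loops."""
    return EphysSimConfig(
        current_steps_pA=(-50.0, 100.0, 150.0, 250.0),
        rheobase_pA=150.0,
        pre_ms=50.0,
        post_ms=50.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_calcium_cfg():
    return CalciumSimConfig(
        n_animals_per_genotype={"WT": 1, "TS": 1},
        cells_per_animal=20,
        sf_grid=(0.014, 0.064, 0.236),
        contrast_grid=(1.0, 0.25, 0.067),
        fraction_nonresponsive=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_calcium_cfg):
    return generate_calcium_dataset(small_calcium_cfg)


def cs_table_for(cohort):
    from v1phys import csf_pipeline as csf

    return pd.concat(
        [csf.build_cs_table(ds, sched.epochs) for _, ds, sched in cohort.items()],
        ignore_index=True,
    )
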