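import os

# single-threaded BLAS so training trajectories are reproducible
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from sonomtl.dataio import SplitAssignment, split_by_patient
from sonomtl.losses import LossConfig
from sonomtl.model import BackboneSpec
from sonomtl.synthgen import SyntheticConfig, generate_dataset
from sonomtl.train import TrainConfig, run_repeats


@pytest.fixture(scope="session")
def small_records():
    """A small split synthetic cohort shared by fast unit tests."""
    records = generate_dataset(SyntheticConfig(n_patients=40, seed=123))
    return split_by_patient(records, SplitAssignment(seed=7))


@pytest.fixture(scope="session")
def tiny_train_setup():
    """Minimal training configuration for trajectory-level tests (seconds)."""
    records = generate_dataset(
        SyntheticConfig(n_patients=20, p_malignant=0.6, seed=0, image_size=64)
    )
    records = split_by_patient(records, SplitAssignment(seed=1))
    backbone = BackboneSpec(widths=(4, 8), input_size=16)
    train_cfg = TrainConfig(epochs=2, lr_step=1, batch_size=8, n_repeats=1, base_seed=3)
    return records, backbone, train_cfg


@pytest.fixture(scope="session")
def mechanism_runs():
    """The headline comparison: multitask vs multitask+hinge on the default
    synthetic cohort (300 patients, effect size 1.5, 5 repeats, fixed seeds).

    Trained once per session; reused by the mechanism and Grad-CAM tests.
    """
    records = generate_dataset(SyntheticConfig(seed=0))
    records = split_by_patient(records, SplitAssignment(seed=0))
    out = {"records": records}
    for arm in ("multitask", "multitask_hl"):
        models, hists, reports = run_repeats(
            records, BackboneSpec(), LossConfig(), TrainConfig(arm=arm, base_seed=0)
        )
        out[arm] = {"models": models, "histories": hists, "reports": reports}
    return out


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
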