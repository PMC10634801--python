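import numpy as np
import pytest

from layervn.connectivity import depth_fc_matrix
from layervn.cortex import (
    BlockParadigm,
    CorticalColumnSpec,
    default_network,
    make_subject_cohort,
)
from layervn.pipeline import preprocess_run
from layervn.preprocess import make_task_design


@pytest.fixture(scope="session")
def column():
    return CorticalColumnSpec()


@pytest.fixture(scope="session")
def paradigm():
    return BlockParadigm()


@pytest.fixture(scope="session")
def task_design(paradigm):
    return make_task_design(paradigm)


@pytest.fixture(scope="session")
def cohort14():
    """Default paired-condition resting cohort (N=14, b in {0, 7})."""
    return make_subject_cohort(n_subjects=14, seed=20240)


@pytest.fixture(scope="session")
def cohort14_depth_matrices(cohort14):
    """Per-subject depth x depth Fisher-z matrices for both conditions."""
    net = default_network()
    mats = {0.0: [], 7.0: []}
    for subj in cohort14:
        for b in (0.0, 7.0):
            per_roi = [preprocess_run(subj.runs[b][roi]) for roi in net.rois]
            mats[b].append(
                depth_fc_matrix(per_roi, condition=f"b={b}", subject_id=subj.subject_id)
            )
    return mats


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
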