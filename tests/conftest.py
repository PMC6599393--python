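import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles/helpers importable

from statedyn.io_cohort import GROUP_KEYS, SubjectRecord, TimeSeriesRun


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_run(rng, run_id="r1", subject_id="s1", t=30, c=4):
    return TimeSeriesRun(
        subject_id=subject_id,
        run_id=run_id,
        data=rng.normal(size=(t, c)),
        channel_labels=[f"roi_{i + 1}" for i in range(c)],
    )


@pytest.fixture
def tiny_cohort(rng):
    """One run per group plus matching phenotypes (4 runs, T=30, C=4)."""
    runs, phenos = [], []
    for i, (sex, dx) in enumerate(GROUP_KEYS):
        run = make_run(rng, run_id=f"run{i}", subject_id=f"sub{i}")
        runs.append(run)
        phenos.append(
            SubjectRecord(
                subject_id=f"sub{i}", run_id=f"run{i}", sex=sex, diagnosis=dx
            )
        )
    return runs, phenos
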