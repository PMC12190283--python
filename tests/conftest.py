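import math

import numpy as np
import pytest

from eegmfe.cohort import SynthConfig, generate_cohort
from eegmfe.preprocess import preprocess
from eegmfe.recording import Recording


def brute_force_fuzzen(x, m, n, r):
    """Independent O(N^2) double-loop fuzzy-entropy oracle.

    Deliberately naive: explicit python loops, per-template mean
    subtraction recomputed in place, no vectorized reuse.
    """
    x = np.asarray(x, dtype=float)
    N = len(x)

    def phi(dim):
        templates = []
        for i in range(N - m):
            v = x[i : i + dim]
            templates.append(v - sum(v) / dim)
        total = 0.0
        count = 0
        for i in range(N - m):
            for j in range(N - m):
                if i == j:
                    continue
                d = max(abs(templates[i][k] - templates[j][k]) for k in range(dim))
                total += math.exp(-(d ** n) / r)
                count += 1
        return total / count

    return math.log(phi(m)) - math.log(phi(m + 1))


def make_recording(data, fs=200.0, subject_id="s0", group="HS", dataset_id="A",
                   channel_names=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if channel_names is None:
        channel_names = [f"CH{i+1}" for i in range(data.shape[0])]
    return Recording(
        subject_id=subject_id, group=group, dataset_id=dataset_id,
        fs=fs, channel_names=channel_names, data=data,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject default-dynamics cohort, 12 s each (fast)."""
    cfg = SynthConfig(n_subjects_per_group=3, duration=12.0, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def preprocessed_cohort20():
    """Twenty preprocessed subjects at the full 51 s duration.

    Shared by the correlation-preservation and null-calibration checks.
    """
    cfg = SynthConfig(n_subjects_per_group=10, seed=17)
    return [preprocess(rec) for rec in generate_cohort(cfg)]
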