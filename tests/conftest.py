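import numpy as np
import pytest

from neuroaudit import SampleTable, SyntheticConfig, generate


@pytest.fixture
def tiny_table() -> SampleTable:
    """4 rows, 2 subjects x 2 instances, 3 features, binary labels."""
    return SampleTable(
        features=np.arange(12, dtype=float).reshape(4, 3),
        labels=np.array([0, 1, 0, 1]),
        label_names=("neg", "pos"),
        subject_id=np.array(["s1", "s1", "s2", "s2"]),
        session_id=np.array(["a", "a", "a", "a"]),
        time_index=np.array([0, 1, 0, 1]),
    )


@pytest.fixture
def session_table() -> SampleTable:
    """4 subjects x 3 sessions x 6 instances with trial structure."""
    cfg = SyntheticConfig(
        n_subjects=4, n_sessions=3, n_per_session=6, n_features=6, seed=11
    )
    table = generate(cfg)
    # two trials of three instances per session
    trial = np.where(table.time_index < 3, "t0", "t1")
    return SampleTable(
        features=table.features,
        labels=table.labels,
        label_names=table.label_names,
        subject_id=table.subject_id,
        session_id=table.session_id,
        time_index=table.time_index,
        trial_id=trial,
    )


def random_small_table(rng) -> SampleTable:
    """A random small hierarchical table for property checks."""
    m = int(rng.integers(2, 6))
    s = int(rng.integers(1, 4))
    n = int(rng.integers(3, 9))
    d = int(rng.integers(1, 5))
    rows = m * s * n
    trial = rng.random() < 0.5
    return SampleTable(
        features=rng.standard_normal((rows, d)),
        labels=rng.integers(0, 2, size=rows),
        label_names=("a", "b"),
        subject_id=np.repeat([f"s{i}" for i in range(m)], s * n),
        session_id=np.tile(np.repeat([f"x{j}" for j in range(s)], n), m),
        time_index=np.tile(np.arange(n), m * s),
        # three near-equal trials per session when long enough, else two
        trial_id=(
            np.tile((np.arange(n) * (3 if n >= 6 else 2) // n).astype(str), m * s)
            if trial
            else None
        ),
    )
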