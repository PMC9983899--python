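import numpy as np
import pytest

import pushpull as pp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


def random_pair_model(rng, stable=True):
    """Random admissible pair model with PSD Q, R."""
    a = rng.normal(0, 0.5, 2)
    A = rng.normal(0, 0.6, (2, 2))
    if stable:
        A = A - 1.2 * np.eye(2)
    L = rng.normal(0, 0.7, (2, 2))
    Q = L @ L.T + 0.1 * np.eye(2)
    M = rng.normal(0, 0.5, (2, 2))
    R = M @ M.T + 0.05 * np.eye(2)
    return pp.PairModel(a=a, A=A, Q=Q, R=R)


def random_series(rng, n_max=6, p_missing=0.25, p_dup=0.3):
    """Small random series with dt = 0 repeats and missing components."""
    n = int(rng.integers(1, n_max + 1))
    gaps = rng.exponential(0.5, n)
    gaps[rng.random(n) < p_dup] = 0.0
    gaps[0] = abs(gaps[0])
    t = np.cumsum(gaps)
    y = rng.normal(0, 1.5, (n, 2))
    miss = rng.random((n, 2)) < p_missing
    # keep at least one observed component per record
    both = miss.all(axis=1)
    miss[both, rng.integers(0, 2, both.sum())] = False
    y[miss] = np.nan
    return pp.PairSeries("x", t, y)


@pytest.fixture(scope="session")
def small_null_cohort():
    """A = 0 cohort with correlated drive and noise, preprocessed."""
    n = 6
    names = tuple(f"B{i}" for i in range(n))
    u = np.ones(n)
    u[n // 2:] = -1
    spec = pp.TruthSpec(
        biomarkers=names, a=np.zeros(n), A=np.zeros((n, n)),
        Q=0.6 * np.eye(n) + 0.4 * np.outer(u, u), R=0.25 * np.eye(n),
        drift_slopes=np.zeros(n), n_animals=25,
        lifespan_range=(15.0, 30.0), mean_gap=0.4,
        same_day_repeat_prob=0.08, missing_prob=0.05, seed=11)
    cohort = pp.generate_cohort(spec)
    cfg = pp.PanelConfig(biomarkers=names, exclusion_rules=(),
                         drop_list=frozenset())
    pre = pp.preprocess_cohort(cohort.table, cfg)
    return spec, cohort, pre
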