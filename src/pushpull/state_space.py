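"""Pairwise (d = 2) linear SDE observed through Gaussian noise.

The latent pair of biomarkers X(t) follows

    dX(t) = [a + A X(t)] dt + B dW(t),        Q = B B^T,

and is observed as Y(t) = X(t) + C eps(t) with R = C C^T, eps ~ N(0, I)
independent at every observation time.  Fitting treats each observation gap
as a single Euler step (transition I + A dt, process covariance dt Q) —
the one-step vector-autoregression view of the SDE — so repeated same-day
draws (dt = 0) share one latent state and differ only through R.  That
dt = 0 structure is what separates the stochastic drive Q from the
observation noise R.

The free parameters are a (2), A (4), Q (3), R (3): 12 in total.  The
initial-state prior is fixed at N(0, I) (data are normalized per animal)
and is not counted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .errors import DegenerateInputError, NumericalError

__all__ = [
    "PairModel",
    "PairSeries",
    "StatePosterior",
    "transition_moments",
    "simulate_pair",
    "kalman_filter",
    "kalman_smooth",
    "joint_loglik_oracle",
    "joint_posterior_oracle",
    "pair_series_from_table",
]


def _as_psd(M, name):
    M = np.asarray(M, dtype=float)
    if M.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(M).min() < -1e-10:
        raise ValueError(f"{name} must be positive semidefinite")
    return 0.5 * (M + M.T)


@dataclass
class PairModel:
    """The 12-parameter pairwise SDE model.

    ``A[v, v']`` is the effect of source biomarker v' on target v, in 1/year.
    """

    a: np.ndarray
    A: np.ndarray
    Q: np.ndarray
    R: np.ndarray
    mu0: np.ndarray = field(default_factory=lambda: np.zeros(2))
    Sigma0: np.ndarray = field(default_factory=lambda: np.eye(2))

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float).reshape(2)
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.Q = _as_psd(self.Q, "Q")
        self.R = _as_psd(self.R, "R")
        self.mu0 = np.asarray(self.mu0, dtype=float).reshape(2)
        self.Sigma0 = _as_psd(self.Sigma0, "Sigma0")

    @property
    def n_free_parameters(self) -> int:
        """Free parameters excluding the fixed initial-state prior."""
        return self.a.size + self.A.size + 3 + 3  # a:2 + A:4 + Q:3 + R:3

    def parameter_vector(self) -> np.ndarray:
        """Flatten (a, A, Q, R) to the canonical 12-vector."""
        return np.concatenate([
            self.a,
            self.A.ravel(),
            [self.Q[0, 0], self.Q[0, 1], self.Q[1, 1]],
            [self.R[0, 0], self.R[0, 1], self.R[1, 1]],
        ])

    @staticmethod
    def parameter_names() -> list[str]:
        return ["a1", "a2", "A11", "A12", "A21", "A22",
                "Q11", "Q12", "Q22", "R11", "R12", "R22"]

    def swapped(self) -> "PairModel":
        """The same model with the two biomarkers' roles exchanged."""
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        return PairModel(self.a[::-1], P @ self.A @ P, P @ self.Q @ P,
                         P @ self.R @ P, self.mu0[::-1], P @ self.Sigma0 @ P)


@dataclass
class PairSeries:
    """One animal's time-ordered 2-vector observations (NaN = missing)."""

    animal_id: str
    times: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float).reshape(-1)
        self.y = np.asarray(self.y, dtype=float).reshape(-1, 2)
        if self.y.shape[0] != self.times.shape[0]:
            raise ValueError("times and observations differ in length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    def __len__(self):
        return self.times.size


@dataclass
class StatePosterior:
    """Filtered or smoothed state estimates for one series."""

    times: np.ndarray
    means: np.ndarray          # (n, 2)
    covs: np.ndarray           # (n, 2, 2)
    cross: np.ndarray | None   # (n-1, 2, 2): Cov(x_{i+1}, x_i) when smoothed
    loglik: float
    kind: str = "filtered"


def transition_moments(model: PairModel, x, dt: float):
    """Single-Euler-step transition mean and covariance over a gap dt."""
    if dt < 0 or not np.isfinite(dt):
        raise ValueError("dt must be finite and non-negative")
    x = np.asarray(x, dtype=float).reshape(2)
    mean = x + (model.a + model.A @ x) * dt
    cov = dt * model.Q
    return mean, cov


def simulate_pair(model: PairModel, times: Sequence[float], seed: int,
                  substeps_per_year: int = 365):
    """Simulate latent and observed trajectories at the given times.

    The latent path advances by Euler–Maruyama with internal step at most
    1/substeps_per_year between consecutive distinct times; duplicate times
    share the latent state and receive independent observation noise.
    """
    times = np.asarray(times, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    if substeps_per_year < 1:
        raise ValueError("substeps_per_year must be >= 1")
    rng = np.random.default_rng(seed)
    n = times.size
    X = np.zeros((n, 2))
    Y = np.zeros((n, 2))
    sqQ = np.linalg.cholesky(model.Q + 1e-300 * np.eye(2))
    sqR = np.linalg.cholesky(model.R + 1e-300 * np.eye(2))
    x = model.mu0 + np.linalg.cholesky(
        model.Sigma0 + 1e-300 * np.eye(2)) @ rng.standard_normal(2)
    h_max = 1.0 / substeps_per_year
    for i in range(n):
        if i > 0:
            gap = times[i] - times[i - 1]
            if gap > 0:
                nsub = max(1, int(np.ceil(gap / h_max)))
                h = gap / nsub
                for _ in range(nsub):
                    x = x + (model.a + model.A @ x) * h \
                        + np.sqrt(h) * (sqQ @ rng.standard_normal(2))
        X[i] = x
        Y[i] = x + sqR @ rng.standard_normal(2)
    return X, Y


# ---------------------------------------------------------------------------
# Kalman filtering / smoothing (compiled kernel under the hood)
# ---------------------------------------------------------------------------

def _run_kernel(model: PairModel, times, y, starts, ends):
    n = times.shape[0]
    pm = np.zeros((n, 2))
    pP = np.zeros((n, 2, 2))
    fm = np.zeros((n, 2))
    fP = np.zeros((n, 2, 2))
    sm = np.zeros((n, 2))
    sP = np.zeros((n, 2, 2))
    cross = np.zeros((max(n, 1), 2, 2))
    ll, status, bad = _kernels.filter_smooth(
        np.ascontiguousarray(times, dtype=float),
        np.ascontiguousarray(y, dtype=float),
        np.ascontiguousarray(starts, dtype=np.int64),
        np.ascontiguousarray(ends, dtype=np.int64),
        model.a, model.A, model.Q, model.R, model.mu0, model.Sigma0,
        pm, pP, fm, fP, sm, sP, cross)
    if status == _kernels.SINGULAR_INNOVATION:
        raise NumericalError(
            f"singular innovation covariance at time index {bad}")
    if status == _kernels.NONFINITE:
        raise NumericalError(
            f"non-finite state propagation at time index {bad} "
            "(unstable A over a long gap?)")
    return ll, pm, pP, fm, fP, sm, sP, cross


def kalman_filter(model: PairModel, series: PairSeries) -> StatePosterior:
    """Forward filter; returns filtered moments and the exact log-likelihood."""
    n = len(series)
    if n == 0:
        return StatePosterior(series.times, np.zeros((0, 2)),
                              np.zeros((0, 2, 2)), None, 0.0, "filtered")
    ll, _, _, fm, fP, _, _, _ = _run_kernel(
        model, series.times, series.y, np.array([0]), np.array([n]))
    return StatePosterior(series.times, fm, fP, None, ll, "filtered")


def kalman_smooth(model: PairModel, series: PairSeries) -> StatePosterior:
    """Fixed-interval smoother with adjacent cross-covariances."""
    n = len(series)
    if n == 0:
        return StatePosterior(series.times, np.zeros((0, 2)),
                              np.zeros((0, 2, 2)), np.zeros((0, 2, 2)),
                              0.0, "smoothed")
    ll, _, _, _, _, sm, sP, cross = _run_kernel(
        model, series.times, series.y, np.array([0]), np.array([n]))
    return StatePosterior(series.times, sm, sP, cross[:n - 1], ll, "smoothed")


# ---------------------------------------------------------------------------
# Brute-force joint-Gaussian oracle (independent of the kernel)
# ---------------------------------------------------------------------------

def _joint_moments(model: PairModel, series: PairSeries):
    """Joint mean/covariance of all latent states and of observed components."""
    t = series.times
    n = t.size
    mean = np.zeros(2 * n)
    cov = np.zeros((2 * n, 2 * n))
    mean[0:2] = model.mu0
    cov[0:2, 0:2] = model.Sigma0
    I2 = np.eye(2)
    for i in range(1, n):
        dt = t[i] - t[i - 1]
        F = I2 + model.A * dt
        mean[2 * i:2 * i + 2] = F @ mean[2 * (i - 1):2 * i] + model.a * dt
        for j in range(i):
            blk = F @ cov[2 * (i - 1):2 * i, 2 * j:2 * j + 2]
            cov[2 * i:2 * i + 2, 2 * j:2 * j + 2] = blk
            cov[2 * j:2 * j + 2, 2 * i:2 * i + 2] = blk.T
        cov[2 * i:2 * i + 2, 2 * i:2 * i + 2] = (
            F @ cov[2 * (i - 1):2 * i, 2 * (i - 1):2 * i] @ F.T + dt * model.Q)
    # observed components
    obs_idx = []
    for i in range(n):
        for c in range(2):
            if not np.isnan(series.y[i, c]):
                obs_idx.append((i, c))
    m = len(obs_idx)
    flat = np.array([2 * i + c for i, c in obs_idx], dtype=int)
    mz = mean[flat]
    Cz = cov[np.ix_(flat, flat)].copy()
    # independent observation noise per record (full R sub-block per time)
    for p, (i, c) in enumerate(obs_idx):
        for q, (j, d) in enumerate(obs_idx):
            if i == j:
                Cz[p, q] += model.R[c, d]
    z = np.array([series.y[i, c] for i, c in obs_idx])
    return mean, cov, flat, z, mz, Cz


def joint_loglik_oracle(model: PairModel, series: PairSeries) -> float:
    """Exact log-likelihood from the explicit joint Gaussian (small n only)."""
    n_obs = int(np.sum(~np.isnan(series.y)))
    if n_obs > 40:
        raise DegenerateInputError("oracle limited to <= 40 observed components")
    if n_obs == 0:
        return 0.0
    _, _, _, z, mz, Cz = _joint_moments(model, series)
    try:
        return float(stats.multivariate_normal(mean=mz, cov=Cz).logpdf(z))
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError(f"singular joint covariance: {exc}") from exc


def joint_posterior_oracle(model: PairModel, series: PairSeries):
    """Conditional latent means/covs given the data, by direct conditioning.

    Returns (means (n,2), covs (n,2,2), cross (n-1,2,2)) where
    cross[i] = Cov(x_{i+1}, x_i | data).
    """
    n = len(series)
    mean, cov, flat, z, mz, Cz = _joint_moments(model, series)
    Cxz = cov[:, flat]
    gain = np.linalg.solve(Cz, Cxz.T).T
    mpost = mean + gain @ (z - mz)
    Cpost = cov - gain @ Cxz.T
    means = mpost.reshape(n, 2)
    covs = np.array([Cpost[2 * i:2 * i + 2, 2 * i:2 * i + 2] for i in range(n)])
    cross = np.array([Cpost[2 * (i + 1):2 * (i + 1) + 2, 2 * i:2 * i + 2]
                      for i in range(n - 1)]) if n > 1 else np.zeros((0, 2, 2))
    return means, covs, cross


# ---------------------------------------------------------------------------
# Long-format table <-> PairSeries
# ---------------------------------------------------------------------------

def pair_series_from_table(table: pd.DataFrame, pair: tuple[str, str]
                           ) -> list[PairSeries]:
    """Pivot a normalized long-format table into per-animal pair series.

    Visits are reconstructed from (animal, age): the k-th record of a
    biomarker at the same (animal, age) is assigned to the k-th same-day
    visit, so same-day repeated draws become distinct dt = 0 records.
    Records where both pair components are missing are dropped.
    """
    v, w = pair
    sub = table[table["biomarker"].isin([v, w])].copy()
    sub["rep"] = sub.groupby(["animal_id", "age_years", "biomarker"]).cumcount()
    wide = sub.pivot_table(index=["animal_id", "age_years", "rep"],
                           columns="biomarker", values="value",
                           aggfunc="first")
    for col in (v, w):
        if col not in wide.columns:
            wide[col] = np.nan
    wide = wide[[v, w]].reset_index().sort_values(
        ["animal_id", "age_years", "rep"], kind="mergesort")
    out = []
    for animal, grp in wide.groupby("animal_id", sort=True):
        y = grp[[v, w]].to_numpy(dtype=float)
        keep = ~np.all(np.isnan(y), axis=1)
        if not keep.any():
            continue
        out.append(PairSeries(str(animal),
                              grp["age_years"].to_numpy(dtype=float)[keep],
                              y[keep]))
    return out
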