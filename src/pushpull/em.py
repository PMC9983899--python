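"""EM estimation of the 12 pairwise SDE parameters, pooled across animals.

The E-step runs the Kalman smoother per animal and accumulates the expected
sufficient statistics of the complete-data log-likelihood; the M-step solves
the generalized-least-squares normal equations for (a, A) over all gaps with
dt > 0 (weight 1/dt, residual r = x' - x - (a + A x) dt), updates
Q as the weighted mean expected residual outer-product, and updates R from
the expected observation-noise outer-products.  For records with a missing
component the noise vector is treated as latent, so the R update is an exact
M-step and the likelihood trace is non-decreasing.

Same-day repeats (dt = 0) inform R through the filter but carry no dynamical
information and are excluded from the (a, A, Q) regression.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .errors import DegenerateInputError, EstimationError, NumericalError
from .state_space import PairModel, PairSeries

__all__ = ["FitConfig", "FitResult", "SufficientStats", "PackedSeries",
           "e_step", "m_step", "fit_pair"]


@dataclass
class FitConfig:
    max_iters: int = 500
    rel_tol: float = 1e-6
    psd_floor: float = 1e-10
    init: str = "diagnostics"      # "diagnostics" or "fixed"
    init_q: float = 1.0
    init_r: float = 0.25
    min_animals: int = 2
    min_observations: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.rel_tol <= 0 or self.psd_floor <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class SufficientStats:
    """Accumulated E-step expectations (see module docstring)."""

    S_uu: np.ndarray       # (3, 3): sum_gaps dt * E[u u^T],  u = (1, x)
    S_ud: np.ndarray       # (3, 2): sum_gaps E[u d^T],       d = x' - x
    S_dd: np.ndarray       # (2, 2): sum_gaps E[d d^T] / dt
    n_gaps: int
    S_ee: np.ndarray       # (2, 2): sum_times E[eps eps^T]
    n_times: int
    loglik: float

    def __add__(self, other: "SufficientStats") -> "SufficientStats":
        return SufficientStats(self.S_uu + other.S_uu,
                               self.S_ud + other.S_ud,
                               self.S_dd + other.S_dd,
                               self.n_gaps + other.n_gaps,
                               self.S_ee + other.S_ee,
                               self.n_times + other.n_times,
                               self.loglik + other.loglik)


@dataclass
class FitResult:
    model: PairModel
    loglik: float
    trace: np.ndarray
    n_iters: int
    converged: bool


class PackedSeries:
    """Concatenated per-animal series in kernel-ready flat arrays."""

    def __init__(self, times, y, starts, ends, animal_ids):
        self.times = np.ascontiguousarray(times, dtype=float)
        self.y = np.ascontiguousarray(y, dtype=float)
        self.starts = np.ascontiguousarray(starts, dtype=np.int64)
        self.ends = np.ascontiguousarray(ends, dtype=np.int64)
        self.animal_ids = list(animal_ids)
        n = self.times.shape[0]
        # left endpoints of within-animal adjacent gaps
        gap = []
        for s, e in zip(self.starts, self.ends):
            gap.extend(range(s, e - 1))
        self.gap_idx = np.asarray(gap, dtype=np.int64)

    @classmethod
    def from_series(cls, sequences: Sequence[PairSeries]) -> "PackedSeries":
        seqs = [s for s in sequences if len(s) > 0]
        if not seqs:
            return cls(np.zeros(0), np.zeros((0, 2)), np.zeros(0, dtype=int),
                       np.zeros(0, dtype=int), [])
        times = np.concatenate([s.times for s in seqs])
        y = np.concatenate([s.y for s in seqs])
        lens = np.array([len(s) for s in seqs])
        ends = np.cumsum(lens)
        starts = ends - lens
        return cls(times, y, starts, ends, [s.animal_id for s in seqs])

    @property
    def n_obs(self) -> int:
        return int(self.times.shape[0])

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)


def _pack(sequences) -> PackedSeries:
    if isinstance(sequences, PackedSeries):
        return sequences
    return PackedSeries.from_series(sequences)


def _run_packed(model: PairModel, packed: PackedSeries):
    n = packed.n_obs
    pm = np.zeros((n, 2))
    pP = np.zeros((n, 2, 2))
    fm = np.zeros((n, 2))
    fP = np.zeros((n, 2, 2))
    sm = np.zeros((n, 2))
    sP = np.zeros((n, 2, 2))
    cross = np.zeros((max(n, 1), 2, 2))
    ll, status, bad = _kernels.filter_smooth(
        packed.times, packed.y, packed.starts, packed.ends,
        model.a, model.A, model.Q, model.R, model.mu0, model.Sigma0,
        pm, pP, fm, fP, sm, sP, cross)
    if status != _kernels.OK:
        k = int(np.searchsorted(packed.ends, bad, side="right"))
        animal = packed.animal_ids[k] if k < len(packed.animal_ids) else "?"
        if status == _kernels.SINGULAR_INNOVATION:
            raise NumericalError(
                f"singular innovation covariance at index {bad} "
                f"(animal {animal})")
        raise NumericalError(
            f"non-finite state propagation at index {bad} (animal {animal}); "
            "unstable A over a long gap?")
    return ll, sm, sP, cross


def e_step(model: PairModel, sequences) -> SufficientStats:
    """Smooth every animal's series and accumulate sufficient statistics."""
    packed = _pack(sequences)
    n = packed.n_obs
    if n == 0:
        z2 = np.zeros((2, 2))
        return SufficientStats(np.zeros((3, 3)), np.zeros((3, 2)), z2, 0,
                               z2.copy(), 0, 0.0)
    ll, sm, sP, cross = _run_packed(model, packed)

    g = packed.gap_idx
    dt = packed.times[g + 1] - packed.times[g]
    pos = dt > 0
    g0, dt0 = g[pos], dt[pos]
    Ex = sm[g0]
    Exn = sm[g0 + 1]
    Exx = sP[g0] + np.einsum("ni,nj->nij", Ex, Ex)
    Exnxn = sP[g0 + 1] + np.einsum("ni,nj->nij", Exn, Exn)
    Exnx = cross[g0] + np.einsum("ni,nj->nij", Exn, Ex)

    S_uu = np.zeros((3, 3))
    S_uu[0, 0] = dt0.sum()
    S_uu[0, 1:] = dt0 @ Ex
    S_uu[1:, 0] = S_uu[0, 1:]
    S_uu[1:, 1:] = np.einsum("n,nij->ij", dt0, Exx)

    Ed = Exn - Ex
    ExnxT = np.transpose(Exnx, (0, 2, 1))          # E[x x'^T]
    Edd = Exnxn - Exnx - ExnxT + Exx
    Exd = ExnxT - Exx                               # E[x d^T]
    S_ud = np.zeros((3, 2))
    S_ud[0] = Ed.sum(axis=0)
    S_ud[1:] = Exd.sum(axis=0)
    S_dd = np.einsum("nij,n->ij", Edd, 1.0 / dt0)

    # observation-noise expectations (noise vector latent when a component
    # is missing: conditional moments use the current R)
    y = packed.y
    miss = np.isnan(y)
    r = np.where(miss, 0.0, y - sm)
    S_ee = np.zeros((2, 2))
    both = ~miss[:, 0] & ~miss[:, 1]
    if both.any():
        rb = r[both]
        S_ee += np.einsum("ni,nj->ij", rb, rb) + sP[both].sum(axis=0)
    R = model.R
    for o, u in ((0, 1), (1, 0)):
        only = ~miss[:, o] & miss[:, u]
        if not only.any():
            continue
        e2 = np.sum(r[only, o] ** 2 + sP[only, o, o])
        cnt = int(only.sum())
        c = R[u, o] / R[o, o] if R[o, o] > 1e-300 else 0.0
        S_ee[o, o] += e2
        S_ee[u, o] += c * e2
        S_ee[o, u] += c * e2
        S_ee[u, u] += c * c * e2 + cnt * (R[u, u] - c * R[u, o])
    none = miss[:, 0] & miss[:, 1]
    if none.any():
        S_ee += int(none.sum()) * R

    return SufficientStats(S_uu, S_ud, S_dd, int(pos.sum()),
                           S_ee, n, float(ll))


def _psd_clip(M: np.ndarray, floor: float) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    return (V * np.maximum(w, floor)) @ V.T


def m_step(stats: SufficientStats, cfg: FitConfig,
           fix_A_zero: bool = False) -> PairModel:
    """Closed-form parameter update from accumulated sufficient statistics."""
    if stats.n_gaps < 1 or stats.n_times < 1:
        raise DegenerateInputError(
            "need at least one dt > 0 gap and one observation")
    if fix_A_zero:
        a = stats.S_ud[0] / stats.S_uu[0, 0]
        Theta = np.column_stack([a, np.zeros((2, 2))])
    else:
        cond = np.linalg.cond(stats.S_uu)
        if not np.isfinite(cond) or cond > 1e12:
            raise EstimationError(
                "rank-deficient regression design (states nearly constant "
                f"or collinear; cond = {cond:.2e})")
        Theta = np.linalg.solve(stats.S_uu, stats.S_ud).T   # (2, 3)
    TS = Theta @ stats.S_ud                                  # (2, 2)
    Q = (stats.S_dd - TS - TS.T + Theta @ stats.S_uu @ Theta.T) / stats.n_gaps
    Q = _psd_clip(Q, cfg.psd_floor)
    R = _psd_clip(stats.S_ee / stats.n_times, cfg.psd_floor)
    return PairModel(a=Theta[:, 0], A=Theta[:, 1:], Q=Q, R=R)


def _initial_model(packed: PackedSeries, cfg: FitConfig) -> PairModel:
    """Data-driven start: R from dt = 0 repeats, Q from the increment slope."""
    q0 = cfg.init_q
    r0 = cfg.init_r
    if cfg.init == "diagnostics" and packed.n_obs:
        g = packed.gap_idx
        dt = packed.times[g + 1] - packed.times[g]
        dy = packed.y[g + 1] - packed.y[g]
        complete = ~np.isnan(dy).any(axis=1)
        z = complete & (dt == 0)
        if z.sum() >= 5:
            r0 = float(np.mean(dy[z] ** 2) / 2.0)   # dt=0 increments have var 2R
        p = complete & (dt > 0)
        if p.sum() >= 10 and np.var(dt[p]) > 0:
            d2 = np.mean(dy[p] ** 2, axis=1)
            slope = np.polyfit(dt[p], d2, 1)[0]
            q0 = float(max(slope, cfg.psd_floor))
    return PairModel(a=np.zeros(2), A=np.zeros((2, 2)),
                     Q=max(q0, cfg.psd_floor) * np.eye(2),
                     R=max(r0, cfg.psd_floor) * np.eye(2))


def fit_pair(sequences, cfg: FitConfig | None = None,
             fix_A_zero: bool = False) -> FitResult:
    """Alternate E and M steps until the log-likelihood stabilizes."""
    cfg = cfg or FitConfig()
    packed = _pack(sequences)
    if packed.n_animals < cfg.min_animals and packed.n_obs < cfg.min_observations:
        raise DegenerateInputError(
            f"too little data: {packed.n_animals} animals, "
            f"{packed.n_obs} observations")
    model = _initial_model(packed, cfg)
    trace = []
    converged = False
    for _ in range(cfg.max_iters):
        stats = e_step(model, packed)
        trace.append(stats.loglik)
        if len(trace) > 1:
            if abs(trace[-1] - trace[-2]) / (1.0 + abs(trace[-2])) < cfg.rel_tol:
                converged = True
                break
        model = m_step(stats, cfg, fix_A_zero=fix_A_zero)
    return FitResult(model=model, loglik=trace[-1], trace=np.asarray(trace),
                     n_iters=len(trace), converged=converged)
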