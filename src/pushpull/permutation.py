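"""Within-animal time-label permutation nulls and multiplicity adjustment.

A label-shuffled trial permutes the time labels of each animal's visits
inside the chosen age window (never across animals), moving whole visit
vectors so contemporaneous cross-biomarker correlations are preserved while
temporal dynamics — hence any directed interaction A — are destroyed.  The
SAME K permutations are reused for every biomarker pair, so null parameter
estimates are trial-aligned across hypotheses; that alignment powers the
step-down max-|z| (empirical Holm) adjustment.

p0 is the two-sided Gaussian tail of z0 = (obs - mean(null)) / sd(null),
evaluated in log space so extreme z never underflow; p_b = min(1, J p0).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .em import FitConfig, PackedSeries, fit_pair
from .errors import (ConfigurationError, DegenerateInputError,
                     EstimationError, NumericalError)
from .state_space import PairModel

__all__ = ["VisitMatrix", "pivot_visits", "PermutationSet",
           "build_permutation_set", "NullEnsemble", "estimate_null_ensemble",
           "zscore_pvalue", "adjust_bonferroni", "adjust_holm_empirical",
           "SignificanceMatrices", "run_pair_analysis",
           "write_signed_logp", "read_signed_logp", "signed_logp_frame"]

LOG2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# Visit pivot: one matrix per animal, rows = visits, columns = biomarkers
# ---------------------------------------------------------------------------

@dataclass
class VisitMatrix:
    """Cohort pivoted to per-animal visit matrices (NaN = missing)."""

    biomarkers: list[str]
    animal_ids: list[str]
    times: list[np.ndarray]     # per animal, sorted, duplicates = repeats
    values: list[np.ndarray]    # per animal, (n_visits, N)

    def pair_packed(self, pair: tuple[str, str]) -> PackedSeries:
        i = self.biomarkers.index(pair[0])
        j = self.biomarkers.index(pair[1])
        times = np.concatenate(self.times) if self.times else np.zeros(0)
        y = (np.concatenate(self.values)[:, [i, j]]
             if self.values else np.zeros((0, 2)))
        lens = np.array([t.size for t in self.times], dtype=int)
        ends = np.cumsum(lens)
        return PackedSeries(times, y, ends - lens, ends, self.animal_ids)


def pivot_visits(table: pd.DataFrame, biomarkers: list[str] | None = None
                 ) -> VisitMatrix:
    """Reconstruct visits from (animal, age): the k-th record of a biomarker
    at one (animal, age) belongs to the k-th same-day visit."""
    if biomarkers is None:
        biomarkers = sorted(table["biomarker"].unique())
    sub = table[table["biomarker"].isin(biomarkers)].copy()
    sub["rep"] = sub.groupby(["animal_id", "age_years", "biomarker"]).cumcount()
    wide = sub.pivot_table(index=["animal_id", "age_years", "rep"],
                           columns="biomarker", values="value",
                           aggfunc="first")
    for b in biomarkers:
        if b not in wide.columns:
            wide[b] = np.nan
    wide = wide[biomarkers].reset_index().sort_values(
        ["animal_id", "age_years", "rep"], kind="mergesort")
    ids, times, values = [], [], []
    for animal, grp in wide.groupby("animal_id", sort=True):
        ids.append(str(animal))
        times.append(grp["age_years"].to_numpy(dtype=float))
        values.append(grp[biomarkers].to_numpy(dtype=float))
    return VisitMatrix(list(biomarkers), ids, times, values)


# ---------------------------------------------------------------------------
# Permutation set
# ---------------------------------------------------------------------------

@dataclass
class PermutationSet:
    """K within-animal permutations of in-window visit slots, shared across
    all biomarker pairs of a run."""

    seed: int
    K: int
    age_window: tuple[float, float]
    animal_ids: list[str]
    perms: dict = field(default_factory=dict)  # animal -> (K, n_visits) int

    @property
    def fingerprint(self) -> dict:
        return {"seed": self.seed, "K": self.K,
                "age_window": list(self.age_window)}


def build_permutation_set(visits: VisitMatrix, K: int, seed: int,
                          age_window: tuple[float, float] = (0.0, 200.0)
                          ) -> PermutationSet:
    """Draw K independent in-window visit permutations per animal."""
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    lo, hi = age_window
    if not lo < hi:
        raise ConfigurationError("empty age window")
    rng = np.random.default_rng(seed)
    pset = PermutationSet(seed=seed, K=K, age_window=(float(lo), float(hi)),
                          animal_ids=list(visits.animal_ids))
    any_inwindow = False
    for animal, t in zip(visits.animal_ids, visits.times):
        n = t.size
        inwin = np.flatnonzero((t >= lo) & (t <= hi))
        any_inwindow = any_inwindow or inwin.size > 0
        perm = np.tile(np.arange(n), (K, 1))
        for k in range(K):
            perm[k, inwin] = inwin[rng.permutation(inwin.size)]
        pset.perms[animal] = perm
    if not any_inwindow:
        raise ConfigurationError("no visits fall inside the age window")
    return pset


def apply_permutation(packed: PackedSeries, pset: PermutationSet,
                      k: int) -> PackedSeries:
    """Trial-k shuffled copy: observation vectors permuted within animals."""
    gperm = np.arange(packed.n_obs)
    for animal, s, e in zip(packed.animal_ids, packed.starts, packed.ends):
        perm = pset.perms[animal][k]
        gperm[s:e] = s + perm
    out = PackedSeries.__new__(PackedSeries)
    out.times = packed.times
    out.y = np.ascontiguousarray(packed.y[gperm])
    out.starts = packed.starts
    out.ends = packed.ends
    out.animal_ids = packed.animal_ids
    out.gap_idx = packed.gap_idx
    return out


# ---------------------------------------------------------------------------
# Null ensembles and p-values
# ---------------------------------------------------------------------------

@dataclass
class NullEnsemble:
    """Observed 12-vector plus trial-aligned null 12-vectors for one pair."""

    pair: tuple[str, str]
    observed: np.ndarray          # (12,)
    nulls: np.ndarray             # (K, 12), NaN rows = failed trials
    ok: np.ndarray                # (K,) bool
    param_names: list[str] = field(
        default_factory=PairModel.parameter_names)

    @property
    def effective_K(self) -> int:
        return int(self.ok.sum())


def estimate_null_ensemble(packed: PackedSeries, pset: PermutationSet,
                           cfg: FitConfig | None = None,
                           observed: np.ndarray | None = None,
                           pair: tuple[str, str] = ("v", "w"),
                           max_failure_frac: float = 0.10) -> NullEnsemble:
    """Refit the pair model on each of the K label-shuffled data sets."""
    cfg = cfg or FitConfig()
    if observed is None:
        observed = fit_pair(packed, cfg).model.parameter_vector()
    K = pset.K
    nulls = np.full((K, 12), np.nan)
    ok = np.zeros(K, dtype=bool)
    for k in range(K):
        shuffled = apply_permutation(packed, pset, k)
        try:
            res = fit_pair(shuffled, cfg)
        except (NumericalError, EstimationError, DegenerateInputError):
            continue
        nulls[k] = res.model.parameter_vector()
        ok[k] = True
    if ok.sum() < (1.0 - max_failure_frac) * K:
        raise EstimationError(
            f"{K - int(ok.sum())} of {K} null fits failed for pair {pair}")
    return NullEnsemble(pair=pair, observed=np.asarray(observed, dtype=float),
                        nulls=nulls, ok=ok)


def zscore_pvalue(observed: float, nulls) -> tuple[float, float, float]:
    """Gaussian z against the null ensemble; two-sided p in log space.

    Returns (z0, p0, log_p0) with log p0 = log 2 + log Phi(-|z0|)
    = log erfc(|z0| / sqrt 2).
    """
    nulls = np.asarray(nulls, dtype=float)
    nulls = nulls[np.isfinite(nulls)]
    if nulls.size < 8:
        raise DegenerateInputError("need >= 8 null estimates")
    sd = nulls.std(ddof=1)
    if sd == 0:
        raise NumericalError("null ensemble has zero spread")
    z0 = float((observed - nulls.mean()) / sd)
    log_p0 = float(min(0.0, LOG2 + log_ndtr(-abs(z0))))
    return z0, float(np.exp(log_p0)), log_p0


def adjust_bonferroni(p0: float, J: int) -> float:
    """Standard Bonferroni: p_b = min(1, J * p0)."""
    if J < 1:
        raise ConfigurationError("J must be >= 1")
    return float(min(1.0, J * p0))


def log_bonferroni(log_p0: float, J: int) -> float:
    return float(min(0.0, np.log(J) + log_p0))


def adjust_holm_empirical(z_obs, z_null) -> np.ndarray:
    """Step-down max-|z| adjustment over trial-aligned null z-scores.

    Hypotheses are ranked by decreasing |z_obs|; the rank-i raw step value is
    the smoothed fraction of trials whose maximum null |z| over hypotheses of
    rank >= i reaches |z_obs| at rank i; values are made monotone
    non-decreasing down the ranking.  Dependence between hypotheses is
    respected automatically because trial k uses the same permutation
    everywhere.
    """
    z_obs = np.asarray(z_obs, dtype=float)
    z_null = np.asarray(z_null, dtype=float)
    H = z_obs.size
    if z_null.shape[0] != H:
        raise ConfigurationError("null z matrix misaligned with hypotheses")
    K = z_null.shape[1]
    order = np.argsort(-np.abs(z_obs), kind="mergesort")
    a_null = np.abs(z_null[order])          # (H, K)
    # suffix maxima over ranks
    suffix = np.maximum.accumulate(a_null[::-1], axis=0)[::-1]
    thresh = np.abs(z_obs[order])[:, None]
    raw = (1.0 + (suffix >= thresh).sum(axis=1)) / (K + 1.0)
    adj = np.maximum.accumulate(raw)
    out = np.empty(H)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Whole-panel significance run
# ---------------------------------------------------------------------------

@dataclass
class SignificanceMatrices:
    """Per-pair significance for directed (A) and drive-covariance (Q) terms.

    A-type frames are ordered (rows = target, columns = source); Q-type
    frames are symmetric.  Entries on the diagonal are NaN.
    """

    biomarkers: list[str]
    A_est: pd.DataFrame
    A_sign: pd.DataFrame
    A_z: pd.DataFrame
    A_logp0: pd.DataFrame
    A_logpb: pd.DataFrame
    A_ph: pd.DataFrame
    Q_est: pd.DataFrame
    Q_sign: pd.DataFrame
    Q_z: pd.DataFrame
    Q_logp0: pd.DataFrame
    Q_logpb: pd.DataFrame
    Q_ph: pd.DataFrame
    fingerprint: dict
    effective_K: dict


def _nan_frame(names):
    return pd.DataFrame(np.full((len(names), len(names)), np.nan),
                        index=names, columns=names)


def run_pair_analysis(table: pd.DataFrame, biomarkers: list[str] | None = None,
                      K: int = 256, seed: int = 0,
                      age_window: tuple[float, float] = (0.0, 200.0),
                      cfg: FitConfig | None = None,
                      pairs: list[tuple[str, str]] | None = None
                      ) -> SignificanceMatrices:
    """Fit every biomarker pair, estimate the shared-permutation null, and
    assemble signed significance matrices.

    J for the Bonferroni correction is N(N-1) for directed terms and
    N(N-1)/2 for covariance terms, with N the panel size — also when a
    subset of pairs is requested, so p_b matches a full-panel screen.
    """
    cfg = cfg or FitConfig()
    visits = pivot_visits(table, biomarkers)
    names = visits.biomarkers
    N = len(names)
    if N < 2:
        raise DegenerateInputError("need at least two biomarkers")
    pset = build_permutation_set(visits, K=K, seed=seed,
                                 age_window=age_window)
    if pairs is None:
        pairs = [(names[i], names[j]) for i in range(N)
                 for j in range(i + 1, N)]
    J_A = N * (N - 1)
    J_B = N * (N - 1) // 2

    frames = {k: _nan_frame(names) for k in
              ("A_est", "A_sign", "A_z", "A_logp0", "A_logpb", "A_ph",
               "Q_est", "Q_sign", "Q_z", "Q_logp0", "Q_logpb", "Q_ph")}
    eff = {}
    # hypothesis registers for the empirical Holm step
    A_entries, A_zobs, A_znull = [], [], []
    Q_entries, Q_zobs, Q_znull = [], [], []
    common_ok = np.ones(K, dtype=bool)
    ensembles = []
    for (v, w) in pairs:
        packed = visits.pair_packed((v, w))
        obs_fit = fit_pair(packed, cfg)
        ens = estimate_null_ensemble(packed, pset, cfg,
                                     observed=obs_fit.model.parameter_vector(),
                                     pair=(v, w))
        ensembles.append(((v, w), ens))
        eff[f"{v},{w}"] = ens.effective_K
        common_ok &= ens.ok
    if common_ok.sum() < 8:
        raise EstimationError("fewer than 8 trials succeeded for all pairs")
    idx = {"A12": 3, "A21": 4, "Q12": 7}
    for (v, w), ens in ensembles:
        nulls = ens.nulls[ens.ok]
        for name, (tgt, src) in (("A12", (v, w)), ("A21", (w, v))):
            p = idx[name]
            est = ens.observed[p]
            z0, _, logp0 = zscore_pvalue(est, nulls[:, p])
            frames["A_est"].loc[tgt, src] = est
            frames["A_sign"].loc[tgt, src] = np.sign(est)
            frames["A_z"].loc[tgt, src] = z0
            frames["A_logp0"].loc[tgt, src] = logp0
            frames["A_logpb"].loc[tgt, src] = log_bonferroni(logp0, J_A)
            mu = ens.nulls[common_ok, p].mean()
            sd = ens.nulls[common_ok, p].std(ddof=1)
            A_entries.append((tgt, src))
            A_zobs.append(z0)
            A_znull.append((ens.nulls[common_ok, p] - mu) / sd)
        p = idx["Q12"]
        est = ens.observed[p]
        z0, _, logp0 = zscore_pvalue(est, nulls[:, p])
        for (r, c) in ((v, w), (w, v)):
            frames["Q_est"].loc[r, c] = est
            frames["Q_sign"].loc[r, c] = np.sign(est)
            frames["Q_z"].loc[r, c] = z0
            frames["Q_logp0"].loc[r, c] = logp0
            frames["Q_logpb"].loc[r, c] = log_bonferroni(logp0, J_B)
        mu = ens.nulls[common_ok, p].mean()
        sd = ens.nulls[common_ok, p].std(ddof=1)
        Q_entries.append((v, w))
        Q_zobs.append(z0)
        Q_znull.append((ens.nulls[common_ok, p] - mu) / sd)

    if A_entries:
        ph = adjust_holm_empirical(np.array(A_zobs), np.array(A_znull))
        for (tgt, src), val in zip(A_entries, ph):
            frames["A_ph"].loc[tgt, src] = val
    if Q_entries:
        ph = adjust_holm_empirical(np.array(Q_zobs), np.array(Q_znull))
        for (v, w), val in zip(Q_entries, ph):
            frames["Q_ph"].loc[v, w] = val
            frames["Q_ph"].loc[w, v] = val

    return SignificanceMatrices(
        biomarkers=names, fingerprint=pset.fingerprint, effective_K=eff,
        **frames)


# ---------------------------------------------------------------------------
# Signed-log-p export (natural log; biomarker names as first row/column)
# ---------------------------------------------------------------------------

def signed_logp_frame(sign: pd.DataFrame, logp: pd.DataFrame) -> pd.DataFrame:
    """Entries sign(estimate) * log(p) (natural log, so magnitude grows with
    significance and the sign carries the direction of the estimate)."""
    return sign * logp


def write_signed_logp(frame: pd.DataFrame, path, fingerprint: dict | None
                      = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if fingerprint is not None:
            fh.write(f"# log_base=e seed={fingerprint['seed']} "
                     f"K={fingerprint['K']} "
                     f"age_window={fingerprint['age_window'][0]}:"
                     f"{fingerprint['age_window'][1]}\n")
        frame.to_csv(fh)


def read_signed_logp(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)
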