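"""Between-group differences in fitted pair parameters.

Observations are split into two non-overlapping groups by sex filter and
half-open age window [lo, hi) (an animal may contribute observations to
both groups at different ages).  Each group is fitted independently; the
difference of estimates is compared with trial-aligned null differences:
trial k pairs the k-th label-shuffled refit in group 1 with the k-th in
group 2, which is a proper null for the difference under within-group
exchangeability.  Positive differences mean "more positive in the first
group".
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .em import FitConfig, fit_pair
from .errors import ConfigurationError, DegenerateInputError
from .permutation import (adjust_bonferroni, adjust_holm_empirical,
                          build_permutation_set, estimate_null_ensemble,
                          pivot_visits, zscore_pvalue)
from .state_space import PairModel

__all__ = ["GroupSpec", "ContrastResult", "split_cohort",
           "contrast_parameters", "contrast_tables"]


@dataclass
class GroupSpec:
    """A cohort subset: sex filter plus half-open age window [lo, hi)."""

    name: str
    age_window: tuple[float, float]
    sexes: frozenset[str] | None = None   # None = any sex

    def __post_init__(self):
        lo, hi = self.age_window
        if not lo < hi:
            raise ConfigurationError(f"group {self.name}: window lo < hi "
                                     "required")

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        age = table["age_years"].to_numpy(dtype=float)
        m = (age >= self.age_window[0]) & (age < self.age_window[1])
        if self.sexes is not None:
            m &= table["sex"].isin(self.sexes).to_numpy()
        return m


def split_cohort(table: pd.DataFrame, g1: GroupSpec, g2: GroupSpec
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each observation to at most one group by its age window."""
    lo1, hi1 = g1.age_window
    lo2, hi2 = g2.age_window
    if max(lo1, lo2) < min(hi1, hi2):
        raise ConfigurationError(
            f"age windows of {g1.name} and {g2.name} overlap")
    t1 = table.loc[g1.mask(table)].reset_index(drop=True)
    t2 = table.loc[g2.mask(table)].reset_index(drop=True)
    for t, g in ((t1, g1), (t2, g2)):
        if len(t) == 0:
            raise DegenerateInputError(f"group {g.name} is empty")
    return t1, t2


@dataclass
class ContrastResult:
    """Per-parameter group difference with permutation significance."""

    pair: tuple[str, str]
    group_names: tuple[str, str]
    param_names: list[str] = field(default_factory=PairModel.parameter_names)
    estimates_g1: np.ndarray = None     # (12,)
    estimates_g2: np.ndarray = None
    delta: np.ndarray = None            # estimates_g1 - estimates_g2
    z: np.ndarray = None
    p0: np.ndarray = None
    p_b: np.ndarray = None
    p_h: np.ndarray = None
    effective_K: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.param_names,
            "estimate_g1": self.estimates_g1,
            "estimate_g2": self.estimates_g2,
            "delta": self.delta, "z": self.z,
            "p0": self.p0, "p_b": self.p_b, "p_h": self.p_h})


def contrast_parameters(table: pd.DataFrame, pair: tuple[str, str],
                        g1: GroupSpec, g2: GroupSpec, K: int = 64,
                        seed: int = 0, cfg: FitConfig | None = None,
                        J: int | None = None) -> ContrastResult:
    """Fit one pair in both groups and test every parameter difference.

    ``J`` is the Bonferroni multiplicity (defaults to the 12 parameters of
    this single pair; pass the panel-wide count for a full screen).
    """
    t1, t2 = split_cohort(table, g1, g2)
    return contrast_tables(t1, t2, pair, g1, g2, K=K, seed=seed, cfg=cfg, J=J)


def contrast_tables(t1: pd.DataFrame, t2: pd.DataFrame,
                    pair: tuple[str, str], g1: GroupSpec, g2: GroupSpec,
                    K: int = 64, seed: int = 0,
                    cfg: FitConfig | None = None,
                    J: int | None = None) -> ContrastResult:
    """Contrast two pre-split observation tables (see contrast_parameters).

    Each group's permutation stream is keyed by (seed, group name) so it
    travels with the group: swapping the two arguments flips the sign of
    every delta and leaves every p-value unchanged, exactly.
    """
    cfg = cfg or FitConfig()
    ensembles = []
    observed = []
    for t, g in ((t1, g1), (t2, g2)):
        gseed = int(np.random.default_rng(
            [seed, zlib.crc32(g.name.encode("utf-8"))]).integers(2 ** 31))
        visits = pivot_visits(t, list(pair))
        pset = build_permutation_set(visits, K=K, seed=gseed,
                                     age_window=g.age_window)
        packed = visits.pair_packed(pair)
        fit = fit_pair(packed, cfg)
        observed.append(fit.model.parameter_vector())
        ensembles.append(estimate_null_ensemble(
            packed, pset, cfg, observed=observed[-1], pair=pair))
    e1, e2 = observed
    delta = e1 - e2
    ok = ensembles[0].ok & ensembles[1].ok
    if ok.sum() < 8:
        raise DegenerateInputError("fewer than 8 aligned null trials")
    null_delta = ensembles[0].nulls[ok] - ensembles[1].nulls[ok]   # (K', 12)
    P = delta.size
    z = np.empty(P)
    p0 = np.empty(P)
    z_null = np.empty((P, int(ok.sum())))
    for p in range(P):
        nd = null_delta[:, p]
        sd = nd.std(ddof=1)
        if sd == 0.0:
            # both groups identical (self-contrast): no evidence either way
            if abs(delta[p] - nd[0]) > 1e-12:
                raise DegenerateInputError(
                    "null delta ensemble has zero spread away from the "
                    f"observed delta for parameter {p}")
            z[p], p0[p] = 0.0, 1.0
            z_null[p] = 0.0
            continue
        z[p], p0[p], _ = zscore_pvalue(delta[p], nd)
        z_null[p] = (nd - nd.mean()) / sd
    Jm = J if J is not None else P
    p_b = np.array([adjust_bonferroni(x, Jm) for x in p0])
    p_h = adjust_holm_empirical(z, z_null)
    return ContrastResult(pair=pair, group_names=(g1.name, g2.name),
                          estimates_g1=e1, estimates_g2=e2, delta=delta,
                          z=z, p0=p0, p_b=p_b, p_h=p_h,
                          effective_K=int(ok.sum()))
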