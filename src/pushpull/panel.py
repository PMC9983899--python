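"""Cohort ingestion, exclusion rules, log-transform, detrending, normalization.

The raw input is a long-format table with one record per
(animal, visit, biomarker): columns ``animal_id, sex, age_years, biomarker,
value, lab_code``.  Preprocessing applies configured threshold exclusions,
drops redundant biomarkers, log-transforms a biomarker (with the assay's
smallest discrete increment as pseudocount) whenever that reduces the
absolute skewness, removes each animal's linear age drift (fit from age 5,
percentile-trimmed), and standardizes every (animal, biomarker) series to
mean 0, variance 1.

Increment diagnostics summarize how the variance of adjacent-observation
increments grows with the time gap: linear growth is the signature of a
Brownian stochastic drive, and a nonzero intercept at dt = 0 is the
signature of observation noise (two independent draws differ with variance
2R).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError

logger = logging.getLogger("pushpull")

__all__ = [
    "DOLPHIN_PANEL", "PanelConfig", "ExclusionRule",
    "read_cohort", "write_cohort", "apply_exclusions",
    "smallest_increment", "choose_log_transform", "transform_table",
    "fit_age_drift", "compute_drift", "detrend_normalize",
    "increment_diagnostics", "preprocess_cohort", "PreprocessResult",
    "IncrementDiagnostics",
]

# The 44-measure hematology/serum-chemistry panel (absolute differential
# counts carry the 'AC' prefix); GFR is dropped by default as functionally
# redundant with Creatinine.
DOLPHIN_PANEL: tuple[str, ...] = (
    "RBC", "HGB", "HCT", "MCV", "MCH", "MCHC", "RDW", "NRBC",
    "Platelets", "MPV", "WBC",
    "EOS", "Lymphs", "Monocytes", "SEGS",
    "ACEosinophils", "ACLymphocytes", "ACMonocytes", "ACNeutrophils",
    "Glucose", "BUN", "Creatinine", "UricAcid",
    "Sodium", "Potassium", "Chloride", "CO2",
    "Protein", "Albumin", "Calcium", "InorgPhos",
    "AlkPhos", "LDH", "AST", "ALT", "GGT", "Bilirubin",
    "Cholesterol", "Triglyceride", "Iron", "CPK", "SED60", "Mg", "GFR",
)

COLUMNS = ["animal_id", "sex", "age_years", "biomarker", "value", "lab_code"]


@dataclass
class ExclusionRule:
    biomarker: str
    bound: float
    direction: str  # "below": remove value < bound; "above": remove value > bound

    def __post_init__(self):
        if self.direction not in ("below", "above"):
            raise ConfigurationError(
                f"direction must be 'below' or 'above', got {self.direction!r}")


@dataclass
class PanelConfig:
    """Panel membership, threshold exclusions, drops, transform overrides."""

    biomarkers: tuple[str, ...] = DOLPHIN_PANEL
    exclusion_rules: tuple[ExclusionRule, ...] = (
        ExclusionRule("Albumin", 2.0, "below"),
        ExclusionRule("RDW", 40.0, "above"),
    )
    drop_list: frozenset[str] = frozenset({"GFR"})
    log_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        panel = set(self.biomarkers)
        for rule in self.exclusion_rules:
            if rule.biomarker not in panel:
                raise ConfigurationError(
                    f"exclusion rule names unknown biomarker {rule.biomarker!r}")
        for b in self.drop_list:
            if b not in panel:
                raise ConfigurationError(
                    f"drop list names unknown biomarker {b!r}")

    @property
    def analyzed_biomarkers(self) -> tuple[str, ...]:
        """Panel members retained for analysis (drop list removed)."""
        return tuple(b for b in self.biomarkers if b not in self.drop_list)


def read_cohort(path) -> pd.DataFrame:
    """Read a long-format cohort CSV (header as in COLUMNS)."""
    df = pd.read_csv(path, dtype={"animal_id": str, "sex": str,
                                  "biomarker": str, "lab_code": str})
    missing = [c for c in COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cohort table missing columns: {missing}")
    if "lab_code" not in df.columns:
        df["lab_code"] = ""
    df["lab_code"] = df["lab_code"].fillna("")
    ages = df["age_years"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ages)) or np.any(ages < 0):
        raise ConfigurationError("ages must be finite and non-negative")
    return df[COLUMNS]


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def apply_exclusions(table: pd.DataFrame, cfg: PanelConfig
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply threshold exclusion rules and remove dropped biomarkers.

    Returns the filtered table and the number of records removed per rule
    (keys ``"<biomarker> <direction> <bound>"`` and ``"drop <biomarker>"``).
    """
    removals: dict[str, int] = {}
    keep = np.ones(len(table), dtype=bool)
    values = table["value"].to_numpy(dtype=float)
    names = table["biomarker"].to_numpy()
    for rule in cfg.exclusion_rules:
        sel = names == rule.biomarker
        if rule.direction == "below":
            bad = sel & (values < rule.bound)
        else:
            bad = sel & (values > rule.bound)
        removals[f"{rule.biomarker} {rule.direction} {rule.bound}"] = int(
            bad.sum())
        keep &= ~bad
    for b in sorted(cfg.drop_list):
        bad = names == b
        removals[f"drop {b}"] = int(bad.sum())
        keep &= ~bad
    return table.loc[keep].reset_index(drop=True), removals


def smallest_increment(values) -> float:
    """Smallest positive gap between distinct sorted values (assay resolution)."""
    vals = np.unique(np.asarray(values, dtype=float))
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise DegenerateInputError("need >= 2 distinct finite values")
    return float(np.min(np.diff(vals)))


def _skewness(values: np.ndarray) -> float:
    """Adjusted Fisher-Pearson sample skewness; 0 for zero-variance input."""
    if np.var(values) == 0:
        return 0.0
    return float(stats.skew(values, bias=False))


def choose_log_transform(values, delta: float):
    """Decide whether log(value + delta) reduces absolute skewness.

    Returns (log_applied, skew_raw, skew_log); skew_log is NaN when the
    log is inapplicable (some value + delta <= 0).  Ties keep the raw scale.
    """
    values = np.asarray(values, dtype=float)
    if delta <= 0:
        raise DegenerateInputError("pseudocount delta must be positive")
    skew_raw = _skewness(values)
    if np.min(values) + delta <= 0:
        return False, skew_raw, float("nan")
    if np.var(values) == 0:
        return False, 0.0, 0.0
    skew_log = _skewness(np.log(values + delta))
    return bool(abs(skew_log) < abs(skew_raw)), skew_raw, skew_log


def transform_table(table: pd.DataFrame, cfg: PanelConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply per-biomarker log decisions cohort-wide; return table + report."""
    out = table.copy()
    rows = []
    for b, grp in table.groupby("biomarker", sort=True):
        vals = grp["value"].to_numpy(dtype=float)
        try:
            delta = smallest_increment(vals)
        except DegenerateInputError:
            rows.append((b, False, np.nan, _skewness(vals), np.nan))
            continue
        applied, skew_raw, skew_log = choose_log_transform(vals, delta)
        if b in cfg.log_overrides:
            forced = bool(cfg.log_overrides[b])
            applied = forced and np.min(vals) + delta > 0
        if applied:
            out.loc[grp.index, "value"] = np.log(vals + delta)
        rows.append((b, applied, delta, skew_raw, skew_log))
    report = pd.DataFrame(rows, columns=["biomarker", "log_applied", "delta",
                                         "skew_raw", "skew_log"])
    return out, report


def fit_age_drift(ages, values, pooled: tuple[float, float] | None = None,
                  min_age: float = 5.0):
    """Per-series OLS age drift with percentile trimming.

    Only points with age >= ``min_age`` and value inside the series'
    [1st, 99th] percentile band enter the fit; with fewer than 3 eligible
    points the cohort-pooled (slope, intercept-recentred) line is used.

    Returns (slope, intercept, n_points_used, fallback_used).
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = ages >= min_age
    if sel.any():
        lo, hi = np.percentile(values[sel], [1.0, 99.0])
        sel &= (values >= lo) & (values <= hi)
    n = int(sel.sum())
    if n >= 3 and np.var(ages[sel]) > 0:
        if np.ptp(values[sel]) == 0.0:
            # constant response: exactly flat, avoid polyfit float noise
            return 0.0, float(values[sel][0]), n, False
        slope, intercept = np.polyfit(ages[sel], values[sel], 1)
        return float(slope), float(intercept), n, False
    slope = pooled[0] if pooled is not None else 0.0
    # recentre the pooled slope through this animal's own points
    base = sel if sel.any() else np.ones_like(ages, dtype=bool)
    intercept = float(np.mean(values[base]) - slope * np.mean(ages[base]))
    return float(slope), intercept, n, True


def _pooled_slopes(table: pd.DataFrame, min_age: float = 5.0) -> dict[str, float]:
    pooled = {}
    for b, grp in table.groupby("biomarker", sort=True):
        sel = grp["age_years"].to_numpy(dtype=float) >= min_age
        a = grp["age_years"].to_numpy(dtype=float)[sel]
        v = grp["value"].to_numpy(dtype=float)[sel]
        if a.size >= 3 and np.var(a) > 0:
            pooled[b] = float(np.polyfit(a, v, 1)[0])
        else:
            pooled[b] = 0.0
    return pooled


def compute_drift(table: pd.DataFrame, min_age: float = 5.0) -> pd.DataFrame:
    """Drift records for every (animal, biomarker) series in the table."""
    pooled = _pooled_slopes(table, min_age)
    rows = []
    for (animal, b), grp in table.groupby(["animal_id", "biomarker"],
                                          sort=True):
        grp = grp.sort_values("age_years", kind="mergesort")
        slope, intercept, n, fb = fit_age_drift(
            grp["age_years"], grp["value"], pooled=(pooled[b], 0.0),
            min_age=min_age)
        rows.append((animal, b, slope, intercept, n, fb))
    return pd.DataFrame(rows, columns=["animal_id", "biomarker", "slope",
                                       "intercept", "n_points_used",
                                       "fallback_used"])


def detrend_normalize(table: pd.DataFrame, drift: pd.DataFrame
                      ) -> pd.DataFrame:
    """Remove each series' age drift and standardize to mean 0, variance 1.

    Series with zero residual variance are dropped with a logged warning.
    Uses the unbiased (n-1) variance; single-point series are dropped.
    """
    d = drift.set_index(["animal_id", "biomarker"])
    pieces = []
    for (animal, b), grp in table.groupby(["animal_id", "biomarker"],
                                          sort=True):
        try:
            rec = d.loc[(animal, b)]
        except KeyError:
            raise ConfigurationError(
                f"no drift record for ({animal}, {b})") from None
        ages = grp["age_years"].to_numpy(dtype=float)
        vals = grp["value"].to_numpy(dtype=float)
        resid = vals - (rec["intercept"] + rec["slope"] * ages)
        # tolerance relative to the data scale: an exactly-constant series
        # detrended by a float-noise slope must still count as zero-variance
        tol = 1e-12 * max(1.0, float(np.max(np.abs(vals), initial=0.0)))
        if resid.size < 2 or resid.std(ddof=1) <= tol:
            logger.warning("dropping zero-variance series (%s, %s), n=%d",
                           animal, b, resid.size)
            continue
        resid = resid - resid.mean()
        resid = resid / resid.std(ddof=1)
        out = grp.copy()
        out["value"] = resid
        pieces.append(out)
    if not pieces:
        return table.iloc[0:0].copy()
    return pd.concat(pieces).sort_index().reset_index(drop=True)


@dataclass
class IncrementDiagnostics:
    """Variance-vs-dt structure of adjacent-observation increments."""

    biomarker: str
    bin_edges: np.ndarray       # (13,) on sqrt(dt)
    bin_mean: np.ndarray        # (12,) mean increment per bin
    bin_sd: np.ndarray          # (12,)
    bin_count: np.ndarray       # (12,)
    bin_mean_dt: np.ndarray     # (12,)
    histogram: np.ndarray       # (12, 18), scaled to max 1 per nonempty bin
    hist_edges: np.ndarray      # (19,) on the increment axis
    slope_vs_dt: float          # drive-variance estimate (units^2 / year)
    intercept_at_dt0: float     # noise-variance estimate (= 2R for pure noise)
    n_increments: int
    dt0_count: int
    dt0_variance: float


def _adjacent_increments(table: pd.DataFrame, biomarker: str):
    sub = table[table["biomarker"] == biomarker]
    dts, dys = [], []
    for _, grp in sub.groupby("animal_id", sort=True):
        grp = grp.sort_values("age_years", kind="mergesort")
        a = grp["age_years"].to_numpy(dtype=float)
        v = grp["value"].to_numpy(dtype=float)
        if a.size >= 2:
            dts.append(np.diff(a))
            dys.append(np.diff(v))
    if not dts:
        return np.zeros(0), np.zeros(0)
    return np.concatenate(dts), np.concatenate(dys)


def increment_diagnostics(table: pd.DataFrame, biomarker: str,
                          n_bins: int = 12, n_boxes: int = 18
                          ) -> IncrementDiagnostics:
    """Bin adjacent increments by sqrt(dt) and regress variance on dt.

    Equal-count bins on sqrt(dt) (dt = 0 repeats fall in bin 1); the OLS of
    per-bin increment variance on per-bin mean dt estimates the drive
    variance (slope) and twice the observation-noise variance (intercept).
    """
    dt, dy = _adjacent_increments(table, biomarker)
    if dt.size < n_bins + 1:
        raise DegenerateInputError(
            f"need >= {n_bins + 1} increments, have {dt.size}")
    s = np.sqrt(dt)
    edges = np.quantile(s, np.linspace(0.0, 1.0, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    bin_mean = np.full(n_bins, np.nan)
    bin_sd = np.full(n_bins, np.nan)
    bin_count = np.zeros(n_bins, dtype=int)
    bin_mean_dt = np.full(n_bins, np.nan)
    lo, hi = dy.min(), dy.max()
    if hi == lo:
        hi = lo + 1.0
    hist_edges = np.linspace(lo, hi, n_boxes + 1)
    hist = np.zeros((n_bins, n_boxes))
    for k in range(n_bins):
        m = idx == k
        bin_count[k] = int(m.sum())
        if bin_count[k]:
            bin_mean[k] = dy[m].mean()
            bin_sd[k] = dy[m].std(ddof=1) if bin_count[k] > 1 else 0.0
            bin_mean_dt[k] = dt[m].mean()
            h, _ = np.histogram(dy[m], bins=hist_edges)
            if h.max() > 0:
                hist[k] = h / h.max()
    ok = (bin_count > 1) & np.isfinite(bin_sd)
    slope, intercept = np.polyfit(bin_mean_dt[ok], bin_sd[ok] ** 2, 1)
    z = dt == 0
    return IncrementDiagnostics(
        biomarker=biomarker, bin_edges=edges, bin_mean=bin_mean,
        bin_sd=bin_sd, bin_count=bin_count, bin_mean_dt=bin_mean_dt,
        histogram=hist, hist_edges=hist_edges, slope_vs_dt=float(slope),
        intercept_at_dt0=float(intercept), n_increments=int(dt.size),
        dt0_count=int(z.sum()),
        dt0_variance=float(dy[z].var(ddof=1)) if z.sum() > 1 else float("nan"))


@dataclass
class PreprocessResult:
    normalized: pd.DataFrame
    transform_report: pd.DataFrame
    drift_records: pd.DataFrame
    removals: dict[str, int]


def preprocess_cohort(table: pd.DataFrame, cfg: PanelConfig | None = None
                      ) -> PreprocessResult:
    """Full preprocessing chain: exclusions, log, drift removal, normalization."""
    cfg = cfg or PanelConfig()
    filtered, removals = apply_exclusions(table, cfg)
    transformed, report = transform_table(filtered, cfg)
    drift = compute_drift(transformed)
    normalized = detrend_normalize(transformed, drift)
    return PreprocessResult(normalized, report, drift, removals)
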