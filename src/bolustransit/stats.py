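"""Derived study quantities and inferential statistics.

Percent changes from baseline, the lung diffusion constant (K_CO, diffusing
capacity per litre of alveolar volume), mean +/- SEM summaries, blood-gas
panel bookkeeping, one-way repeated-measures ANOVA with subject as block, and
the Holm-Sidak step-down multiple-comparison adjustment for post hoc paired
tests.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "StatsError",
    "BloodGasPanel",
    "SpirometryPanel",
    "PairwiseComparison",
    "RmAnovaResult",
    "percent_change",
    "percent_change_rounded",
    "apply_percent_change",
    "diffusion_constant",
    "mean_sem",
    "holm_sidak",
    "rm_anova",
    "summarize_panels",
]


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass(frozen=True)
class BloodGasPanel:
    """One arterial blood-gas draw for one subject and condition."""

    condition: str
    fo2hb: float                 # % oxygenated hemoglobin
    hemoglobin: float            # mmol/L
    hematocrit: float            # %
    met_hemoglobin: float        # %
    ph: float
    pco2: float                  # kPa
    po2: float                   # kPa
    lactate: float               # mmol/L
    bicarbonate: float           # mmol/L
    base_excess: float           # mmol/L

    def __post_init__(self) -> None:
        if not 0.0 <= self.fo2hb <= 100.0:
            raise StatsError(f"FO2Hb must be in [0, 100] %, got {self.fo2hb}")
        if not 6.5 < self.ph < 8.0:
            raise StatsError(f"pH {self.ph} outside the physiological range (6.5, 8.0)")


@dataclass(frozen=True)
class SpirometryPanel:
    """Body-box spirometry summary for one group or subject.

    ``kco`` may be supplied as printed; it is checked against
    ``dlco / alveolar_volume`` and a mismatch beyond 5% warns.
    """

    dlco: float                  # mmol/(min*kPa)
    alveolar_volume: float       # L
    kco: float | None = None     # mmol/(min*kPa*L)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dlco <= 0 or self.alveolar_volume <= 0:
            raise StatsError("dlco and alveolar_volume must be positive")
        if self.kco is not None:
            implied = self.dlco / self.alveolar_volume
            if abs(self.kco - implied) > 0.05 * max(self.kco, implied):
                warnings.warn(
                    f"stated K_CO {self.kco:.3g} inconsistent with "
                    f"D_LCO/V_A = {implied:.3g}", RuntimeWarning, stacklevel=2)


def percent_change(baseline: float, value: float) -> float:
    """Signed percent change ``100 * (value - baseline) / baseline``."""
    if baseline == 0:
        raise StatsError("percent change undefined for zero baseline")
    return 100.0 * (value - baseline) / baseline


def percent_change_rounded(baseline: float, value: float, ndigits: int = 0) -> float:
    """Percent change rounded half-away-from-zero, as printed summaries round."""
    pc = percent_change(baseline, value)
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(pc) * scale + 0.5) / scale, pc)


def apply_percent_change(baseline: float, pct: float) -> float:
    """Invert :func:`percent_change`: the value a signed change leads to."""
    return baseline * (1.0 + pct / 100.0)


def diffusion_constant(dlco: float, alveolar_volume: float) -> float:
    """K_CO: diffusing capacity per litre of alveolar volume."""
    if alveolar_volume <= 0:
        raise StatsError("alveolar volume must be positive")
    return dlco / alveolar_volume


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sd with n-1 denominator / sqrt(n))."""
    v = np.asarray(values, float)
    if v.ndim != 1 or len(v) < 2:
        raise StatsError("SEM requires at least two values")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    Sorted ascending, the k-th smallest of m raw p-values is adjusted to
    ``1 - (1 - p_(k))^(m - k + 1)``, with monotonicity enforced by a running
    maximum and capping at 1.
    """
    p = np.asarray(p_values, float)
    if p.ndim != 1 or p.size == 0:
        raise StatsError("need a 1-D, non-empty vector of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass(frozen=True)
class PairwiseComparison:
    """One post hoc paired comparison between two conditions."""

    a: str
    b: str
    mean_diff: float
    t: float
    p_raw: float
    p_adjusted: float


@dataclass
class RmAnovaResult:
    """One-way repeated-measures ANOVA with subject as block."""

    F: float
    df_between: float
    df_error: float
    p: float
    ss_between: float
    ss_error: float
    ss_subjects: float
    n_subjects: int
    n_conditions: int
    epsilon: float | None = None           # Greenhouse-Geisser, when applied
    comparisons: list[PairwiseComparison] = field(default_factory=list)


def _gg_epsilon(X: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the condition covariance."""
    S = np.cov(X, rowvar=False, ddof=1)
    k = S.shape[0]
    A = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    num = np.trace(A) ** 2
    den = (k - 1) * np.sum(A**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova(data, conditions: list[str] | None = None, *, posthoc: bool = True,
             gg_correction: bool = False) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Rows with missing values are dropped (listwise deletion, logged).  F is
    MS_condition / MS_error after removing the subject block effect; post hoc
    paired t-tests over all condition pairs are Holm-Sidak adjusted.  No
    sphericity correction is applied unless ``gg_correction=True``
    (Greenhouse-Geisser).
    """
    if isinstance(data, pd.DataFrame):
        if conditions is None:
            conditions = [str(c) for c in data.columns]
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise StatsError("data must be a 2-D subjects x conditions table")
    n_all, k = X.shape
    if k < 2:
        raise StatsError("need at least two conditions")
    if conditions is None:
        conditions = [f"cond{i}" for i in range(k)]

    complete = ~np.isnan(X).any(axis=1)
    if complete.sum() < n_all:
        logger.warning("rm_anova: dropped %d of %d subjects with missing values",
                       n_all - int(complete.sum()), n_all)
    X = X[complete]
    n = X.shape[0]
    if n < 2:
        raise StatsError("fewer than two complete subjects")

    grand = X.mean()
    col_means = X.mean(axis=0)
    row_means = X.mean(axis=1)
    ss_between = n * float(np.sum((col_means - grand) ** 2))
    ss_subjects = k * float(np.sum((row_means - grand) ** 2))
    ss_total = float(np.sum((X - grand) ** 2))
    ss_error = max(ss_total - ss_between - ss_subjects, 0.0)
    df1, df2 = float(k - 1), float((k - 1) * (n - 1))

    epsilon = None
    if gg_correction:
        epsilon = _gg_epsilon(X)
        df1, df2 = df1 * epsilon, df2 * epsilon

    ms_between = ss_between / df1
    ms_error = ss_error / df2 if df2 > 0 else np.nan
    if ss_between <= 1e-300 * max(ss_total, 1.0):
        F, p = 0.0, 1.0
    elif ms_error == 0:
        F, p = np.inf, 0.0
    else:
        F = ms_between / ms_error
        p = float(sps.f.sf(F, df1, df2))

    comparisons: list[PairwiseComparison] = []
    if posthoc and k >= 2:
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
        raw = []
        stats_ = []
        for i, j in pairs:
            with warnings.catch_warnings():
                # identical columns trigger a scipy precision warning; the
                # resulting NaN is mapped to p = 1 below
                warnings.simplefilter("ignore", RuntimeWarning)
                tt = sps.ttest_rel(X[:, i], X[:, j])
            # zero-variance differences (identical columns) carry no evidence
            p_raw = float(tt.pvalue) if np.isfinite(tt.pvalue) else 1.0
            raw.append(p_raw)
            stats_.append((float(X[:, j].mean() - X[:, i].mean()), float(tt.statistic)))
        adj = holm_sidak(raw)
        comparisons = [
            PairwiseComparison(conditions[i], conditions[j], d, t_, pr, pa)
            for (i, j), (d, t_), pr, pa in zip(pairs, stats_, raw, adj)
        ]

    return RmAnovaResult(F=float(F), df_between=df1, df_error=df2, p=float(p),
                         ss_between=ss_between, ss_error=ss_error,
                         ss_subjects=ss_subjects, n_subjects=n, n_conditions=k,
                         epsilon=epsilon, comparisons=comparisons)


def summarize_panels(panels: list[BloodGasPanel]) -> pd.DataFrame:
    """Mean +/- SEM of each blood-gas variable by condition.

    Descriptive only: one row per condition, columns ``<field>_mean`` and
    ``<field>_sem``.
    """
    if not panels:
        raise StatsError("no panels supplied")
    df = pd.DataFrame([vars(p) for p in panels])
    num = df.columns.drop("condition")
    grouped = df.groupby("condition", sort=False)[list(num)]
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem(ddof=1).add_suffix("_sem")
    return pd.concat([mean, sem], axis=1).sort_index(axis=1)
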