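"""Nonparametric preanalytics statistics.

The battery mirrors repeated-measures condition testing on compositional
glycan data: technical replicates are averaged, each analyte is screened
with a Friedman test across conditions (donors as blocks), analytes passing
the gate (p < .05) are compared condition-by-condition against the matrix
reference with paired Wilcoxon signed-rank tests under Bonferroni-corrected
thresholds (.05/9 for serum, .05/5 for plasma), and hemolysis effects are
quantified as Pearson correlations between free hemoglobin and analyte or
score values, labeled with Evans strength classes.

The Wilcoxon Z uses the plain normal approximation without continuity
correction, Z = (T - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24) with T the smaller
signed-rank sum, which reproduces the printed -2.803 / -2.701 / -2.599
triple for n = 10 at T = 0 / 1 / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import design

__all__ = [
    "StatsError",
    "CorrelationResult",
    "average_replicates",
    "bonferroni_alpha",
    "friedman_per_analyte",
    "wilcoxon_z",
    "signed_rank_T",
    "posthoc_vs_reference",
    "run_battery",
    "normality_check",
    "evans_label",
    "hemolysis_correlation",
]


class StatsError(ValueError):
    """Invalid input to a statistical operation."""


# ---------------------------------------------------------------------------
# Replicate averaging
# ---------------------------------------------------------------------------

def average_replicates(
    profiles: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean profile per (donor, condition), renormalized to sum 1.

    *profiles*: one row per replicate preparation (index = sample id, columns
    = analytes); *meta*: same index with at least donor and condition columns.
    A (donor, condition) cell present in *meta* but matching no profile rows
    raises :class:`StatsError` naming the cell.
    """
    cells = meta[["donor", "condition"]].drop_duplicates()
    frames, rows = [], []
    for _, cell in cells.iterrows():
        sel = (meta["donor"] == cell["donor"]) & (meta["condition"] == cell["condition"])
        ids = profiles.index.intersection(meta.index[sel])
        if len(ids) == 0:
            raise StatsError(
                f"zero replicates for donor {cell['donor']} condition {cell['condition']}"
            )
        mean = profiles.loc[ids].mean(axis=0)
        mean = mean / mean.sum()
        frames.append(mean)
        m = meta.loc[meta.index[sel][0]].drop(labels=["replicate"], errors="ignore")
        rows.append(m)
    avg = pd.DataFrame(frames).reset_index(drop=True)
    avg_meta = pd.DataFrame(rows).reset_index(drop=True)
    idx = [
        f"{d}_c{int(c):02d}" for d, c in zip(avg_meta["donor"], avg_meta["condition"])
    ]
    avg.index = pd.Index(idx, name="sample")
    avg_meta.index = avg.index
    return avg, avg_meta


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def bonferroni_alpha(m: int, family_alpha: float = 0.05) -> tuple[float, float]:
    """Per-comparison threshold: exact family_alpha/m and its 4-decimal rounding."""
    if m < 1:
        raise StatsError("comparison count must be >= 1")
    exact = family_alpha / m
    return exact, round(exact, 4)


def friedman_per_analyte(data: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Friedman chi-square over a complete donors x conditions block design.

    Uses average ranks with tie correction; p from the chi-square reference
    distribution.  Missing cells or fewer than 3 conditions are errors.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise StatsError("need a 2-D matrix with at least 3 conditions")
    if not np.all(np.isfinite(arr)):
        raise StatsError("Friedman requires a complete block design (no missing cells)")
    with np.errstate(invalid="ignore"):
        stat, p = sps.friedmanchisquare(*[arr[:, j] for j in range(arr.shape[1])])
    if not np.isfinite(stat):  # all ranks tie
        return 0.0, 1.0
    return float(stat), float(p)


def wilcoxon_z(T: float, n: int) -> tuple[float, float]:
    """Normal-approximation Z and two-sided p for a signed-rank sum.

    *T* is the smaller of the positive/negative rank sums over *n* nonzero
    pairs.  No continuity correction.  n < 5 raises (approximation invalid).
    """
    if n < 5:
        raise StatsError("normal approximation invalid for n < 5")
    max_T = n * (n + 1) / 2
    if not 0 <= T <= max_T:
        raise StatsError(f"T={T} outside [0, {max_T}]")
    mu = n * (n + 1) / 4.0
    sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (T - mu) / sigma
    p = 2.0 * sps.norm.cdf(-abs(z))
    return float(z), float(p)


def signed_rank_T(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Smaller signed-rank sum and nonzero-pair count for paired samples.

    Zero differences are dropped (SPSS convention); ties in |d| get average
    ranks.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 0
    ranks = sps.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    return min(t_plus, t_minus), n


def normality_check(values: np.ndarray) -> float:
    """Shapiro-Wilk p value (reported to justify the nonparametric path).

    Degenerate constant input returns NaN; n outside [3, 5000] is an error.
    """
    v = np.asarray(values, dtype=float)
    if not 3 <= len(v) <= 5000:
        raise StatsError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        return float("nan")
    return float(sps.shapiro(v).pvalue)


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

def _condition_matrix(
    values: pd.Series, meta: pd.DataFrame, conditions: list[int]
) -> pd.DataFrame:
    """donors x conditions matrix of one analyte's averaged values."""
    df = pd.DataFrame(
        {"donor": meta["donor"], "condition": meta["condition"], "value": values}
    )
    wide = df.pivot_table(index="donor", columns="condition", values="value")
    return wide.reindex(columns=conditions)


def posthoc_vs_reference(
    values: pd.Series,
    meta: pd.DataFrame,
    reference_condition: int,
    altered_conditions: tuple[int, ...],
    threshold: float,
) -> list[dict]:
    """Paired Wilcoxon of each altered condition versus the reference.

    Pairs are matched by donor; donors missing either arm are dropped (the
    shaking-hemolysis condition exists only for the 5 second-set donors).
    Returns one row dict per altered condition with T, n, Z, p, medians/IQR
    and the significance flag against *threshold*.
    """
    wide = _condition_matrix(values, meta, [reference_condition, *altered_conditions])
    if wide[reference_condition].isna().all():
        raise StatsError(f"reference condition {reference_condition} absent")
    rows = []
    for cond in altered_conditions:
        pair = wide[[reference_condition, cond]].dropna()
        x, y = pair[cond].to_numpy(), pair[reference_condition].to_numpy()
        T, n = signed_rank_T(x, y)
        if n == 0:
            z, p = 0.0, 1.0
        elif n < 5:
            z, p = float("nan"), float("nan")
        else:
            z, p = wilcoxon_z(T, n)
        if len(x):
            q25, med, q75 = np.percentile(x, [25, 50, 75], method="linear")
        else:
            q25 = med = q75 = np.nan
        rows.append(
            dict(
                condition=cond,
                n=n,
                T=T,
                Z=z,
                p=p,
                threshold=threshold,
                significant=bool(np.isfinite(p) and p < threshold),
                median=float(med) if len(x) else np.nan,
                iqr_low=float(q25) if len(x) else np.nan,
                iqr_high=float(q75) if len(x) else np.nan,
            )
        )
    return rows


def run_battery(
    avg_profiles: pd.DataFrame,
    avg_meta: pd.DataFrame,
    matrix: str,
    family_alpha: float = 0.05,
    friedman_conditions: tuple[int, ...] = tuple(range(1, 16)),
) -> pd.DataFrame:
    """Friedman gate plus Wilcoxon post-hoc report for one matrix.

    The Friedman test runs on the complete design (conditions 1-15, all
    donors); only analytes with Friedman p < .05 get post-hoc rows.  The
    matrix decides the reference condition and the Bonferroni threshold
    (serum: 9 comparisons at .0056; plasma: 5 comparisons at .01).
    """
    if matrix == "serum":
        reference, altered = design.SERUM_REFERENCE, design.SERUM_ALTERED
    elif matrix == "plasma":
        reference, altered = design.PLASMA_REFERENCE, design.PLASMA_ALTERED
    else:
        raise StatsError(f"matrix must be 'serum' or 'plasma', got {matrix!r}")
    _, threshold = bonferroni_alpha(len(altered), family_alpha)
    records = []
    for analyte in avg_profiles.columns:
        values = avg_profiles[analyte]
        wide = _condition_matrix(values, avg_meta, list(friedman_conditions)).dropna()
        stat, p_friedman = friedman_per_analyte(wide.to_numpy())
        records.append(
            dict(analyte=analyte, test="friedman", condition=np.nan, n=wide.shape[0],
                 statistic=stat, p=p_friedman, threshold=family_alpha,
                 significant=bool(p_friedman < family_alpha))
        )
        if p_friedman < family_alpha:
            for row in posthoc_vs_reference(values, avg_meta, reference, altered, threshold):
                records.append(
                    dict(analyte=analyte, test="wilcoxon", condition=row["condition"],
                         n=row["n"], statistic=row["Z"], p=row["p"],
                         threshold=threshold, significant=row["significant"],
                         median=row["median"], iqr_low=row["iqr_low"],
                         iqr_high=row["iqr_high"])
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

_EVANS_BINS = (
    (0.0, 0.2, "very weak"),
    (0.2, 0.4, "weak"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "strong"),
    (0.8, 1.0 + 1e-12, "very strong"),
)


def evans_label(r: float) -> str:
    """Evans strength class of a correlation coefficient, by |r| in 0.2-wide
    bins; boundary values go to the upper bin (.80 is 'very strong')."""
    a = abs(r)
    if not 0 <= a <= 1:
        raise StatsError(f"|r| must be in [0, 1], got {r}")
    for lo, hi, label in _EVANS_BINS:
        if lo <= a < hi:
            return label
    return "very strong"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    label: str
    sign: int


def hemolysis_correlation(values: np.ndarray, hemoglobin: np.ndarray) -> CorrelationResult:
    """Pearson correlation between free hemoglobin (mg/dl) and a target value.

    Two-sided p from the t reference distribution; the Evans strength label
    is attached.  Zero variance in either variable is an error.
    """
    v = np.asarray(values, dtype=float)
    hb = np.asarray(hemoglobin, dtype=float)
    if len(v) != len(hb) or len(v) < 3:
        raise StatsError("need >= 3 paired observations")
    if np.ptp(v) == 0 or np.ptp(hb) == 0:
        raise StatsError("zero variance in correlation input")
    res = sps.pearsonr(hb, v)
    r = float(np.clip(res.statistic, -1.0, 1.0))
    return CorrelationResult(
        r=r, n=len(v), p=float(res.pvalue), label=evans_label(r),
        sign=int(np.sign(r)),
    )
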