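"""Nonparametric statistics relating morphology to pathology burdens.

Group comparisons use the two-sided Mann–Whitney U test (exact enumeration
for small tie-free samples, tie-corrected normal approximation otherwise);
associations use Spearman rank correlation with the squared coefficient
reported alongside. All tests run at the 5% level with no multiple-testing
correction, reflecting the explorative character of the analysis. The module
also provides the greedy Pearson-correlation feature reduction (|r| > 0.80
drops a feature against the already-retained set) and cohort descriptives
(group means of age and post-mortem delay, percent female).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult",
    "CorrelationResult",
    "CohortSummary",
    "mann_whitney_u",
    "spearman_r",
    "feature_select_correlation",
    "cohort_summary",
    "correlation_matrix",
    "ALPHA",
]

ALPHA = 0.05

#: Largest combined sample size for which the exact U distribution is used.
EXACT_N_MAX = 12


@dataclass
class StatResult:
    statistic: float  # U statistic of the first sample
    p_value: float
    n1: int
    n2: int
    significant: bool
    comparison: str = ""


@dataclass
class CorrelationResult:
    rho: float
    r2_spear: float
    p_value: float
    n: int
    significant: bool


def mann_whitney_u(sample_a, sample_b, comparison: str = "") -> StatResult:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when the combined sample size is at
    most 12 and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= EXACT_N_MAX and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return StatResult(
        statistic=float(res.statistic),
        p_value=p,
        n1=int(a.size),
        n2=int(b.size),
        significant=p < ALPHA,
        comparison=comparison,
    )


def spearman_r(x, y) -> CorrelationResult:
    """Spearman rank correlation with average-rank tie handling.

    p-value from the t-distribution approximation. Constant inputs raise,
    since the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for a constant sample")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    p = float(p)
    return CorrelationResult(
        rho=rho, r2_spear=rho**2, p_value=p, n=int(x.size), significant=p < ALPHA
    )


def feature_select_correlation(
    matrix: pd.DataFrame | np.ndarray, r_max: float = 0.80
) -> list[str]:
    """Greedy correlation-based feature reduction.

    Scanning features in canonical (column) order, a feature is dropped when
    its absolute Pearson correlation with any already-retained feature
    exceeds ``r_max``; otherwise it is retained. Constant features carry an
    undefined correlation and are retained.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    if matrix.shape[1] < 2:
        raise ValueError("need at least two features")
    values = matrix.to_numpy(dtype=float)
    names = [str(c) for c in matrix.columns]
    stds = values.std(axis=0)
    retained: list[int] = []
    for j in range(values.shape[1]):
        if stds[j] == 0:
            retained.append(j)  # constant: correlated with nothing
            continue
        drop = False
        for i in retained:
            if stds[i] == 0:
                continue
            r = np.corrcoef(values[:, i], values[:, j])[0, 1]
            if abs(r) > r_max:
                drop = True
                break
        if not drop:
            retained.append(j)
    return [names[j] for j in retained]


def _round1(value: float) -> float:
    """Round to 1 decimal, halves away from zero (on the binary double)."""
    return float(Decimal(value).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _mean(values) -> float:
    """Mean via exact (fsum) summation, so printed-precision descriptives do
    not depend on the summation order of the backing array library."""
    values = list(map(float, values))
    return math.fsum(values) / len(values)


@dataclass
class CohortSummary:
    """Printed-precision descriptives of one analysis group."""

    group: str
    n: int
    mean_age: float  # years, 1 decimal
    mean_pmd: float  # hours, 1 decimal
    percent_female: float  # %, 1 decimal


def cohort_summary(
    cohort_table: pd.DataFrame, analysis_groups: dict[str, list[str]]
) -> dict[str, CohortSummary]:
    """Group descriptives (mean age/PMD, percent female) at printed precision.

    ``analysis_groups`` maps a group label to the case ids entering that
    group's summaries, letting validation-only cases be excluded explicitly.
    """
    table = cohort_table.set_index(cohort_table["case_id"].astype(str))
    out: dict[str, CohortSummary] = {}
    for group, case_ids in analysis_groups.items():
        ids = [str(c) for c in case_ids]
        missing = [c for c in ids if c not in table.index]
        if missing:
            raise ValueError(f"group {group!r}: unknown case ids {missing}")
        if not ids:
            raise ValueError(f"group {group!r} is empty")
        sub = table.loc[ids]
        out[group] = CohortSummary(
            group=group,
            n=len(sub),
            mean_age=_round1(_mean(sub["age"])),
            mean_pmd=_round1(_mean(sub["pmd"])),
            percent_female=_round1(100.0 * _mean(sub["sex"] == "F")),
        )
    return out


def correlation_matrix(
    variables: pd.DataFrame,
    loads: pd.DataFrame,
    min_n: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of every variable against every marker load.

    ``variables``: one row per sample (indexed or keyed by ``case_id`` and
    ``subfield``) with feature or cluster-abundance columns. ``loads``: long
    table with columns ``case_id``, ``subfield``, ``marker``, ``percent``.
    One test per (variable, marker, subfield) on the case-matched samples;
    cells with fewer than ``min_n`` matched samples are marked undefined.
    Significance at 5%, uncorrected.
    """
    for col in ("case_id", "subfield"):
        if col not in variables.columns:
            raise ValueError(f"variables table must contain {col!r}")
        if col not in loads.columns:
            raise ValueError(f"loads table must contain {col!r}")
    var_cols = [
        c for c in variables.columns if c not in ("case_id", "subfield", "condition")
    ]
    rows = []
    for subfield in sorted(variables["subfield"].unique()):
        vsub = variables[variables["subfield"] == subfield]
        lsub = loads[loads["subfield"] == subfield]
        for marker in sorted(lsub["marker"].unique()):
            msub = lsub[lsub["marker"] == marker].set_index("case_id")["percent"]
            merged = vsub.set_index("case_id").join(msub.rename("_load"), how="inner")
            for var in var_cols:
                pair = merged[[var, "_load"]].dropna()
                record = {
                    "subfield": subfield,
                    "marker": marker,
                    "variable": var,
                    "n": len(pair),
                }
                try:
                    if len(pair) < min_n:
                        raise ValueError("too few matched samples")
                    res = spearman_r(pair[var].to_numpy(), pair["_load"].to_numpy())
                    record.update(
                        rho=res.rho,
                        r2_spear=res.r2_spear,
                        p_value=res.p_value,
                        significant=res.significant,
                        defined=True,
                    )
                except ValueError:
                    record.update(
                        rho=np.nan,
                        r2_spear=np.nan,
                        p_value=np.nan,
                        significant=False,
                        defined=False,
                    )
                rows.append(record)
    return pd.DataFrame(rows)
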