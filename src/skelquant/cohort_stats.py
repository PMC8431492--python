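"""Paired before/after comparison of per-subject numeric columns.

Works on any numeric column set keyed by subject — the 33 movement features
or externally supplied scale scores.  Each column is compared with a
two-tailed paired t test (n - 1 degrees of freedom); pairs with a missing
value on either side are dropped per column and the effective n is reported.
No multiple-testing correction is applied to the primary p-values; a
Holm-adjusted column is emitted alongside as a clearly labelled extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    InputError,
    InsufficientPairsError,
    SubjectMismatchError,
)

#: Significance thresholds and their star labels, most stringent first.
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p_value: float) -> str:
    """'***' for p < 0.001, '**' for p < 0.01, '*' for p < 0.05, else ''."""
    if not math.isfinite(p_value):
        return ""
    for threshold, stars in STAR_THRESHOLDS:
        if p_value < threshold:
            return stars
    return ""


def paired_t_test(before: Sequence[float], after: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired t test on before - after differences.

    Pairs with a missing value on either side are dropped.  A positive t
    means the column decreased after.  All-zero differences give (0.0, 1.0);
    identical nonzero differences raise :class:`DegenerateVarianceError`.
    """
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("before/after must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    d = x[keep] - y[keep]
    n = d.size
    if n < 2:
        raise InsufficientPairsError(f"only {n} complete pair(s); need >= 2")
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d[0] == 0.0:
            return 0.0, 1.0
        raise DegenerateVarianceError(
            "identical nonzero differences: t statistic diverges"
        )
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p


@dataclass
class PairedCohort:
    """Matched before/after numeric tables indexed by subject_id."""

    before: pd.DataFrame
    after: pd.DataFrame

    def __post_init__(self) -> None:
        b, a = set(self.before.index), set(self.after.index)
        if b != a:
            raise SubjectMismatchError(
                f"unmatched subjects: only-before={sorted(b - a)}, "
                f"only-after={sorted(a - b)}"
            )
        if len(b) < 2:
            raise InputError("a paired cohort needs at least 2 subjects")
        if set(self.before.columns) != set(self.after.columns):
            raise InputError("before/after column sets differ")
        self.after = self.after.loc[self.before.index, self.before.columns]

    @property
    def subjects(self) -> list:
        return list(self.before.index)

    @classmethod
    def from_feature_frames(cls, before: pd.DataFrame, after: pd.DataFrame) -> "PairedCohort":
        """Build from feature CSV frames carrying subject_id/session columns."""
        def prep(df: pd.DataFrame) -> pd.DataFrame:
            df = df.set_index("subject_id")
            return df.drop(columns=[c for c in ("session",) if c in df.columns])
        return cls(prep(before), prep(after))


@dataclass
class PairedComparisonResult:
    """One comparison-table row: summary stats, t, p, stars."""

    column: str
    n: int
    mean_before: float
    sd_before: float
    mean_after: float
    sd_after: float
    t_statistic: float
    p_value: float
    stars: str
    holm_p: float = float("nan")
    note: str = ""


def compare_cohort(
    cohort: PairedCohort,
    columns: Sequence[str] | None = None,
) -> list[PairedComparisonResult]:
    """One result row per column, in the given (or table) order.

    Per-column failures (too few pairs, degenerate variance) are reported as
    flagged rows with NaN statistics rather than aborting the run.  The
    ``holm_p`` field carries Holm step-down adjusted p-values across the
    compared columns — an extension beyond the uncorrected primary analysis.
    """
    if columns is None:
        columns = list(cohort.before.columns)
    else:
        missing = [c for c in columns if c not in cohort.before.columns]
        if missing:
            raise InputError(f"columns not present in cohort: {missing}")
    results: list[PairedComparisonResult] = []
    for col in columns:
        x = cohort.before[col].to_numpy(dtype=float)
        y = cohort.after[col].to_numpy(dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        n_eff = int(keep.sum())
        xk, yk = x[keep], y[keep]
        summary = dict(
            mean_before=float(xk.mean()) if n_eff else float("nan"),
            sd_before=float(xk.std(ddof=1)) if n_eff > 1 else float("nan"),
            mean_after=float(yk.mean()) if n_eff else float("nan"),
            sd_after=float(yk.std(ddof=1)) if n_eff > 1 else float("nan"),
        )
        try:
            t, p = paired_t_test(x, y)
            results.append(
                PairedComparisonResult(
                    col, n_eff, **summary,
                    t_statistic=t, p_value=p, stars=significance_stars(p),
                )
            )
        except (InsufficientPairsError, DegenerateVarianceError) as exc:
            results.append(
                PairedComparisonResult(
                    col, n_eff, **summary,
                    t_statistic=float("nan"), p_value=float("nan"),
                    stars="", note=str(exc),
                )
            )
    _attach_holm(results)
    return results


def _attach_holm(results: list[PairedComparisonResult]) -> None:
    """Holm step-down adjustment over the rows with a defined p-value."""
    indexed = [(i, r.p_value) for i, r in enumerate(results) if math.isfinite(r.p_value)]
    m = len(indexed)
    if m == 0:
        return
    order = sorted(range(m), key=lambda k: indexed[k][1])
    running = 0.0
    adjusted = [0.0] * m
    for rank, k in enumerate(order):
        running = max(running, (m - rank) * indexed[k][1])
        adjusted[k] = min(1.0, running)
    for (i, _), adj in zip(indexed, adjusted):
        results[i].holm_p = adj


def results_to_frame(results: Sequence[PairedComparisonResult]) -> pd.DataFrame:
    """Comparison rows as a table mirroring the before/after report layout."""
    return pd.DataFrame(
        [
            {
                "parameter": r.column,
                "n": r.n,
                "mean_before": r.mean_before,
                "sd_before": r.sd_before,
                "mean_after": r.mean_after,
                "sd_after": r.sd_after,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "stars": r.stars,
                "holm_p": r.holm_p,
                "note": r.note,
            }
            for r in results
        ]
    )


def write_comparison_csv(results: Sequence[PairedComparisonResult], path: str | Path) -> Path:
    path = Path(path)
    results_to_frame(results).to_csv(path, index=False)
    return path
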