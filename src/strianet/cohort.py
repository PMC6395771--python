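"""Group-comparison statistics for the demographic table.

Categorical variables are compared with a Wald test on the log odds ratio
of a 2x2 contingency table; continuous variables with Mood's median test
(exact Fisher p on the dichotomized 2x2, appropriate at the study's sample
sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "LogOddsResult",
    "log_odds_ratio_wald",
    "median_test",
    "cohort_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows = groups (case, control), columns = levels."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each row needs at least one observation")


@dataclass(frozen=True)
class LogOddsResult:
    odds_ratio: float
    log_or: float
    se: float
    z: float
    p: float
    continuity_corrected: bool


def log_odds_ratio_wald(table: ContingencyTable2x2) -> LogOddsResult:
    """Wald test on ln OR with se = sqrt(1/a + 1/b + 1/c + 1/d).

    A zero cell triggers the Haldane–Anscombe +0.5 correction on all four
    cells; the result is flagged via ``continuity_corrected``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    odds_ratio = (a * d) / (b * c)
    log_or = np.log(odds_ratio)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return LogOddsResult(float(odds_ratio), float(log_or), float(se), float(z),
                         float(p), corrected)


def median_test(x, y) -> tuple[float, float]:
    """Mood's median test with an exact (Fisher) p-value.

    Each value is classified against the pooled grand median; values equal
    to it count on the "<= median" side.  Returns ``(statistic, p)`` where
    the statistic is the case-group count above the grand median.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    grand = np.median(np.concatenate([x, y]))
    ax, bx = int(np.sum(x > grand)), int(np.sum(x <= grand))
    ay, by = int(np.sum(y > grand)), int(np.sum(y <= grand))
    if ax + ay == 0:
        warnings.warn("all values tied at the grand median; p set to 1")
        return float(ax), 1.0
    _, p = stats.fisher_exact([[ax, bx], [ay, by]], alternative="two-sided")
    return float(ax), float(min(1.0, p))


def _categorical_row(meta: pd.DataFrame, var: str) -> tuple[pd.DataFrame, float]:
    levels = sorted(meta[var].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"categorical variable {var!r} must have exactly 2 levels")
    case = meta[meta["group"] == "case"][var]
    ctrl = meta[meta["group"] == "control"][var]
    t = ContingencyTable2x2(
        a=int((case == levels[0]).sum()),
        b=int((case == levels[1]).sum()),
        c=int((ctrl == levels[0]).sum()),
        d=int((ctrl == levels[1]).sum()),
    )
    res = log_odds_ratio_wald(t)
    rows = []
    for lev, n_case, n_ctrl in [(levels[0], t.a, t.c), (levels[1], t.b, t.d)]:
        rows.append(
            {
                "variable": var,
                "parameter": str(lev),
                "case_summary": f"{n_case} ({100 * n_case / (t.a + t.b):.0f})",
                "control_summary": f"{n_ctrl} ({100 * n_ctrl / (t.c + t.d):.0f})",
            }
        )
    return pd.DataFrame(rows), res.p


def _continuous_row(meta: pd.DataFrame, var: str) -> tuple[pd.DataFrame, float]:
    case = meta[meta["group"] == "case"][var].dropna().astype(float)
    ctrl = meta[meta["group"] == "control"][var].dropna().astype(float)
    _, p = median_test(case, ctrl)
    rows = [
        {
            "variable": var,
            "parameter": "Median",
            "case_summary": f"{case.median():.1f}",
            "control_summary": f"{ctrl.median():.1f}",
        },
        {
            "variable": var,
            "parameter": "Mean (SE)",
            "case_summary": f"{case.mean():.1f} ({case.sem():.1f})",
            "control_summary": f"{ctrl.mean():.1f} ({ctrl.sem():.1f})",
        },
    ]
    return pd.DataFrame(rows), p


def cohort_table(metadata: pd.DataFrame, variables: dict[str, str]) -> pd.DataFrame:
    """Per-variable group summary table with p-values.

    ``variables`` maps column name -> type (``"categorical"`` dispatches to
    the log-odds-ratio Wald test, ``"continuous"`` to the median test).
    The first row of each variable block carries its p-value.
    """
    if set(metadata["group"].unique()) != {"case", "control"}:
        raise ValueError("metadata must contain both case and control groups")
    blocks = []
    for var, kind in variables.items():
        if kind == "categorical":
            block, p = _categorical_row(metadata, var)
        elif kind == "continuous":
            block, p = _continuous_row(metadata, var)
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
        block["p"] = [round(p, 4)] + [np.nan] * (len(block) - 1)
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)
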