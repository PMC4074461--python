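"""Measurement-reliability statistics for sway metrics.

Implements the agreement toolbox a reliability study needs:

* two-way ANOVA intraclass correlation coefficients (ICC) with 95% CIs in the
  McGraw–Wong parameterisation — absolute agreement or consistency, single or
  average measures. The default for inter-rater and device-validity
  comparisons is ICC(2,1) (two-way random, absolute agreement, single
  measures), the form whose assumptions match SEM and Bland–Altman; the
  consistency form ICC(3,1) is additionally reported for intra-rater
  comparisons.
* ICC banding: >= 0.80 high, >= 0.60 moderate, below low (band edges are
  half-open at the lower bound).
* standard error of measurement, SEM = SD * sqrt(1 - ICC), with the
  repeated-measures correction factor sqrt(n_repeats).
* paired differences (second condition minus first) with a two-sided paired
  t-test, and Bland–Altman bias / 95% limits of agreement (1.96 multiplier).
* report generation shaped like a reliability-study table: one row per
  task x metric, columns mean±SD per condition, difference, ICC (95% CI), SEM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DesignError,
    PairingError,
    ParameterError,
    UndefinedICCError,
)
from .metrics import TASKS

logger = logging.getLogger(__name__)

#: 95% limits-of-agreement multiplier (normal two-sided 95% quantile).
LOA_MULTIPLIER = 1.96

METRIC_LABELS = {"pl_cm": "PL(cm)", "va_cm_s": "VA(cm/s)"}


# ---------------------------------------------------------------------------
# Ratings matrix
# ---------------------------------------------------------------------------

@dataclass
class RatingsMatrix:
    """n_subjects x k_measurements grid of one metric, complete cases only."""

    values: np.ndarray
    rows: Tuple[str, ...]
    cols: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("ratings must form a 2-D matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ParameterError(
                f"need at least 2 subjects and 2 measurements, got {n} x {k}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("ratings matrix contains missing/non-finite cells")
        if len(self.rows) != n or len(self.cols) != k:
            raise ParameterError("row/column labels must match the matrix shape")

    @classmethod
    def from_long(
        cls,
        table: pd.DataFrame,
        value_col: str,
        row_col: str = "subject",
        col_col: str = "session",
        cols: Optional[Sequence[str]] = None,
    ) -> "RatingsMatrix":
        """Pivot a long table to a complete-case ratings matrix.

        Subjects with any missing cell are dropped (count logged) — the
        two-way ANOVA requires a complete grid.
        """
        wide = table.pivot_table(
            index=row_col, columns=col_col, values=value_col, aggfunc="mean"
        )
        if cols is not None:
            missing = [c for c in cols if c not in wide.columns]
            if missing:
                raise DesignError(f"sessions not present in data: {missing}")
            wide = wide[list(cols)]
        complete = wide.dropna()
        dropped = len(wide) - len(complete)
        if dropped:
            logger.warning(
                "DROPPED_INCOMPLETE_SUBJECT: %d subject(s) lacked a complete "
                "set of measurements", dropped,
            )
        return cls(
            values=complete.to_numpy(dtype=float),
            rows=tuple(str(r) for r in complete.index),
            cols=tuple(str(c) for c in complete.columns),
        )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    """One ICC estimate with its 95% CI and the ANOVA mean squares."""

    icc: float
    ci_low: float
    ci_high: float
    definition: str
    unit: str
    n: int
    k: int
    ms_rows: float
    ms_cols: float
    ms_error: float


def _anova_mean_squares(values: np.ndarray) -> Tuple[float, float, float]:
    """Two-way single-observation ANOVA decomposition (rows, columns, error)."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((values - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    if ss_total <= 0:
        raise UndefinedICCError(
            "all ratings are identical: total variance is zero, ICC undefined"
        )
    return ms_rows, ms_cols, ms_err


def icc_two_way(
    m: RatingsMatrix,
    definition: str = "agreement",
    unit: str = "single",
    alpha: float = 0.05,
) -> ICCResult:
    """Two-way ANOVA ICC with a (1 - alpha) confidence interval.

    ``definition="agreement"`` treats column (rater/session/device) offsets as
    error — ICC(2,1)/ICC(2,k); ``"consistency"`` ignores them —
    ICC(3,1)/ICC(3,k). ``unit`` selects single- or average-measures scaling.
    CIs follow the exact/approximate F constructions of the McGraw–Wong
    conventions.
    """
    if definition not in ("agreement", "consistency"):
        raise ParameterError(f"unknown ICC definition {definition!r}")
    if unit not in ("single", "average"):
        raise ParameterError(f"unknown ICC unit {unit!r}")
    n, k = m.n, m.k
    msr, msc, mse = _anova_mean_squares(m.values)

    if definition == "consistency":
        if unit == "single":
            icc = (msr - mse) / (msr + (k - 1) * mse)
        else:
            icc = (msr - mse) / msr if msr > 0 else 0.0
        df2 = (n - 1) * (k - 1)
        if mse <= 0:
            lo = hi = icc
        else:
            fstat = msr / mse
            f_upper = stats.f.ppf(1 - alpha / 2, n - 1, df2)
            f_lower = stats.f.ppf(1 - alpha / 2, df2, n - 1)
            fl = fstat / f_upper
            fu = fstat * f_lower
            if unit == "single":
                lo = (fl - 1) / (fl + k - 1)
                hi = (fu - 1) / (fu + k - 1)
            else:
                lo = 1 - 1 / fl
                hi = 1 - 1 / fu
    else:
        denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
        if denom_single <= 0:
            raise UndefinedICCError("degenerate ANOVA table: ICC denominator <= 0")
        icc_single = (msr - mse) / denom_single
        icc = icc_single if unit == "single" else (msr - mse) / (
            msr + (msc - mse) / n
        )
        if mse <= 0 and msc <= 0:
            lo = hi = icc
        else:
            # Satterthwaite df for the agreement form
            r = icc_single
            if abs(1 - r) < 1e-12:
                lo = hi = icc
            else:
                a = (k * r) / (n * (1 - r))
                b = 1 + (k * r * (n - 1)) / (n * (1 - r))
                num = (a * msc + b * mse) ** 2
                den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                v = num / den if den > 0 else (n - 1) * (k - 1)
                if not (np.isfinite(v) and v > 0):
                    # Satterthwaite df collapses on degenerate tables; fall
                    # back to the error df (widest reasonable interval)
                    v = (n - 1) * (k - 1)
                f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    lo = (
                        n * (msr - f1 * mse)
                        / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
                    )
                    hi = (
                        n * (f2 * msr - mse)
                        / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
                    )
                if not np.isfinite(lo):
                    lo = -1.0
                if not np.isfinite(hi):
                    hi = 1.0
                if unit == "average":
                    # Spearman-Brown step-up of the single-measures bounds
                    lo = k * lo / (1 + (k - 1) * lo)
                    hi = k * hi / (1 + (k - 1) * hi)

    lo, hi = float(np.clip(lo, -1, 1)), float(np.clip(hi, -1, 1))
    lo = min(lo, float(icc))
    hi = max(hi, float(icc))
    return ICCResult(
        icc=float(icc),
        ci_low=lo,
        ci_high=hi,
        definition=definition,
        unit=unit,
        n=n,
        k=k,
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
    )


def classify_icc(icc: float) -> str:
    """Band an ICC estimate: >= 0.80 high, >= 0.60 moderate, else low."""
    if not np.isfinite(icc):
        raise ParameterError(f"ICC must be finite to classify, got {icc}")
    if icc >= 0.80:
        return "high"
    if icc >= 0.60:
        return "moderate"
    return "low"


def sem(sd: float, icc: float, n_repeats: int = 1) -> float:
    """Standard error of measurement: SD * sqrt(1 - ICC) * sqrt(n_repeats).

    Negative ICC estimates (possible in small samples) and estimates above 1
    are clamped into [0, 1] with a warning. ``n_repeats`` applies the
    repeated-measures correction; the default 1 matches an analysis run on
    already-averaged trials.
    """
    if sd < 0:
        raise ParameterError(f"SD must be >= 0, got {sd}")
    if n_repeats < 1:
        raise ParameterError(f"n_repeats must be >= 1, got {n_repeats}")
    if not 0.0 <= icc <= 1.0:
        warnings.warn(
            f"ICC {icc:.4f} outside [0, 1]; clamped for SEM", stacklevel=2
        )
        icc = float(np.clip(icc, 0.0, 1.0))
    return float(sd * np.sqrt(1.0 - icc) * np.sqrt(n_repeats))


# ---------------------------------------------------------------------------
# Paired differences and Bland-Altman
# ---------------------------------------------------------------------------

def mean_difference(a_mean: float, b_mean: float) -> float:
    """Difference-column sign convention: second condition minus first."""
    return float(b_mean) - float(a_mean)


@dataclass(frozen=True)
class PairedDifference:
    diff_mean: float
    diff_sd: float
    p_value: float
    n: int


def _paired(a, b) -> Tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(f"paired vectors must match in length, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise PairingError("paired analysis needs at least 2 pairs")
    return a, b


def paired_difference(a, b) -> PairedDifference:
    """Elementwise b - a with mean, SD (n-1 denominator) and paired-t p-value.

    The p-value is NaN when every difference is identical (zero variance).
    """
    a, b = _paired(a, b)
    d = b - a
    sd_d = float(d.std(ddof=1))
    if sd_d == 0:
        p = float("nan")
    else:
        p = float(stats.ttest_rel(b, a).pvalue)
    return PairedDifference(
        diff_mean=float(d.mean()), diff_sd=sd_d, p_value=p, n=d.size
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement summary: bias, SD of differences, 95% limits of agreement."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pairs: np.ndarray  # (n, 2) columns: pairwise mean, difference (b - a)


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland–Altman analysis of two paired measurement sets.

    Each pair contributes the point ((a+b)/2, b-a); bias is the mean
    difference and the limits of agreement are bias ± 1.96 * SD(differences).
    """
    a, b = _paired(a, b)
    d = b - a
    bias = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd_d,
        loa_low=bias - LOA_MULTIPLIER * sd_d,
        loa_high=bias + LOA_MULTIPLIER * sd_d,
        pairs=np.column_stack([(a + b) / 2.0, d]),
    )


def plot_bland_altman(result: BlandAltmanResult, ax=None, title: str = ""):
    """Render a Bland–Altman plot (mean vs difference, bias and LOA lines)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.pairs[:, 0], result.pairs[:, 1], s=18, color="k")
    ax.axhline(result.bias, color="b", lw=1.2, label=f"bias {result.bias:.2f}")
    for y, lbl in ((result.loa_low, "LOA low"), (result.loa_high, "LOA high")):
        ax.axhline(y, color="r", ls="--", lw=1.0, label=f"{lbl} {y:.2f}")
    ax.set_xlabel("mean of measurements")
    ax.set_ylabel("difference (second - first)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


# ---------------------------------------------------------------------------
# Report generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonSpec:
    """One session-pair comparison (e.g. inter-rater: A1 vs B)."""

    name: str
    session_a: str
    session_b: str
    kind: str = "inter_rater"  # inter_rater | intra_rater | validity

    def __post_init__(self) -> None:
        if self.kind not in ("inter_rater", "intra_rater", "validity"):
            raise DesignError(f"unknown comparison kind {self.kind!r}")


#: Standard study design: rater1/day1 vs rater2/day1, vs rater1/day2,
#: vs force-platform/day3.
DEFAULT_COMPARISONS = (
    ComparisonSpec("inter_rater", "A1", "B", "inter_rater"),
    ComparisonSpec("intra_rater", "A1", "A2", "intra_rater"),
    ComparisonSpec("validity", "A1", "A3", "validity"),
)

REPORT_COLUMNS = (
    "task", "metric", "mean_a", "sd_a", "mean_b", "sd_b",
    "diff_mean", "diff_sd", "p", "stars",
    "icc", "ci_low", "ci_high", "sem", "band",
    "icc_consistency", "ci_c_low", "ci_c_high", "n_subjects",
)


def significance_stars(p: float) -> str:
    """Two-sided paired-test flags: * p<0.05, ** p<0.01, blank otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def reliability_report(
    summaries: pd.DataFrame,
    comparison: ComparisonSpec,
    metrics: Sequence[str] = ("pl_cm", "va_cm_s"),
    tasks: Optional[Sequence[str]] = None,
    n_repeats: int = 1,
) -> pd.DataFrame:
    """Build the reliability table for one session-pair comparison.

    ``summaries`` is the condition-summary table (one row per subject x task
    x session, mean of trials). Output: one row per task x metric with
    condition means ± SD, paired difference (+ t-test stars), ICC(2,1) with
    95% CI and band, and SEM from the pooled two-condition SD. For
    intra-rater comparisons the consistency ICC(3,1) and its CI are filled in
    as well; for other kinds those columns are NaN.
    """
    for ses in (comparison.session_a, comparison.session_b):
        if ses not in set(summaries["session"]):
            raise DesignError(
                f"session {ses!r} required by comparison {comparison.name!r} "
                "is absent from the summary table"
            )
    if tasks is None:
        present = list(dict.fromkeys(summaries["task"]))
        tasks = [t for t in TASKS if t in present] or present

    rows = []
    for task in tasks:
        sub = summaries[summaries["task"] == task]
        for metric in metrics:
            m = RatingsMatrix.from_long(
                sub, metric, cols=(comparison.session_a, comparison.session_b)
            )
            a, b = m.values[:, 0], m.values[:, 1]
            diff = paired_difference(a, b)
            agree = icc_two_way(m, definition="agreement", unit="single")
            pooled_sd = float(np.sqrt((a.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2))
            row = {
                "task": task,
                "metric": metric,
                "mean_a": float(a.mean()),
                "sd_a": float(a.std(ddof=1)),
                "mean_b": float(b.mean()),
                "sd_b": float(b.std(ddof=1)),
                "diff_mean": diff.diff_mean,
                "diff_sd": diff.diff_sd,
                "p": diff.p_value,
                "stars": significance_stars(diff.p_value),
                "icc": agree.icc,
                "ci_low": agree.ci_low,
                "ci_high": agree.ci_high,
                "sem": sem(pooled_sd, agree.icc, n_repeats),
                "band": classify_icc(agree.icc),
                "icc_consistency": np.nan,
                "ci_c_low": np.nan,
                "ci_c_high": np.nan,
                "n_subjects": m.n,
            }
            if comparison.kind == "intra_rater":
                cons = icc_two_way(m, definition="consistency", unit="single")
                row.update(
                    icc_consistency=cons.icc,
                    ci_c_low=cons.ci_low,
                    ci_c_high=cons.ci_high,
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def render_report_text(report: pd.DataFrame, comparison: ComparisonSpec) -> str:
    """Aligned plain-text rendering in the conventional table layout."""
    header = (
        f"Comparison {comparison.name}: {comparison.session_a} vs "
        f"{comparison.session_b} ({comparison.kind})"
    )
    lines = [header, "-" * len(header)]
    lines.append(
        f"{'Task':<6}{'Metric':<10}{comparison.session_a:>16}"
        f"{comparison.session_b:>16}{'Difference':>18}{'ICC (95% CI)':>24}{'SEM':>8}"
    )
    for _, r in report.iterrows():
        lines.append(
            f"{r['task']:<6}{METRIC_LABELS.get(r['metric'], r['metric']):<10}"
            f"{r['mean_a']:>8.2f} ± {r['sd_a']:<5.2f}"
            f"{r['mean_b']:>8.2f} ± {r['sd_b']:<5.2f}"
            f"{r['diff_mean']:>9.2f} ± {r['diff_sd']:<5.2f}{r['stars']:<3}"
            f"{r['icc']:>8.3f} ({r['ci_low']:.3f}, {r['ci_high']:.3f})"
            f"{r['sem']:>8.3f}"
        )
    return "\n".join(lines)


def bland_altman_table(
    summaries: pd.DataFrame,
    comparison: ComparisonSpec,
    task: str,
    metric: str = "pl_cm",
) -> Tuple[pd.DataFrame, BlandAltmanResult]:
    """Per-subject (mean, difference) points for one task/metric agreement plot."""
    sub = summaries[summaries["task"] == task]
    m = RatingsMatrix.from_long(
        sub, metric, cols=(comparison.session_a, comparison.session_b)
    )
    res = bland_altman(m.values[:, 0], m.values[:, 1])
    points = pd.DataFrame(
        {
            "subject": list(m.rows),
            "mean": res.pairs[:, 0],
            "difference": res.pairs[:, 1],
        }
    )
    return points, res
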