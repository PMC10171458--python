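"""Rank-correlation and agreement statistics for the radiology-pathology layer.

Spearman's rho is computed as the Pearson correlation of midranks (average
ranks over ties -- required because WHO grade takes only three values), and
its two-tailed significance via the t approximation
``t = |rho| sqrt((n-2)/(1-rho^2))`` on n-2 degrees of freedom, the method
standard statistical packages use for these sample sizes. Inter-reader
agreement uses the single-rater, absolute-agreement, two-way random-effects
intraclass correlation ICC(2,1) computed from the mean squares of the
subjects x raters layout. Correlation strength and agreement are binned
with the conventional cut points noted on each function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, UndefinedStatisticError
from .pathology_quant import Specimen
from .roi_extraction import PARAMETER_NAMES

__all__ = [
    "CorrelationResult",
    "ICCResult",
    "spearman_rho",
    "spearman_pvalue",
    "classify_correlation",
    "icc",
    "correlate_table",
    "correlation_frame",
    "format_report",
]

PATHOLOGY_INDICES = ("pmib1", "cd34_mvd", "who_grade")


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p_two_tailed: float
    n: int
    category: str
    exact_monotone: bool = False

    @property
    def significant_05(self) -> bool:
        return self.p_two_tailed < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_two_tailed < 0.01


@dataclass(frozen=True)
class ICCResult:
    icc: float
    n_subjects: int
    k_raters: int
    agreement: str


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ConfigurationError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ConfigurationError("inputs must be finite")
    rx = sps.rankdata(x)  # midranks for ties
    ry = sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise UndefinedStatisticError("zero variance in ranked values")
    rho = np.corrcoef(rx, ry)[0, 1]
    return float(np.clip(rho, -1.0, 1.0))


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-tailed p for an observed rho via the t approximation.

    |rho| = 1 (an exactly monotone sample) returns 0.0: the t statistic
    diverges, and any exact tail is below every reporting precision.
    """
    if n < 4:
        raise ConfigurationError("need n >= 4 for a p-value")
    if not -1.0 <= rho <= 1.0:
        raise ConfigurationError("rho must lie in [-1, 1]")
    if abs(rho) == 1.0:
        return 0.0
    t = abs(rho) * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(t, df=n - 2))


def classify_correlation(rho: float) -> str:
    """Strength bins on |rho|: <=0.40 little/fair, (0.40, 0.75] moderate to
    good, >0.75 very good to excellent."""
    r = abs(rho)
    if r > 1.0:
        raise ConfigurationError("|rho| cannot exceed 1")
    if r <= 0.40:
        return "little or fair"
    if r <= 0.75:
        return "moderate to good"
    return "very good to excellent"


def _agreement_label(value: float) -> str:
    # <0.40 poor; 0.40-0.60 moderate; 0.61-0.80 good; >0.80 excellent
    if value < 0.40:
        return "poor"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "good"
    return "excellent"


def icc(ratings) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an (n_subjects, k_raters) array with no missing cells.
    From the two-way mean squares (MSR between subjects, MSC between raters,
    MSE residual):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2:
        raise ConfigurationError("ratings must be a subjects x raters table")
    n, k = r.shape
    if n < 5 or k < 2:
        raise ConfigurationError("need at least 5 subjects and 2 raters")
    if not np.all(np.isfinite(r)):
        raise ConfigurationError("ratings table must be complete")

    grand = r.mean()
    subj_means = r.mean(axis=1)
    rater_means = r.mean(axis=0)
    ss_rows = k * np.sum((subj_means - grand) ** 2)
    ss_cols = n * np.sum((rater_means - grand) ** 2)
    ss_err = np.sum((r - subj_means[:, None] - rater_means[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if ss_rows == 0 and denom == 0:
        raise UndefinedStatisticError("zero between-subject variance")
    value = float((msr - mse) / denom)
    return ICCResult(icc=value, n_subjects=n, k_raters=k,
                     agreement=_agreement_label(value))


def correlate_table(
    specimens: list[Specimen],
    params: dict[tuple[str, str], float],
) -> list[CorrelationResult]:
    """All parameter x pathology-index correlations.

    ``params`` maps (specimen_id, parameter_name) to the reader-averaged
    ROI mean. Twelve results: {ddc1500, alpha1500, ddc5000, alpha5000} x
    {pMIB-1, CD34-MVD, WHO grade}; pMIB-1 rows use only specimens with the
    MIB-1 stain available, so their N may be smaller.
    """
    ids = [s.specimen_id for s in specimens]
    unmatched = [
        (sid, p) for sid in ids for p in PARAMETER_NAMES if (sid, p) not in params
    ]
    if unmatched:
        raise ConfigurationError(f"no parameter means for: {unmatched[:5]}")

    index_values = {
        "pmib1": np.array([s.pmib1 for s in specimens]),
        "cd34_mvd": np.array([s.cd34_mvd for s in specimens]),
        "who_grade": np.array([s.who_grade for s in specimens], dtype=float),
    }
    avail = {
        "pmib1": np.array([s.pmib1_available for s in specimens]),
        "cd34_mvd": np.ones(len(specimens), dtype=bool),
        "who_grade": np.ones(len(specimens), dtype=bool),
    }
    results = []
    for idx_name in PATHOLOGY_INDICES:
        keep = avail[idx_name]
        y = index_values[idx_name][keep]
        for p in PARAMETER_NAMES:
            x = np.array([params[(sid, p)] for sid in ids])[keep]
            rho = spearman_rho(x, y)
            exact = abs(rho) == 1.0
            results.append(
                CorrelationResult(
                    x_name=p,
                    y_name=idx_name,
                    rho=rho,
                    p_two_tailed=spearman_pvalue(rho, int(keep.sum())),
                    n=int(keep.sum()),
                    category=classify_correlation(rho),
                    exact_monotone=exact,
                )
            )
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.x_name for r in results],
            "index": [r.y_name for r in results],
            "rho": [r.rho for r in results],
            "p_two_tailed": [r.p_two_tailed for r in results],
            "n": [r.n for r in results],
            "category": [r.category for r in results],
            "sig_005": [r.significant_05 for r in results],
            "sig_001": [r.significant_01 for r in results],
        }
    )


def format_report(results: list[CorrelationResult]) -> str:
    """Formatted text table: pathology indices as rows, the four SEM
    parameters as columns; each cell shows rho (with significance markers),
    p and N. No multiple-testing correction is applied across the cells."""
    by = {(r.y_name, r.x_name): r for r in results}
    cols = PARAMETER_NAMES
    row_labels = {"pmib1": "pMIB-1", "cd34_mvd": "CD34-MVD", "who_grade": "WHO grades"}
    col_labels = {"ddc1500": "DDC_1500", "ddc5000": "DDC_5000",
                  "alpha1500": "alpha_1500", "alpha5000": "alpha_5000"}
    ordered_cols = ("ddc1500", "ddc5000", "alpha1500", "alpha5000")

    width = 12
    lines = ["Correlations of SEM-derived parameters with pathology indices",
             "(Spearman rho; two-tailed p; ** p<0.01, * p<0.05; no multiplicity correction)",
             ""]
    header = f"{'':<12}{'':<16}" + "".join(f"{col_labels[c]:>{width}}" for c in ordered_cols)
    lines.append(header)
    for idx in PATHOLOGY_INDICES:
        rs = [by[(idx, c)] for c in ordered_cols]
        mark = lambda r: "**" if r.significant_01 else ("*" if r.significant_05 else "")
        lines.append(
            f"{row_labels[idx]:<12}{'rho':<16}"
            + "".join(f"{f'{r.rho:.3f}{mark(r)}':>{width}}" for r in rs)
        )
        lines.append(
            f"{'':<12}{'Sig. (2-tailed)':<16}"
            + "".join(f"{r.p_two_tailed:>{width}.3f}" for r in rs)
        )
        lines.append(
            f"{'':<12}{'N':<16}" + "".join(f"{r.n:>{width}d}" for r in rs)
        )
        lines.append("")
    return "\n".join(lines)
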