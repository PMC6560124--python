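"""Measurement analysis: ICC(1,1) reliability, correlations, cohort QC.

Test–retest reliability uses the intraclass correlation from a one-way
random-effects model for the consistency of single measurements, ICC(1,1):

    ICC(1,1) = (MSB - MSW) / (MSB + (k - 1) * MSW)

with MSB/MSW the between/within-subject mean squares of a one-way ANOVA over
n subjects and k sessions, and the 95% confidence interval from the
F-distribution (single-measurement, one-way formulas of McGraw & Wong).
Conventional interpretation bands: >= .75 'excellent', .60-.74 'good',
.40-.59 'fair', < .40 'poor'.

Age relationships use product-moment correlations, optionally partialling
out covariates of age-related atrophy (mean cortical thickness, ventricle
volume) by the residual-regression method.  Missing measures are explicit
NaNs, never zeros; correlations use pairwise complete cases, ICC listwise.
No multiple-testing correction is applied here.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .registry import SUPPORTED_SULCI

#: Failure-rate threshold above which a sulcus is flagged as unsupported
#: for the cohort at hand.
FAILURE_RATE_THRESHOLD = 0.10


@dataclasses.dataclass
class ICCResult:
    """ICC(1,1) with its 95% CI and the underlying ANOVA mean squares."""

    icc: float
    ci_low: float
    ci_high: float
    ms_between: float
    ms_within: float
    n_subjects: int
    k_sessions: int
    undefined: bool = False

    @property
    def classification(self) -> str:
        return classify_icc(self.icc)


def classify_icc(icc: float) -> str:
    """Conventional reliability band for an ICC value."""
    if not np.isfinite(icc):
        return "undefined"
    if icc >= 0.75:
        return "excellent"
    if icc >= 0.60:
        return "good"
    if icc >= 0.40:
        return "fair"
    return "poor"


def icc_1_1(table, confidence: float = 0.95) -> ICCResult:
    """ICC(1,1) from a subjects x sessions table.

    Rows with any missing cell are dropped (listwise).  Requires >= 2
    complete subjects and >= 2 sessions.  Zero total variance yields an
    *undefined* result (NaN, flagged), not 1.0.
    """
    x = np.asarray(pd.DataFrame(table).dropna(), dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D table with k >= 2 sessions")
    n, k = x.shape
    if n < 2:
        raise ValueError("need >= 2 subjects with complete sessions")
    grand = x.mean()
    row_means = x.mean(axis=1)
    ssb = k * ((row_means - grand) ** 2).sum()
    ssw = ((x - row_means[:, None]) ** 2).sum()
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if ssb + ssw == 0.0:
        return ICCResult(np.nan, np.nan, np.nan, msb, msw, n, k, undefined=True)
    alpha = 1.0 - confidence
    if msw == 0.0:
        return ICCResult(1.0, 1.0, 1.0, msb, msw, n, k)
    f_obs = msb / msw
    fl = f_obs / sps.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
    fu = f_obs * sps.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return ICCResult(icc, ci_low, ci_high, msb, msw, n, k)


@dataclasses.dataclass
class CorrelationResult:
    """Correlation coefficient with two-sided p and the n used."""

    r: float
    p: float
    n: int
    flag: str | None = None


def pearson_r(x, y) -> CorrelationResult:
    """Product-moment correlation; pairwise complete cases; t-based p."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        return CorrelationResult(np.nan, np.nan, n, flag="insufficient-pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, n, flag="zero-variance")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n)


def partial_correlation(x, y, controls=()) -> CorrelationResult:
    """Correlation of x and y after regressing both on the control covariates.

    Residuals from ordinary least squares (with intercept); p is computed on
    n - 2 - q degrees of freedom for q controls.  With no controls this is
    exactly :func:`pearson_r`.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    controls = [np.asarray(c, dtype=np.float64) for c in controls]
    if not controls:
        return pearson_r(x, y)
    z = np.column_stack(controls)
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z).all(axis=1)
    x, y, z = x[keep], y[keep], z[keep]
    n, q = len(x), z.shape[1]
    if n < q + 3:
        return CorrelationResult(np.nan, np.nan, n, flag="insufficient-pairs")
    design = np.column_stack([np.ones(n), z])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        return CorrelationResult(np.nan, np.nan, n, flag="collinear-controls")
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ bx
    ry = y - design @ by
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        return CorrelationResult(np.nan, np.nan, n, flag="zero-variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - q
    if abs(r) >= 1.0:
        return CorrelationResult(r, 0.0, n)
    t = r * np.sqrt(df / (1 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(r, p, n)


def summarize_cohort(
    long_table: pd.DataFrame,
    mean_requires_all: bool = True,
    sulci=SUPPORTED_SULCI,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the cohort measurement table and the QC report.

    ``long_table`` has one row per measure with columns
    ``subject, hemi, sulcus, metric, value, status`` (status ``"ok"`` or a
    failure reason; failed measures carry NaN values, never zeros).

    Returns a wide per-subject table with one ``{hemi}_{sulcus}_{metric}``
    column per measure plus ``mean_width``/``mean_depth`` over the 16
    per-hemisphere sulci (NaN unless all 16 are present, by default), and a
    QC dict with per-measure failure rates; any sulcus failing in more than
    10% of subjects is flagged as unsupported for this cohort.
    """
    t = long_table.copy()
    required = {"subject", "hemi", "sulcus", "metric", "value", "status"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"long table is missing columns: {sorted(missing)}")
    t["measure"] = t["hemi"] + "_" + t["sulcus"] + "_" + t["metric"]
    wide = t.pivot_table(
        index="subject", columns="measure", values="value", aggfunc="first"
    )
    for metric in ("width", "depth"):
        cols = [
            f"{h}_{s}_{metric}" for h in ("lh", "rh") for s in sulci
        ]
        block = wide.reindex(columns=cols)
        if mean_requires_all:
            means = block.mean(axis=1).where(block.notna().all(axis=1))
        else:
            means = block.mean(axis=1)
        wide[f"mean_{metric}"] = means
        wide[f"n_{metric}_available"] = block.notna().sum(axis=1)
    failure = (
        t.assign(failed=t["status"] != "ok")
        .groupby(["hemi", "sulcus", "metric"])["failed"]
        .agg(["mean", "sum", "count"])
        .rename(columns={"mean": "failure_rate", "sum": "n_failed", "count": "n"})
    )
    flagged = sorted(
        {
            (h, s)
            for (h, s, _m), row in failure.iterrows()
            if row["failure_rate"] > FAILURE_RATE_THRESHOLD
        }
    )
    qc = {
        "failure_rates": {
            f"{h}_{s}_{m}": {
                "failure_rate": float(row["failure_rate"]),
                "n_failed": int(row["n_failed"]),
                "n": int(row["n"]),
            }
            for (h, s, m), row in failure.iterrows()
        },
        "failure_rate_threshold": FAILURE_RATE_THRESHOLD,
        "flagged_sulci": [f"{h}_{s}" for h, s in flagged],
    }
    return wide, qc
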