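"""Repeated-measures statistics over sub-volume levels and agreement ICCs.

Each metric (JI, HD, nVV) yields a subjects × levels matrix.  The analysis
chain is normality-gated: Shapiro–Wilk is applied to every level column and
the parametric branch (one-way repeated-measures ANOVA, post hoc paired t
tests) is taken only if *all* columns pass; otherwise the nonparametric
branch (Friedman omnibus, Wilcoxon signed-rank post hoc) is used.  Post hoc
p-values are Bonferroni-corrected over the full family of level pairs
(45 pairs for 10 levels).  Sphericity is not corrected.

Intraclass correlation follows the Shrout–Fleiss conventions: ICC(1,1) from
the one-way random-effects ANOVA and ICC(3,1) from the two-way mixed model,
both with F-based 95% confidence intervals.  Estimates are *not* clamped at
zero — a negative estimate is informative about the variance structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "MetricMatrix",
    "TestReport",
    "ICCReport",
    "normality_gate",
    "rm_anova",
    "friedman",
    "posthoc",
    "icc",
    "analyze_metric",
]


@dataclass
class MetricMatrix:
    """One metric's subjects × levels values, complete cases only."""

    values: np.ndarray
    metric_name: str = ""
    level_labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("metric matrix must be 2D (subjects × levels)")
        if not self.level_labels:
            self.level_labels = list(range(1, self.values.shape[1] + 1))
        if len(self.level_labels) != self.values.shape[1]:
            raise ValueError("level_labels length must match the number of columns")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_levels(self) -> int:
        return self.values.shape[1]

    def drop_incomplete_rows(self) -> "MetricMatrix":
        """Listwise deletion of subjects with any missing level value."""
        keep = np.all(np.isfinite(self.values), axis=1)
        dropped = int((~keep).sum())
        if dropped:
            log.warning("%s: %d subject(s) dropped listwise (incomplete levels)",
                        self.metric_name or "metric", dropped)
        return MetricMatrix(self.values[keep], self.metric_name, list(self.level_labels))


@dataclass
class TestReport:
    branch: str                      # "parametric" | "nonparametric"
    omnibus_test: str                # "rm_anova" | "friedman"
    omnibus_stat: float
    omnibus_p: float
    posthoc_p: np.ndarray            # levels × levels Bonferroni-corrected
    alpha: float = 0.05
    shapiro_p: list[float] = field(default_factory=list)
    level_labels: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "branch": self.branch,
            "omnibus_test": self.omnibus_test,
            "omnibus_stat": self.omnibus_stat,
            "omnibus_p": self.omnibus_p,
            "alpha": self.alpha,
            "shapiro_p": list(self.shapiro_p),
            "level_labels": list(self.level_labels),
            "posthoc_p": np.where(np.isnan(self.posthoc_p), None, self.posthoc_p).tolist(),
        }


@dataclass
class ICCReport:
    form: str
    estimate: float
    ci_lower: float
    ci_upper: float
    n_subjects: int
    n_raters: int


def normality_gate(m: MetricMatrix, alpha: float = 0.05) -> str:
    """Choose the analysis branch: parametric iff every level column is normal.

    Shapiro–Wilk per column at `alpha`; a constant column forces the
    nonparametric branch (its distribution is degenerate).  The per-column
    p-values are logged so the gating decision is auditable.
    """
    if m.n_subjects < 3:
        raise ValueError("normality testing needs at least 3 subjects")
    pvals = []
    for j in range(m.n_levels):
        col = m.values[:, j]
        if np.ptp(col) == 0:
            log.warning("%s level %s: constant column, nonparametric branch forced",
                        m.metric_name, m.level_labels[j])
            return "nonparametric"
        pvals.append(float(stats.shapiro(col).pvalue))
    log.info("%s Shapiro–Wilk per-level p-values: %s", m.metric_name,
             np.round(pvals, 4).tolist())
    return "parametric" if all(p > alpha for p in pvals) else "nonparametric"


def _shapiro_pvalues(m: MetricMatrix) -> list[float]:
    out = []
    for j in range(m.n_levels):
        col = m.values[:, j]
        out.append(float("nan") if np.ptp(col) == 0 else float(stats.shapiro(col).pvalue))
    return out


def rm_anova(m: MetricMatrix) -> tuple[float, float]:
    """One-way within-subject ANOVA: F = MS_level / MS_error.

    Sums of squares are the classical two-way decomposition with subjects as
    blocks: df_level = k-1, df_error = (n-1)(k-1).  Returns (F, p).
    """
    x = m.values
    n, k = x.shape
    if k < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 levels")
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 subjects")
    grand = x.mean()
    ss_level = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subject = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_error = ss_total - ss_level - ss_subject
    df_level = k - 1
    df_error = (n - 1) * (k - 1)
    ms_error = ss_error / df_error
    if ms_error <= 0:
        return 0.0 if ss_level == 0 else float("inf"), 1.0 if ss_level == 0 else 0.0
    f = (ss_level / df_level) / ms_error
    p = float(stats.f.sf(f, df_level, df_error))
    return float(f), p


def friedman(m: MetricMatrix) -> tuple[float, float]:
    """Friedman chi-square over within-subject midranks.  Returns (stat, p)."""
    x = m.values
    n, k = x.shape
    if n < 3 or k < 3:
        raise ValueError("Friedman test needs >= 3 subjects and >= 3 levels")
    if np.all(np.ptp(x, axis=1) == 0):
        log.warning("%s: every subject is tied across all levels; Friedman "
                    "statistic set to 0", m.metric_name)
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*(x[:, j] for j in range(k)))
    return float(stat), float(p)


def posthoc(m: MetricMatrix, branch: str, n_comparisons: int | None = None) -> np.ndarray:
    """All-pairs level comparisons with Bonferroni correction.

    Paired t tests on the parametric branch, Wilcoxon signed-rank (zeros
    discarded, midrank ties) otherwise.  Every unordered level pair is tested;
    the family size is C(k, 2) unless overridden.  A pair with an identically
    zero difference vector gets p = 1 (no evidence of a difference).  Returns
    a symmetric levels × levels matrix with NaN on the diagonal.
    """
    if branch not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown branch {branch!r}")
    x = m.values
    k = x.shape[1]
    pairs = list(combinations(range(k), 2))
    m_comp = n_comparisons if n_comparisons is not None else len(pairs)
    out = np.full((k, k), np.nan)
    for i, j in pairs:
        diff = x[:, i] - x[:, j]
        if np.all(diff == 0):
            log.warning("%s levels %s vs %s: zero-variance difference, p set to 1",
                        m.metric_name, m.level_labels[i], m.level_labels[j])
            p = 1.0
        elif branch == "parametric":
            p = float(stats.ttest_rel(x[:, i], x[:, j]).pvalue)
        else:
            p = float(stats.wilcoxon(x[:, i], x[:, j], zero_method="wilcox").pvalue)
        p_adj = min(1.0, m_comp * p)
        out[i, j] = out[j, i] = p_adj
    return out


def analyze_metric(m: MetricMatrix, alpha: float = 0.05) -> TestReport:
    """Full chain for one metric: gate -> omnibus -> post hoc."""
    m = m.drop_incomplete_rows()
    branch = normality_gate(m, alpha=alpha)
    if branch == "parametric":
        stat, p = rm_anova(m)
        test = "rm_anova"
    else:
        stat, p = friedman(m)
        test = "friedman"
    ph = posthoc(m, branch)
    return TestReport(
        branch=branch, omnibus_test=test, omnibus_stat=stat, omnibus_p=p,
        posthoc_p=ph, alpha=alpha, shapiro_p=_shapiro_pvalues(m),
        level_labels=list(m.level_labels),
    )


def _f_bounds(f_obs: float, q: float, df1: int, df2: int, k: int) -> tuple[float, float]:
    """F-based confidence bounds for a single-rater ICC."""
    if np.isinf(f_obs):  # zero error variance: the ICC is exactly 1
        return 1.0, 1.0
    fl = f_obs / stats.f.ppf(q, df1, df2)
    fu = f_obs * stats.f.ppf(q, df2, df1)
    return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)


def icc(values: np.ndarray, form: str = "ICC11", confidence: float = 0.95) -> ICCReport:
    """Single-rater intraclass correlation from ANOVA mean squares.

    ICC(1,1) = (BMS - WMS) / (BMS + (k-1) WMS)   one-way random effects
    ICC(3,1) = (BMS - EMS) / (BMS + (k-1) EMS)   two-way mixed, consistency

    `values` is subjects × raters with no missing cells.  Confidence bounds
    are the classical F-based intervals.  Estimates can be negative when the
    between-subject variance is small; they are returned unclamped with a
    warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a subjects × raters matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("ICC needs >= 5 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ICC input must have no missing cells")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    bms = k * ((row_means - grand) ** 2).sum() / (n - 1)            # between subjects
    wms = ((x - row_means[:, None]) ** 2).sum() / (n * (k - 1))     # within subjects
    jms = n * ((col_means - grand) ** 2).sum() / (k - 1)            # between raters
    ems = (((x - grand) ** 2).sum() - (n - 1) * bms - (k - 1) * jms) / ((n - 1) * (k - 1))

    q = 1 - (1 - confidence) / 2
    if form == "ICC11":
        denom = bms + (k - 1) * wms
        est = (bms - wms) / denom if denom != 0 else float("nan")
        f_obs = bms / wms if wms > 0 else float("inf")
        df1, df2 = n - 1, n * (k - 1)
        lo, hi = _f_bounds(f_obs, q, df1, df2, k)
    elif form == "ICC31":
        denom = bms + (k - 1) * ems
        est = (bms - ems) / denom if denom != 0 else float("nan")
        f_obs = bms / ems if ems > 0 else float("inf")
        df1, df2 = n - 1, (n - 1) * (k - 1)
        lo, hi = _f_bounds(f_obs, q, df1, df2, k)
    else:
        raise ValueError("form must be 'ICC11' or 'ICC31'")
    if est <= 0:
        log.warning("ICC %s estimate is non-positive (%.4f): between-subject "
                    "variance does not exceed error variance", form, est)
    return ICCReport(form=form, estimate=float(est), ci_lower=float(lo),
                     ci_upper=float(hi), n_subjects=n, n_raters=k)
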