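"""Interobserver agreement and group-comparison statistics.

Agreement between two (or more) raters is summarised by:

* **ICC(2,k)** — the Shrout–Fleiss two-way random-effects, average-measures
  intraclass correlation, computed from the two-way ANOVA mean squares
  ``ICC = (MSR - MSE) / (MSR + (MSC - MSE)/n)`` with n subjects and k
  raters.  Negative estimates are reported as computed, never clipped.
* **CoV** — per subject, the SD of the rater values (n-1 divisor) divided by
  their mean; reported as the across-subject mean, in percent.  (With two
  raters the per-subject SD reduces to |difference|/sqrt(2).)  An RMS
  pooling alternative is available.
* **Bland–Altman** — bias (mean rater1 - rater2 difference) and 95% limits
  of agreement bias +/- 1.96 SD(diff).

Group comparisons use conventional two-sided paired/two-sample t-tests,
Pearson correlation and one-way ANOVA (scipy implementations); significance
thresholds are a reporting-layer concern and are not applied here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RaterMatrix", "BlandAltman", "ReproResult",
    "icc_2k", "two_way_mean_squares", "cov_interobserver", "bland_altman",
    "paired_ttest", "two_sample_ttest", "pearson", "oneway_anova",
    "repro_result", "group_difference_report", "repro_report",
    "rater_matrix_from_tables", "bland_altman_plot",
]


@dataclass
class RaterMatrix:
    """A complete subjects x raters measurement grid."""

    values: np.ndarray  # (n_subjects, k_raters)
    subject_ids: tuple = ()
    rater_ids: tuple = ()
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x raters grid")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if not np.isfinite(self.values).all():
            raise ValueError("missing/non-finite cells are not allowed; "
                             "take the pairwise-complete subset upstream")
        if not self.subject_ids:
            self.subject_ids = tuple(range(n))
        if not self.rater_ids:
            self.rater_ids = tuple(range(k))
        if len(self.subject_ids) != n or len(self.rater_ids) != k:
            raise ValueError("id lengths must match the grid")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class ReproResult:
    """Interobserver statistics for one measurement."""

    icc: float
    cov_percent: float
    bland_altman: BlandAltman | None
    n_subjects: int
    mean_squares: dict = field(default_factory=dict)


def two_way_mean_squares(m: RaterMatrix) -> dict[str, float]:
    """Two-way ANOVA decomposition (rows = subjects, columns = raters)."""
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    return {
        "MSR": ssr / (n - 1),
        "MSC": ssc / (k - 1),
        "MSE": sse / ((n - 1) * (k - 1)),
        "SST": sst,
    }


def icc_2k(m: RaterMatrix) -> float:
    """Two-way random-effects, average-measures intraclass correlation."""
    ms = two_way_mean_squares(m)
    if ms["SST"] == 0:
        raise ValueError("zero total variance: ICC undefined")
    n = m.n_subjects
    denom = ms["MSR"] + (ms["MSC"] - ms["MSE"]) / n
    if denom == 0:
        raise ValueError("degenerate ANOVA decomposition: ICC undefined")
    return (ms["MSR"] - ms["MSE"]) / denom


def cov_interobserver(m: RaterMatrix, pooling: str = "mean") -> float:
    """Between-rater coefficient of variation, percent.

    Per subject: SD of the rater values (n-1 divisor) over their mean.
    ``pooling='mean'`` averages the per-subject CoVs; ``'rms'`` pools them
    as sqrt(mean CoV^2).
    """
    means = m.values.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("a subject mean is zero: CoV undefined")
    covs = m.values.std(axis=1, ddof=1) / np.abs(means)
    if pooling == "mean":
        return float(covs.mean()) * 100.0
    if pooling == "rms":
        return float(np.sqrt((covs ** 2).mean())) * 100.0
    raise ValueError(f"unknown pooling {pooling!r} (use 'mean' or 'rms')")


def bland_altman(m: RaterMatrix) -> BlandAltman:
    """Bias and 95% limits of agreement for exactly two raters
    (difference direction rater1 - rater2, fixed by column order)."""
    if m.n_raters != 2:
        raise ValueError("Bland-Altman analysis requires exactly 2 raters")
    diffs = m.values[:, 0] - m.values[:, 1]
    means = m.values.mean(axis=1)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                       loa_high=bias + 1.96 * sd, means=means, diffs=diffs)


# ---------------------------------------------------------------------------
# conventional tests (thin scipy wrappers with explicit degeneracy errors)

def paired_ttest(a, b) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length samples, n >= 2")
    d = a - b
    if np.all(d == d[0]) and d[0] == 0:
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def two_sample_ttest(a, b, equal_var: bool = True) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample t-test needs n >= 2 per group")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("Pearson correlation needs two equal-length samples")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def oneway_anova(*groups) -> tuple[float, float]:
    if len(groups) < 2 or any(np.asarray(g).size < 2 for g in groups):
        raise ValueError("one-way ANOVA needs >= 2 groups with n >= 2 each")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def repro_result(m: RaterMatrix) -> ReproResult:
    """Assemble the full interobserver summary for one measurement."""
    ms = two_way_mean_squares(m)
    ba = bland_altman(m) if m.n_raters == 2 else None
    return ReproResult(
        icc=icc_2k(m), cov_percent=cov_interobserver(m),
        bland_altman=ba, n_subjects=m.n_subjects,
        mean_squares={k: ms[k] for k in ("MSR", "MSC", "MSE")})


# ---------------------------------------------------------------------------
# tabular reports

def group_difference_report(
    table: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    subject_col: str = "subject",
    by: tuple[str, ...] = ("sequence", "roi"),
) -> pd.DataFrame:
    """Pairwise differences of group means with two-sample t-test p-values.

    One row per stratum (``by``) and ordered group pair; groups with fewer
    than 2 subjects are excluded with a warning.
    """
    rows = []
    for key, grp in table.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        samples = {}
        for gname, gdat in grp.groupby(group_col, sort=True):
            vals = gdat[value_col].to_numpy(dtype=float)
            if vals.size < 2:
                warnings.warn(
                    f"group {gname!r} in stratum {key} has fewer than 2 "
                    "subjects; excluded from pairwise comparison")
                continue
            samples[gname] = vals
        names = list(samples)
        for i, ga in enumerate(names):
            for gb in names[i + 1:]:
                t, p = two_sample_ttest(samples[ga], samples[gb])
                row = dict(zip(by, key))
                row.update({
                    "group_a": ga, "group_b": gb,
                    "mean_a": float(samples[ga].mean()),
                    "mean_b": float(samples[gb].mean()),
                    "mean_difference": float(samples[ga].mean()
                                             - samples[gb].mean()),
                    "t": t, "p": p,
                    "n_a": samples[ga].size, "n_b": samples[gb].size,
                })
                rows.append(row)
    columns = list(by) + ["group_a", "group_b", "mean_a", "mean_b",
                          "mean_difference", "t", "p", "n_a", "n_b"]
    return pd.DataFrame(rows, columns=columns)


def rater_matrix_from_tables(
    df_a: pd.DataFrame, df_b: pd.DataFrame,
    value_col: str = "value", subject_col: str = "subject",
    label: str = "", units: str = "",
) -> RaterMatrix:
    """Align two per-subject observer tables into a subjects x 2 matrix."""
    a = df_a.set_index(subject_col)[value_col]
    b = df_b.set_index(subject_col)[value_col]
    only_a = sorted(set(a.index) - set(b.index))
    only_b = sorted(set(b.index) - set(a.index))
    if only_a or only_b:
        raise ValueError(
            f"subject mismatch between observers: only in A {only_a}, "
            f"only in B {only_b}")
    subjects = sorted(a.index)
    values = np.column_stack([a.loc[subjects].to_numpy(dtype=float),
                              b.loc[subjects].to_numpy(dtype=float)])
    return RaterMatrix(values=values, subject_ids=tuple(subjects),
                       rater_ids=("A", "B"), label=label, units=units)


def repro_report(
    df_a: pd.DataFrame, df_b: pd.DataFrame,
    value_col: str = "value", subject_col: str = "subject",
    by: tuple[str, ...] = ("sequence", "roi"),
) -> pd.DataFrame:
    """Per-stratum interobserver grid: mean of the two observers, ICC (2 dp
    in the printed convention), CoV% and Bland–Altman bias/limits."""
    if df_a.empty or df_b.empty:
        raise ValueError("observer tables must be non-empty")
    keys_a = set(map(tuple, df_a[list(by)].drop_duplicates().to_numpy()))
    keys_b = set(map(tuple, df_b[list(by)].drop_duplicates().to_numpy()))
    if keys_a != keys_b:
        raise ValueError(f"stratum mismatch between observers: "
                         f"{sorted(keys_a ^ keys_b)}")
    rows = []
    ga = df_a.groupby(list(by), sort=True)
    gb = df_b.groupby(list(by), sort=True)
    for key in sorted(keys_a):
        sub_a = ga.get_group(key if len(by) > 1 else key[0])
        sub_b = gb.get_group(key if len(by) > 1 else key[0])
        m = rater_matrix_from_tables(sub_a, sub_b, value_col, subject_col)
        res = repro_result(m)
        row = dict(zip(by, key))
        row.update({
            "mean": float(m.values.mean()),
            "icc": res.icc,
            "cov_percent": res.cov_percent,
            "bias": res.bland_altman.bias,
            "loa_low": res.bland_altman.loa_low,
            "loa_high": res.bland_altman.loa_high,
            "n_subjects": res.n_subjects,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def bland_altman_plot(ba: BlandAltman, path, title: str = "",
                      units: str = "") -> None:
    """Write a Bland–Altman scatter with bias and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=18, color="tab:blue")
    for yval, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(yval, linestyle=style, color="tab:red", linewidth=1)
    ax.set_xlabel(f"mean of observers {f'({units})' if units else ''}".strip())
    ax.set_ylabel(f"difference A - B {f'({units})' if units else ''}".strip())
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
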