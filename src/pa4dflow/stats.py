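"""Longitudinal cohort statistics: paired pre/post comparisons with a
normality gate, unpaired group contrasts, and Spearman correlations at
baseline and on pre-to-post deltas.

The gating rule: Shapiro-Wilk on the paired differences at alpha 0.05;
normal differences get a paired t-test, non-normal ones a Wilcoxon
signed-rank test.  Welch's t-test serves unpaired group contrasts.  No
multiple-testing correction is applied; significance threshold 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import MetricsTable


@dataclass
class PairedSample:
    """Matched pre/post values for one metric across subjects."""

    subject_ids: Sequence[str]
    pre: np.ndarray
    post: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if len(self.pre) != len(self.post) or len(self.pre) != len(self.subject_ids):
            raise ValueError("pre, post and subject ids must have equal length")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")

    @property
    def differences(self) -> np.ndarray:
        return self.post - self.pre


@dataclass
class TestReport:
    test: str          # 'paired-t' | 'wilcoxon' | 'none'
    statistic: float
    p_value: float
    n: int
    significant: bool
    normal_differences: Optional[bool]
    shapiro_p: Optional[float]
    mean_difference: float


def paired_compare(sample: PairedSample, alpha: float = 0.05,
                   normality_alpha: float = 0.05) -> TestReport:
    """Pre/post comparison with a Shapiro-Wilk normality gate.

    Normally distributed differences -> paired t-test; otherwise Wilcoxon
    signed-rank.  Constant differences (zero variance) are degenerate: all-
    zero differences report no difference; a constant non-zero shift is
    reported as significant without a finite test statistic.
    """
    d = sample.differences
    n = len(d)
    if n < 3:
        raise ValueError("paired comparison needs at least 3 complete pairs")
    mean_d = float(np.mean(d))
    if np.allclose(d, d[0]):
        if np.allclose(d, 0):
            return TestReport("none", 0.0, 1.0, n, False, None, None, 0.0)
        # sd of differences is 0: the t statistic diverges; report directly
        return TestReport("constant-shift", np.inf, 0.0, n, True, None, None, mean_d)
    sw_stat, sw_p = sps.shapiro(d)
    normal = sw_p > normality_alpha
    if normal:
        t, p = sps.ttest_rel(sample.post, sample.pre)
        return TestReport("paired-t", float(t), float(p), n, bool(p < alpha),
                          True, float(sw_p), mean_d)
    w, p = sps.wilcoxon(sample.post, sample.pre)
    return TestReport("wilcoxon", float(w), float(p), n, bool(p < alpha),
                      False, float(sw_p), mean_d)


def welch_compare(x, y, alpha: float = 0.05) -> TestReport:
    """Welch's unequal-variance t-test for unpaired group contrasts."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return TestReport("welch-t", float(t), float(p), len(x) + len(y),
                      bool(p < alpha), None, None,
                      float(np.mean(y) - np.mean(x)))


def spearman_baseline(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, t-approximation p).

    Pools all observations; raises on constant input where ranks are
    undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("Spearman correlation needs at least 4 observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant input: rank correlation undefined")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def spearman_delta(pre_table: pd.DataFrame, post_table: pd.DataFrame,
                   metric_x: str, metric_y: str,
                   ) -> tuple[float, float, int]:
    """Spearman correlation of longitudinal changes (post - pre) between two
    metrics, matching subjects across timepoints.

    Tables need columns ``subject`` and one column per metric (wide format,
    e.g. from :func:`metrics_wide`).
    """
    pre = pre_table.set_index("subject")
    post = post_table.set_index("subject")
    common = pre.index.intersection(post.index)
    dx = (post.loc[common, metric_x] - pre.loc[common, metric_x]).astype(float)
    dy = (post.loc[common, metric_y] - pre.loc[common, metric_y]).astype(float)
    ok = dx.notna() & dy.notna()
    if int(ok.sum()) < 4:
        raise ValueError("need at least 4 matched subjects with both metrics")
    r, p = spearman_baseline(dx[ok].to_numpy(), dy[ok].to_numpy())
    return r, p, int(ok.sum())


def metrics_wide(table: MetricsTable, window: str = "cycle",
                 statistic: str = "mean") -> pd.DataFrame:
    """Pivot a long metrics table to one row per subject, columns
    '<branch>_<metric>', for one window/statistic combination."""
    df = table.df
    sel = df[(df["window"] == window) & (df["statistic"] == statistic)].copy()
    sel["colname"] = sel["branch"] + "_" + sel["metric"]
    wide = sel.pivot_table(index="subject", columns="colname", values="value",
                           aggfunc="first")
    return wide.reset_index()


def null_calibration(n_pairs: int = 20, n_reps: int = 1000, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Empirical type-I error of :func:`paired_compare` under the null.

    Simulates normal pre/post samples with no true difference and returns
    the fraction of replicates declared significant at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n_pairs)]
    hits = 0
    for _ in range(n_reps):
        pre = rng.normal(size=n_pairs)
        post = pre + rng.normal(size=n_pairs)
        rep = paired_compare(PairedSample(ids, pre, post), alpha=alpha)
        hits += int(rep.significant)
    return hits / n_reps
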