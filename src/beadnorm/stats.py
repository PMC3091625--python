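"""Per-probe inferential statistics for normalized expression matrices.

Implements the one-way ANOVA mean-square decomposition (MSQ_between,
MSQ_within and their F ratio with (k-1, N-k) degrees of freedom),
Benjamini-Hochberg FDR adjustment, empirical-Bayes moderated t-statistics
for pairwise group comparisons, and residual standard deviations from the
group-means fit.  All operations are vectorised over probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .io import SampleDesign

__all__ = [
    "AnovaTable",
    "ModeratedTTable",
    "group_msq",
    "f_test",
    "bh_adjust",
    "moderated_t",
    "residual_sd",
]


@dataclass
class AnovaTable:
    """Per-probe one-way ANOVA results.

    ``table`` columns: msq_between, msq_within, f_stat, p, p_adj; plus the
    shared degrees of freedom ``df1 = k - 1`` and ``df2 = N - k``.
    """

    table: pd.DataFrame
    df1: int
    df2: int

    @property
    def p_adj(self) -> pd.Series:
        return self.table["p_adj"]


@dataclass
class ModeratedTTable:
    """Moderated t results, one row per (probe, comparison).

    ``table`` columns: probe_id, comparison, log2_ratio, moderated_t, p,
    p_adj.  ``d0`` and ``s0_sq`` are the empirical-Bayes prior degrees of
    freedom and prior variance shared across probes.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float

    def for_comparison(self, comparison: str) -> pd.DataFrame:
        sel = self.table[self.table["comparison"] == comparison]
        if sel.empty:
            raise KeyError(f"unknown comparison {comparison!r}")
        return sel.set_index("probe_id")


def group_msq(values_by_group) -> tuple[float, float]:
    """Between- and within-group mean squares of a one-way layout.

    ``msq_between = sum_i n_i (xbar_i - xbar)^2 / (k - 1)`` and
    ``msq_within = sum_i sum_j (x_ij - xbar_i)^2 / (N - k)``.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    n_i = np.array([len(g) for g in groups])
    N = int(n_i.sum())
    if N == k:
        raise ValueError("no residual degrees of freedom (N == k)")
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    msq_between = float(np.sum(n_i * (means - grand) ** 2) / (k - 1))
    msq_within = float(
        sum(((g - m) ** 2).sum() for g, m in zip(groups, means)) / (N - k)
    )
    return msq_between, msq_within


def _group_matrix(matrix: pd.DataFrame, design: SampleDesign, groups=None):
    """Column indices per group, validated against the design."""
    design.check_samples(matrix.columns)
    use = groups if groups is not None else design.groups
    cols = {}
    for g in use:
        ids = [s for s in design.samples_in(g) if s in set(matrix.columns)]
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples in the matrix")
        cols[g] = [matrix.columns.get_loc(s) for s in ids]
    return cols


def f_test(matrix: pd.DataFrame, design: SampleDesign, groups=None) -> AnovaTable:
    """Per-probe one-way F-test across ``groups`` (default: all in design).

    Probes with zero within-group variance are retained: F is +inf (p = 0)
    when the between mean square is positive, and p = 1 when both mean
    squares vanish.
    """
    cols = _group_matrix(matrix, design, groups)
    X = matrix.to_numpy(float)
    k = len(cols)
    n_i = np.array([len(c) for c in cols.values()])
    N = int(n_i.sum())
    df1, df2 = k - 1, N - k
    if df1 < 1 or df2 < 1:
        raise ValueError("need k >= 2 groups and N > k observations")

    means = np.column_stack([X[:, c].mean(axis=1) for c in cols.values()])
    grand = sum(X[:, c].sum(axis=1) for c in cols.values()) / N
    ssb = (n_i[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = sum(
        ((X[:, c] - means[:, [i]]) ** 2).sum(axis=1)
        for i, c in enumerate(cols.values())
    )
    msq_between = ssb / df1
    msq_within = ssw / df2

    with np.errstate(divide="ignore", invalid="ignore"):
        f = msq_between / msq_within
        p = sps.f.sf(f, df1, df2)
    zero_within = msq_within == 0
    f = np.where(zero_within & (msq_between > 0), np.inf, f)
    p = np.where(zero_within & (msq_between > 0), 0.0, p)
    both_zero = zero_within & (msq_between == 0)
    f = np.where(both_zero, np.nan, f)
    p = np.where(both_zero, 1.0, p)

    table = pd.DataFrame(
        {
            "msq_between": msq_between,
            "msq_within": msq_within,
            "f_stat": f,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=matrix.index,
    )
    return AnovaTable(table=table, df1=df1, df2=df2)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/trigamma)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of ``log(s2)`` against the log-F
    distribution implied by the hierarchical model; returns ``(d0, s0_sq)``.
    ``d0 = inf`` (complete shrinkage) when the observed spread of log
    variances is no larger than expected from sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 >= 0)]
    if s2.size < 2:
        raise ValueError("cannot estimate variance prior from < 2 variances")
    med = np.median(s2)
    if med == 0:
        raise ValueError("more than half of the residual variances are zero")
    s2 = np.maximum(s2, 1e-5 * med)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (e.size - 1)
    excess = evar - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(s2.mean())
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_t(
    matrix: pd.DataFrame,
    design: SampleDesign,
    comparisons,
    d0_override: float | None = None,
) -> ModeratedTTable:
    """Empirical-Bayes moderated t for pairwise group comparisons.

    Fits the group-means linear model per probe, shrinks the residual
    variances toward a common prior ``(d0, s0^2)`` estimated by method of
    moments on the log variances, and tests each ``(test, reference)`` pair
    in ``comparisons`` with ``d0 + d_g`` degrees of freedom.  ``d0_override``
    forces the prior df (0 reproduces the ordinary t; inf gives complete
    shrinkage to ``s0``).
    """
    cols = _group_matrix(matrix, design)
    X = matrix.to_numpy(float)
    labels = list(cols)
    n_i = {g: len(c) for g, c in cols.items()}
    N = sum(n_i.values())
    k = len(labels)
    d_g = N - k
    if d_g < 1:
        raise ValueError("no residual degrees of freedom")

    means = {g: X[:, c].mean(axis=1) for g, c in cols.items()}
    ssr = sum(((X[:, c] - means[g][:, None]) ** 2).sum(axis=1)
              for g, c in cols.items())
    s2 = ssr / d_g

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    else:
        try:
            d0, s0_sq = estimate_variance_prior(s2, d_g)
        except ValueError:
            warnings.warn(
                "variance prior estimation failed; falling back to ordinary t",
                RuntimeWarning,
            )
            d0, s0_sq = 0.0, 1.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g) if d0 > 0 else s2
    # cap at the pooled residual df across probes (information actually seen)
    df_total = min(d0 + d_g, d_g * len(matrix))

    frames = []
    for test, ref in comparisons:
        if test not in cols or ref not in cols:
            raise ValueError(f"comparison ({test}, {ref}) not in design groups {labels}")
        lev = 1.0 / n_i[test] + 1.0 / n_i[ref]
        ratio = means[test] - means[ref]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = ratio / np.sqrt(s2_post * lev)
            p = 2.0 * sps.t.sf(np.abs(t), df_total)
        p = np.where(np.isnan(p) & (ratio == 0), 1.0, p)
        p = np.where(np.isnan(p) & (ratio != 0), 0.0, p)
        frames.append(pd.DataFrame({
            "probe_id": matrix.index,
            "comparison": f"{test}_vs_{ref}",
            "log2_ratio": ratio,
            "moderated_t": t,
            "p": p,
            "p_adj": bh_adjust(np.clip(p, 0.0, 1.0)),
        }))
    return ModeratedTTable(
        table=pd.concat(frames, ignore_index=True), d0=float(d0), s0_sq=float(s0_sq)
    )


def residual_sd(matrix: pd.DataFrame, design: SampleDesign, groups=None) -> pd.DataFrame:
    """Residual SD of the group-means fit plus mean and minimum expression.

    The residual SD uses ``N - k`` degrees of freedom, so its square is
    identically the within-group mean square of :func:`f_test`.
    """
    cols = _group_matrix(matrix, design, groups)
    X = matrix.to_numpy(float)
    used = [j for c in cols.values() for j in c]
    k = len(cols)
    N = len(used)
    if N <= k:
        raise ValueError("need N > k observations")
    ssr = sum(
        ((X[:, c] - X[:, c].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        for c in cols.values()
    )
    sd = np.sqrt(ssr / (N - k))
    sub = X[:, used]
    return pd.DataFrame(
        {"sd": sd, "mean_expr": sub.mean(axis=1), "min_expr": sub.min(axis=1)},
        index=matrix.index,
    )
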