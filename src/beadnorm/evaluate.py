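"""Quality measures, scoring rules and aggregation for pipeline comparison.

Each measure condenses one diagnostic view of a normalized expression
matrix — ECDF of FDR-corrected F-test p-values, MSQ distribution summaries,
volcano and residual-SD trends, replicate-scatter symmetry, pseudo-ROC AUC
against a known true-positive panel, and fold-change agreement with a
qRT-PCR-like reference (Pearson correlation and orthogonal regression).
Measure outcomes are mapped to integer quality scores in -2..2, collected
into a pipeline x measure matrix, summed per pipeline, and ordered by
hierarchical clustering (Manhattan distance, complete linkage).

Scores that printed rules exist for (correlation cut-offs, AUC bins of
sizes 5/18/2, slope cut points) are hard-coded defaults; the remaining
measures are scored by explicit rank-quintile rules so the historically
subjective step is reproducible, and any cell can be replaced through a
manual-override mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import pdist
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .io import ReferenceFoldChanges, SampleDesign
from .stats import AnovaTable, ModeratedTTable, group_msq

__all__ = [
    "MeasureResult",
    "EvalMatrix",
    "RocCurve",
    "OrthoFit",
    "fstat_cdf",
    "pvalue_vs_msq",
    "msq_summaries",
    "volcano_summary",
    "residual_sd_trend",
    "replicate_scatter_metrics",
    "pseudo_roc",
    "auc_bin_scores",
    "fc_correlation",
    "correlation_score",
    "orthogonal_regression",
    "slope_bin_scores",
    "quantile_bin_scores",
    "fold_changes_from_matrix",
    "aggregate",
]

#: cutoffs highlighted on the p-value ECDF
ECDF_HIGHLIGHTS = (0.02, 0.05)


@dataclass
class MeasureResult:
    """Score of one pipeline under one measure, with its raw summaries."""

    pipeline: str
    measure: str
    score: int
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -2 <= int(self.score) <= 2:
            raise ValueError(f"score {self.score} outside -2..2")
        for k, v in self.raw.items():
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValueError(f"non-finite raw summary {k}={v}")


@dataclass
class EvalMatrix:
    """Pipeline x measure quality-score table with sums and cluster orders."""

    scores: pd.DataFrame
    row_sums: pd.Series
    ranking: list[str]
    row_order: list[str]
    col_order: list[str]


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class OrthoFit:
    slope: float
    intercept: float
    residuals: np.ndarray

    @property
    def objective(self) -> float:
        """Sum of squared perpendicular distances to the fitted line."""
        return float(np.sum(self.residuals ** 2))


# ---------------------------------------------------------------------------
# Variance-oriented measures
# ---------------------------------------------------------------------------

def fstat_cdf(anova: AnovaTable, n_grid: int = 512) -> pd.DataFrame:
    """Empirical CDF of FDR-corrected F-test p-values on a fixed cutoff grid.

    The grid always contains the highlighted cutoffs 0.02 and 0.05.
    """
    p = anova.p_adj.to_numpy(float)
    if p.size == 0:
        raise ValueError("empty ANOVA table")
    grid = np.unique(np.concatenate([np.linspace(0.0, 1.0, n_grid),
                                     ECDF_HIGHLIGHTS]))
    frac = np.searchsorted(np.sort(p), grid, side="right") / p.size
    return pd.DataFrame({"cutoff": grid, "fraction": frac})


def pvalue_vs_msq(
    anova: AnovaTable,
    msq_cap: float = 5.0,
    span: float = 0.4,
    msq_low: float = 1.0,
    neglogp_high: float = 2.0,
) -> dict:
    """Scatter summary of -log10(p) against MSQ_between (MSQ_between <= cap).

    Returns the loess trend, the dispersion around it (median absolute
    residual), and the fraction of probes that combine low between-group
    variability with high significance — the pathology this view exposes.
    """
    if msq_cap <= 0:
        raise ValueError("msq_cap must be positive")
    t = anova.table
    sel = t[t["msq_between"] <= msq_cap]
    if len(sel) < 10:
        raise ValueError("fewer than 10 probes under the MSQ cap")
    x = sel["msq_between"].to_numpy(float)
    y = -np.log10(np.clip(sel["p"].to_numpy(float), 1e-300, None))
    if np.ptp(x) == 0:  # degenerate scatter: flat trend
        fitted = np.full_like(y, y.mean())
    else:
        fitted = _lowess(y, x, frac=span, it=1, return_sorted=False)
    resid = y - fitted
    return {
        "msq_between": x,
        "neg_log10_p": y,
        "trend": fitted,
        "dispersion": float(np.median(np.abs(resid))),
        "low_msq_high_p_fraction": float(
            np.mean((x <= msq_low) & (y >= neglogp_high))
        ),
    }


def _count_modes(values: np.ndarray, rel_floor: float = 0.01) -> int:
    """Modes of a Gaussian-kernel density (Silverman bandwidth).

    Local maxima below ``rel_floor`` of the global maximum are ignored.
    """
    if np.ptp(values) == 0:
        return 1
    kde = sps.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), 512)
    d = kde(grid)
    peaks = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:]) & (d[1:-1] >= rel_floor * d.max())
    inner = int(peaks.sum())
    # endpoints can carry a mode when the density is monotone there
    if d[0] > d[1] and d[0] >= rel_floor * d.max():
        inner += 1
    if d[-1] > d[-2] and d[-1] >= rel_floor * d.max():
        inner += 1
    return max(inner, 1)


def msq_summaries(
    anova: AnovaTable,
    benchmark_group_means=(6.0, 6.0, 7.0),
    benchmark_n: int = 4,
) -> dict:
    """Distribution summaries of MSQ_between and MSQ_within.

    The benchmark MSQ_between comes from artificial group means (default
    (6, 6, 7), four replicates each, i.e. a log2 ratio of 1 for the third
    group) computed through the same MSQ decomposition; MSQ_within values
    exceeding it count as outliers, and the mode count of the MSQ_within
    density flags bimodality.
    """
    bench, _ = group_msq([[m] * benchmark_n for m in benchmark_group_means])
    out = {"benchmark_msq_between": bench}
    for which in ("msq_between", "msq_within"):
        v = anova.table[which].to_numpy(float)
        q1, q2, q3 = np.percentile(v, [25, 50, 75])
        out[which] = {
            "q1": q1, "median": q2, "q3": q3, "iqr": q3 - q1,
            "n_above_benchmark": int((v > bench).sum()),
        }
    out["msq_within_modes"] = _count_modes(anova.table["msq_within"].to_numpy(float))
    return out


def volcano_summary(modt: ModeratedTTable, span: float = 0.5) -> dict:
    """Per-comparison volcano (-log10 p vs log2 ratio) trend summaries.

    ``asymmetry`` is the integrated absolute difference between the loess
    trends of the mirrored negative branch and the positive branch; a
    symmetric volcano scores ~0.
    """
    out: dict[str, dict] = {}
    for comp in modt.table["comparison"].unique():
        sub = modt.table[modt.table["comparison"] == comp]
        x = sub["log2_ratio"].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"constant log2 ratios for comparison {comp}")
        y = -np.log10(np.clip(sub["p"].to_numpy(float), 1e-300, None))
        fitted = _lowess(y, x, frac=span, it=1, return_sorted=False)
        dispersion = float(np.median(np.abs(y - fitted)))
        neg, pos = x < 0, x > 0
        if neg.sum() >= 5 and pos.sum() >= 5:
            hi = min((-x[neg]).max(), x[pos].max())
            grid = np.linspace(0.0, hi, 64)
            tn = _branch_trend(-x[neg], y[neg], grid, span)
            tp = _branch_trend(x[pos], y[pos], grid, span)
            asymmetry = float(np.mean(np.abs(tp - tn)))
        else:
            asymmetry = np.nan
        out[comp] = {"trend_x": x, "trend": fitted,
                     "dispersion": dispersion, "asymmetry": asymmetry}
    return out


def _branch_trend(x, y, grid, span):
    order = np.argsort(x)
    fit = _lowess(y[order], x[order], frac=span, it=1, return_sorted=True)
    return np.interp(grid, fit[:, 0], fit[:, 1])


def residual_sd_trend(sd_table: pd.DataFrame, n_bins: int = 10) -> dict:
    """Binned-median residual SD against mean and minimum expression.

    ``flatness`` is the ratio of the largest to the smallest binned-median
    SD: ~1 for homoscedastic data, large when the variance depends on
    intensity.
    """
    if len(sd_table) < 20:
        raise ValueError("need at least 20 probes")
    out = {}
    for axis in ("mean_expr", "min_expr"):
        x = sd_table[axis].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"degenerate intensity range on {axis}")
        sd = sd_table["sd"].to_numpy(float)
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
        med = np.array([np.median(sd[idx == b]) for b in range(n_bins)
                        if (idx == b).any()])
        lo = med.min()
        out[axis] = {
            "bin_median_sd": med,
            "flatness": float(med.max() / lo) if lo > 0 else np.inf,
        }
    out["flatness_mean"] = out["mean_expr"]["flatness"]
    out["flatness_min"] = out["min_expr"]["flatness"]
    return out


def replicate_scatter_metrics(matrix: pd.DataFrame, design: SampleDesign) -> dict:
    """Symmetry and spread of replicate-pair scatter about the diagonal.

    Per replicate pair: signed median of the paired differences (symmetry;
    0 when the cloud straddles the diagonal) and median absolute paired
    difference (spread).  Aggregates are means over all pairs.
    """
    rows = []
    for g in design.groups:
        samples = [s for s in design.samples_in(g) if s in set(matrix.columns)]
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                d = matrix[samples[i]].to_numpy(float) - matrix[samples[j]].to_numpy(float)
                rows.append((g, samples[i], samples[j],
                             float(np.median(d)), float(np.median(np.abs(d)))))
    if not rows:
        raise ValueError("no replicate pairs in the design")
    pairs = pd.DataFrame(rows, columns=["group", "a", "b", "symmetry", "spread"])
    return {
        "pairs": pairs,
        "mean_abs_symmetry": float(pairs["symmetry"].abs().mean()),
        "mean_spread": float(pairs["spread"].mean()),
    }


# ---------------------------------------------------------------------------
# Pseudo-ROC
# ---------------------------------------------------------------------------

def pseudo_roc(
    p_adj: pd.Series,
    tp_set,
    tn_pool=None,
    tn_sample_size: int | None = None,
    seed: int = 0,
) -> RocCurve:
    """ROC curve from known true positives and randomly sampled negatives.

    Thresholds sweep the observed adjusted p-values; TPR is the fraction of
    the TP panel called at each threshold and FPR the fraction of the
    sampled presumed negatives.  The AUC (trapezoid rule) equals the
    normalized Mann-Whitney statistic of the two p-value sets.  The
    negative sample defaults to ``20 * |TP|`` probes drawn reproducibly
    from everything outside the panel.
    """
    tp_set = list(tp_set)
    if not tp_set:
        raise ValueError("empty true-positive set")
    if tn_pool is None:
        tn_pool = [g for g in p_adj.index if g not in set(tp_set)]
    tn_pool = list(tn_pool)
    if set(tp_set) & set(tn_pool):
        raise ValueError("TP set and TN pool overlap")
    if tn_sample_size is None:
        tn_sample_size = min(20 * len(tp_set), len(tn_pool))
    if tn_sample_size > len(tn_pool):
        raise ValueError(
            f"tn_sample_size {tn_sample_size} exceeds pool size {len(tn_pool)}"
        )
    rng = np.random.default_rng(seed)
    tn_set = [tn_pool[i] for i in
              rng.choice(len(tn_pool), size=tn_sample_size, replace=False)]

    p_tp = p_adj.loc[tp_set].to_numpy(float)
    p_tn = p_adj.loc[tn_set].to_numpy(float)
    thresholds = np.unique(np.concatenate([p_tp, p_tn]))
    tpr = np.concatenate([[0.0], [np.mean(p_tp <= t) for t in thresholds]])
    fpr = np.concatenate([[0.0], [np.mean(p_tn <= t) for t in thresholds]])
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=np.concatenate([[-np.inf], thresholds]),
                    fpr=fpr, tpr=tpr, auc=auc)


def auc_bin_scores(
    auc_by_pipeline: dict[str, float],
    bin_sizes=(5, 18, 2),
    bin_scores=(-1, 0, 1),
) -> dict[str, int]:
    """Rank-based AUC scoring: sorted ascending into bins of 5/18/2 members
    scoring -1/0/+1.  Ties are broken by pipeline name (deterministic)."""
    if sum(bin_sizes) != len(auc_by_pipeline):
        raise ValueError(
            f"bin sizes {bin_sizes} do not sum to {len(auc_by_pipeline)} pipelines"
        )
    ordered = sorted(auc_by_pipeline, key=lambda k: (auc_by_pipeline[k], k))
    scores: dict[str, int] = {}
    pos = 0
    for size, sc in zip(bin_sizes, bin_scores):
        for name in ordered[pos:pos + size]:
            scores[name] = sc
        pos += size
    return scores


# ---------------------------------------------------------------------------
# Bias measures against the reference fold changes
# ---------------------------------------------------------------------------

def fold_changes_from_matrix(
    matrix: pd.DataFrame,
    design: SampleDesign,
    comparisons,
    genes,
    probe_map: dict[str, str] | None = None,
) -> ReferenceFoldChanges:
    """Mean log2 ratios for selected genes from a normalized matrix.

    ``probe_map`` translates gene ids to probe ids when they differ.
    """
    rows = []
    for gene in genes:
        probe = (probe_map or {}).get(gene, gene)
        if probe not in matrix.index:
            raise KeyError(f"gene {gene!r} (probe {probe!r}) absent from matrix")
        for test, ref in comparisons:
            t = matrix.loc[probe, design.samples_in(test)].mean()
            r = matrix.loc[probe, design.samples_in(ref)].mean()
            rows.append((gene, f"{test}_vs_{ref}", float(t - r)))
    return ReferenceFoldChanges(
        pd.DataFrame(rows, columns=["gene_id", "comparison", "log2_ratio"])
    )


def correlation_score(r: float) -> int:
    """Quality score for a fold-change Pearson correlation.

    2 for r >= 0.96, 1 on [0.94, 0.96), 0 on [0.92, 0.94), -1 on
    (0.90, 0.92), -2 for r <= 0.90.
    """
    if r >= 0.96:
        return 2
    if r >= 0.94:
        return 1
    if r >= 0.92:
        return 0
    if r > 0.90:
        return -1
    return -2


def fc_correlation(
    pipeline_fc: ReferenceFoldChanges, reference: ReferenceFoldChanges
) -> tuple[float, int]:
    """Pooled Pearson correlation of pipeline vs reference fold changes.

    Matches on (gene, comparison) across all comparisons jointly and scores
    the coefficient with :func:`correlation_score`.
    """
    merged = pipeline_fc.table.merge(
        reference.table, on=["gene_id", "comparison"],
        suffixes=("_pipeline", "_ref"), how="right",
    )
    unmatched = merged[merged["log2_ratio_pipeline"].isna()]
    if len(unmatched):
        raise ValueError(
            f"unmatched reference genes: {unmatched['gene_id'].unique().tolist()}"
        )
    if len(merged) < 3:
        raise ValueError("need at least 3 matched (gene, comparison) pairs")
    r = float(sps.pearsonr(merged["log2_ratio_pipeline"],
                           merged["log2_ratio_ref"]).statistic)
    return r, correlation_score(r)


def orthogonal_regression(x, y) -> OrthoFit:
    """Total least squares line through the (x, y) cloud.

    The slope is the direction of the first principal axis of the centered
    cloud; residuals are signed perpendicular distances, so the fit
    minimizes their sum of squares.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 matched points")
    xc, yc = x - x.mean(), y - y.mean()
    cov = np.cov(np.vstack([xc, yc]))
    if np.allclose(cov, 0):
        raise ValueError("zero variance in both coordinates")
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if abs(v[0]) < 1e-12:
        raise ValueError("degenerate (vertical) principal axis")
    slope = float(v[1] / v[0])
    intercept = float(y.mean() - slope * x.mean())
    residuals = (y - (intercept + slope * x)) / np.hypot(1.0, slope)
    return OrthoFit(slope=slope, intercept=intercept, residuals=residuals)


def slope_bin_scores(
    slopes_by_pipeline: dict[str, float], cut_points
) -> dict[str, int]:
    """Bin regression slopes into -2..2 by four ascending cut points.

    The historical cut points were read off visually; here they are explicit
    configuration.  Higher slopes never score lower.
    """
    cuts = list(cut_points)
    if len(cuts) != 4 or sorted(cuts) != cuts or len(set(cuts)) != 4:
        raise ValueError("cut_points must be 4 strictly increasing values")
    return {name: int(sum(s > c for c in cuts)) - 2
            for name, s in slopes_by_pipeline.items()}


def quantile_bin_scores(
    values_by_pipeline: dict[str, float], higher_is_better: bool = True
) -> dict[str, int]:
    """Rank-quintile scoring for measures without printed cut-offs.

    Pipelines are sorted (worst first, ties broken by name) and split into
    five near-equal bins scoring -2..2.
    """
    sign = 1.0 if higher_is_better else -1.0
    ordered = sorted(values_by_pipeline,
                     key=lambda k: (sign * values_by_pipeline[k], k))
    bins = np.array_split(np.arange(len(ordered)), 5)
    scores: dict[str, int] = {}
    for b, chunk in enumerate(bins):
        for i in chunk:
            scores[ordered[i]] = b - 2
    return scores


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate(
    results: list[MeasureResult],
    manual_overrides: dict[tuple[str, str], int] | None = None,
) -> EvalMatrix:
    """Collect measure scores into the pipeline x measure quality matrix.

    Row sums rank the pipelines (descending, names break ties); rows and
    columns are also ordered by hierarchical clustering with Manhattan
    distance and complete linkage.  Missing cells are filled with 0 after a
    warning; duplicates are an error.  ``manual_overrides`` maps
    (pipeline, measure) to a replacement score.
    """
    seen = set()
    for r in results:
        key = (r.pipeline, r.measure)
        if key in seen:
            raise ValueError(f"duplicate measure result for {key}")
        seen.add(key)
    pipelines = list(dict.fromkeys(r.pipeline for r in results))
    measures = list(dict.fromkeys(r.measure for r in results))
    scores = pd.DataFrame(np.nan, index=pipelines, columns=measures)
    for r in results:
        scores.at[r.pipeline, r.measure] = r.score
    for (p, m), v in (manual_overrides or {}).items():
        if not -2 <= int(v) <= 2:
            raise ValueError(f"override score {v} outside -2..2")
        scores.at[p, m] = int(v)
    if scores.isna().any().any():
        missing = [(p, m) for p in pipelines for m in measures
                   if pd.isna(scores.at[p, m])]
        warnings.warn(f"missing measure cells treated as 0: {missing}")
        scores = scores.fillna(0)
    scores = scores.astype(int)
    row_sums = scores.sum(axis=1)
    ranking = sorted(pipelines, key=lambda p: (-row_sums[p], p))

    def _cluster_order(frame: pd.DataFrame) -> list[str]:
        if len(frame) < 3:
            return list(frame.index)
        link = complete(pdist(frame.to_numpy(float), metric="cityblock"))
        return [frame.index[i] for i in leaves_list(link)]

    return EvalMatrix(
        scores=scores,
        row_sums=row_sums,
        ranking=ranking,
        row_order=_cluster_order(scores),
        col_order=_cluster_order(scores.T),
    )
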