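"""The pre-processing grid: background handling, transforms, normalizations.

Twenty-five named pipelines combine a background step (BeadStudio-style
subtraction of mean negative-control signal, or none), a positivity fix
(forcePos global shift or RMA-style background correction, needed because
background subtraction can yield negative intensities), a transformation
(log2 or a bead-variance-driven variance-stabilizing transform), and a
between-array normalization (quantile, robust spline, loess, vsn, or the
BeadStudio-style average / rank-invariant / cubic-spline methods applied on
the original scale and log2-transformed afterwards).

Pipeline names follow the grammar
``<background correction>_<transformation>_<normalization>`` for R-style
pipelines and ``<background normalization>_<normalization>`` for
BeadStudio-style ones, e.g. ``noBg_log_rsn`` or ``bg_cubicSpline``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.interpolate import PchipInterpolator
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .io import ControlProfile, ProbeProfileTable

__all__ = [
    "PipelineSpec",
    "PipelineError",
    "enumerate_pipelines",
    "parse_pipeline_name",
    "subtract_background",
    "force_positive",
    "rma_background",
    "log2_transform",
    "vst_transform",
    "quantile_normalize",
    "rsn_normalize",
    "loess_normalize",
    "vsn_normalize",
    "average_normalize",
    "rank_invariant_normalize",
    "cubic_spline_normalize",
    "run_pipeline",
]

_BEADSTUDIO_NORMS = ("average", "rankInvariant", "cubicSpline")
_R_NORMS = ("loess", "quantile", "rsn")


class PipelineError(RuntimeError):
    """A pre-processing stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineSpec:
    """One cell of the background x transformation x normalization grid."""

    background: str          # "bg" | "noBg"
    positivity: str          # "none" | "forcePos" | "rma"
    transform: str           # "log" | "vst" | "none"
    normalization: str       # "none" | quantile/rsn/loess/vsn | BeadStudio ones

    def __post_init__(self) -> None:
        if self.background not in ("bg", "noBg"):
            raise ValueError(f"bad background {self.background!r}")
        if self.positivity not in ("none", "forcePos", "rma"):
            raise ValueError(f"bad positivity {self.positivity!r}")
        if self.transform not in ("log", "vst", "none"):
            raise ValueError(f"bad transform {self.transform!r}")
        valid_norms = ("none", "vsn") + _R_NORMS + _BEADSTUDIO_NORMS
        if self.normalization not in valid_norms:
            raise ValueError(f"bad normalization {self.normalization!r}")
        if self.positivity != "none" and not (
            self.background == "bg" and self.transform == "log"
        ):
            raise ValueError(
                "positivity fixes apply only to background-corrected data "
                "before log2 (vst and vsn handle negative values themselves)"
            )

    @property
    def is_beadstudio(self) -> bool:
        return self.normalization in _BEADSTUDIO_NORMS

    @property
    def name(self) -> str:
        if self.normalization == "vsn":
            return f"{self.background}_vsn"
        if self.is_beadstudio:
            return f"{self.background}_{self.normalization}"
        if self.normalization == "none":
            return f"{self.background}_noNorm"
        if self.transform == "vst":
            return f"{self.background}_vst_{self.normalization}"
        if self.positivity != "none":
            return f"bg_{self.positivity}_log_{self.normalization}"
        return f"{self.background}_log_{self.normalization}"


def enumerate_pipelines() -> list[PipelineSpec]:
    """The 25 pipelines of the comparison grid, each name emitted once."""
    specs: list[PipelineSpec] = []
    for bgc in ("bg", "noBg"):
        pos = "forcePos" if bgc == "bg" else "none"  # auto-fix before log2
        specs.append(PipelineSpec(bgc, pos, "log", "none"))
    for bgc in ("bg", "noBg"):
        for norm in _BEADSTUDIO_NORMS:
            specs.append(PipelineSpec(bgc, "none", "none", norm))
    for bgc in ("bg", "noBg"):
        specs.append(PipelineSpec(bgc, "none", "none", "vsn"))
    for pos in ("forcePos", "rma"):
        for norm in _R_NORMS:
            specs.append(PipelineSpec("bg", pos, "log", norm))
    for norm in _R_NORMS:
        specs.append(PipelineSpec("bg", "none", "vst", norm))
    for norm in _R_NORMS:
        specs.append(PipelineSpec("noBg", "none", "log", norm))
    for norm in _R_NORMS:
        specs.append(PipelineSpec("noBg", "none", "vst", norm))
    assert len(specs) == 25 and len({s.name for s in specs}) == 25
    return specs


def parse_pipeline_name(name: str) -> PipelineSpec:
    """Inverse of :attr:`PipelineSpec.name` (bijective over the grid)."""
    parts = name.split("_")
    if len(parts) < 2 or parts[0] not in ("bg", "noBg"):
        raise ValueError(f"unparseable pipeline name {name!r}")
    bgc, rest = parts[0], parts[1:]
    if rest == ["noNorm"]:
        return PipelineSpec(bgc, "forcePos" if bgc == "bg" else "none", "log", "none")
    if rest == ["vsn"]:
        return PipelineSpec(bgc, "none", "none", "vsn")
    if len(rest) == 1 and rest[0] in _BEADSTUDIO_NORMS:
        return PipelineSpec(bgc, "none", "none", rest[0])
    if len(rest) == 2 and rest[0] in ("log", "vst") and rest[1] in _R_NORMS:
        return PipelineSpec(bgc, "none", rest[0], rest[1])
    if (
        len(rest) == 3
        and bgc == "bg"
        and rest[0] in ("forcePos", "rma")
        and rest[1] == "log"
        and rest[2] in _R_NORMS
    ):
        return PipelineSpec(bgc, rest[0], "log", rest[2])
    raise ValueError(f"unparseable pipeline name {name!r}")


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------

def subtract_background(
    profile: ProbeProfileTable, controls: ControlProfile
) -> ProbeProfileTable:
    """BeadStudio-style background normalization.

    Subtracts, per sample, the mean negative-control signal from every probe.
    The result may contain negative intensities; that is expected and legal.
    """
    missing = [s for s in profile.sample_ids if s not in set(controls.sample_ids)]
    if missing:
        raise ValueError(f"no negative controls for samples: {missing}")
    bg = controls.avg_signal[profile.sample_ids].mean(axis=0)
    return ProbeProfileTable(
        avg_signal=profile.avg_signal - bg,
        bead_stderr=profile.bead_stderr,
        n_beads=profile.n_beads,
        detection_p=profile.detection_p,
    )


def force_positive(matrix: pd.DataFrame) -> pd.DataFrame:
    """Global shift so the matrix minimum becomes 1 (identity if already >= 1).

    The shift is applied to the whole matrix, not per column, so every
    between-array difference is preserved exactly.
    """
    m = float(np.nanmin(matrix.values)) if matrix.size else 1.0
    if m < 1.0:
        return matrix + (1.0 - m)
    return matrix


def rma_background(matrix: pd.DataFrame) -> pd.DataFrame:
    """RMA-style background correction, one column at a time.

    Models each column as signal ~ Exponential(alpha) plus background
    ~ Normal(mu, sigma^2): mu is the kernel-density mode, sigma the RMS of
    values below the mode, alpha the reciprocal mean excess above it.  Each
    observation o is replaced by the posterior mean of the signal,
    ``a + b * phi(a/b) / Phi(a/b)`` with ``a = o - mu - sigma^2 * alpha`` and
    ``b = sigma``; the output is strictly positive.
    """
    out = matrix.copy().astype(float)
    for col in matrix.columns:
        x = matrix[col].to_numpy(float)
        if np.ptp(x) == 0:
            raise ValueError(f"constant column {col!r}: background model degenerate")
        kde = sps.gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), 512)
        mu = float(grid[np.argmax(kde(grid))])
        below = x[x < mu]
        sigma = float(np.sqrt(np.mean((below - mu) ** 2))) if below.size else np.std(x) / 10
        sigma = max(sigma, 1e-12)
        above = x[x > mu]
        alpha = 1.0 / float(np.mean(above - mu)) if above.size else 1.0
        a = x - mu - sigma * sigma * alpha
        z = a / sigma
        with np.errstate(divide="ignore", over="ignore"):
            post = a + sigma * sps.norm.pdf(z) / sps.norm.cdf(z)
        # Mills-ratio asymptote for deep-left-tail observations
        far = z < -30
        post[far] = sigma * sigma / (-a[far])
        out[col] = np.maximum(post, np.finfo(float).tiny)
    return out


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; rejects non-positive entries by name."""
    vals = matrix.values
    bad = ~(vals > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive intensity at probe {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r}; apply a positivity fix first"
        )
    return np.log2(matrix)


def _fit_vst_params(
    u: np.ndarray, v: np.ndarray, n_bins: int = 20
) -> tuple[float, float, float]:
    """Fit the bead variance-mean model v(u) = (c1*u + c2)^2 + c3.

    Robust two-stage fit: median bead-level variance within quantile bins of
    the mean signal, then least squares of the model against the binned
    medians on the log-variance scale (so the orders-of-magnitude span of v
    does not let the bright probes dominate).
    """
    order = np.argsort(u, kind="stable")
    bins = np.array_split(order, min(n_bins, max(3, u.size // 10)))
    bu = np.array([np.median(u[b]) for b in bins if len(b)])
    bv = np.maximum(
        np.array([np.median(v[b]) for b in bins if len(b)]), 1e-12
    )
    span = max(bu[-1] - bu[0], 1e-12)
    c1_0 = max(np.sqrt(max(bv[-1] - bv[0], 1e-12)) / span, 1e-8)
    theta0 = np.array([np.log(c1_0), -c1_0 * bu[0], np.log(bv[0])])

    def resid(theta):
        c1 = np.exp(theta[0])
        z = c1 * bu + theta[1]
        return np.log(z * z + np.exp(theta[2])) - np.log(bv)

    fit = optimize.least_squares(resid, theta0, method="lm", max_nfev=2000)
    c1 = float(np.exp(fit.x[0]))
    return max(c1, 1e-8), float(fit.x[1]), float(np.exp(fit.x[2]))


def vst_transform(
    profile: ProbeProfileTable, matrix: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Variance-stabilizing transform driven by bead-level replicate variance.

    Per sample, the bead-level variance ``stderr^2 * n_beads`` is regressed
    on the mean signal under ``v(u) = (c1*u + c2)^2 + c3``; the induced
    generalized-log transform ``log2(z + sqrt(z^2 + c3))`` with
    ``z = c1*x + c2`` is then applied.  It is strictly increasing, defined
    for negative intensities, and agrees with log2 up to an additive
    constant at high intensities.

    ``matrix`` lets callers transform e.g. background-subtracted intensities
    while the variance model is still fitted against the profile's bead
    statistics.
    """
    if profile.bead_stderr is None or profile.n_beads is None:
        raise ValueError(
            "vst needs bead_stderr and n_beads; use a log pipeline instead"
        )
    X = (matrix if matrix is not None else profile.avg_signal).astype(float)
    V = profile.bead_stderr.values ** 2 * profile.n_beads.values
    out = X.copy()
    for j, col in enumerate(X.columns):
        u = X[col].to_numpy(float)
        c1, c2, c3 = _fit_vst_params(u, V[:, j])
        c3 = max(c3, (1e-3 * (abs(c2) + 1.0)) ** 2)  # keep glog defined for z < 0
        z = c1 * u + c2
        out[col] = np.log2(z + np.sqrt(z * z + c3))
    return out


# ---------------------------------------------------------------------------
# Between-array normalizations (transformed scale)
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic sorted-mean quantile normalization.

    Afterwards every column shares the same sorted value multiset; tied
    values within a column receive the mean of the reference slots they span.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    A = matrix.to_numpy(float)
    order = np.argsort(A, axis=0, kind="stable")
    ref = np.take_along_axis(A, order, axis=0).mean(axis=1)
    out = np.empty_like(A)
    for j in range(A.shape[1]):
        assigned = np.empty(A.shape[0])
        assigned[order[:, j]] = ref
        s = pd.Series(assigned)
        out[:, j] = s.groupby(A[:, j]).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _monotone_map(x_anchor: np.ndarray, y_anchor: np.ndarray):
    """Monotone interpolating map through anchors with linear extrapolation."""
    x_anchor, keep = np.unique(x_anchor, return_index=True)
    y_anchor = np.maximum.accumulate(y_anchor[np.sort(keep)])
    if x_anchor.size < 2:
        c = y_anchor[0] - x_anchor[0]
        return lambda v: v + c
    interp = PchipInterpolator(x_anchor, y_anchor, extrapolate=False)
    lo_slope = (y_anchor[1] - y_anchor[0]) / (x_anchor[1] - x_anchor[0])
    hi_slope = (y_anchor[-1] - y_anchor[-2]) / (x_anchor[-1] - x_anchor[-2])

    def f(v):
        v = np.asarray(v, float)
        out = interp(v)
        low, high = v < x_anchor[0], v > x_anchor[-1]
        out[low] = y_anchor[0] + lo_slope * (v[low] - x_anchor[0])
        out[high] = y_anchor[-1] + hi_slope * (v[high] - x_anchor[-1])
        return out

    return f


def rsn_normalize(matrix: pd.DataFrame, n_anchors: int = 200) -> pd.DataFrame:
    """Robust spline normalization.

    The reference column is the one whose median is the median of column
    medians; every other column is mapped onto it through a monotone cubic
    spline fitted on matched quantile anchors, combining quantile-style
    distribution matching with a continuous, rank-preserving map.
    """
    if matrix.shape[1] < 2:
        raise ValueError("rsn needs >= 2 columns")
    A = matrix.to_numpy(float)
    medians = np.median(A, axis=0)
    ref_idx = int(np.argsort(medians, kind="stable")[(len(medians) - 1) // 2])
    q = np.linspace(0.0, 1.0, min(n_anchors, A.shape[0]))
    ref_anchors = np.quantile(A[:, ref_idx], q)
    out = A.copy()
    for j in range(A.shape[1]):
        if j == ref_idx:
            continue
        col_anchors = np.quantile(A[:, j], q)
        out[:, j] = _monotone_map(col_anchors, ref_anchors)(A[:, j])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def loess_normalize(
    matrix: pd.DataFrame, span: float = 0.4, iterations: int = 2
) -> pd.DataFrame:
    """MA-style loess normalization against the row-mean pseudo-reference.

    For each column, M = column - rowmean and A = (column + rowmean)/2; a
    loess trend of M on A is subtracted.  The procedure is repeated once
    with the refreshed pseudo-reference.
    """
    if matrix.shape[1] < 2:
        raise ValueError("loess normalization needs >= 2 columns")
    if matrix.shape[0] < 10:
        raise ValueError("too few probes for the loess smoother")
    X = matrix.to_numpy(float).copy()
    for _ in range(iterations):
        rowmean = X.mean(axis=1)
        for j in range(X.shape[1]):
            a = (X[:, j] + rowmean) / 2.0
            m = X[:, j] - rowmean
            delta = 0.01 * (a.max() - a.min())
            fitted = _lowess(m, a, frac=span, it=1, delta=delta,
                             return_sorted=False)
            X[:, j] = X[:, j] - fitted
    return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)


class VsnConvergenceError(RuntimeError):
    """vsn model fit failed; carries the objective trace."""

    def __init__(self, trace):
        super().__init__(f"vsn fit did not converge; objective trace: {trace}")
        self.trace = list(trace)


def vsn_normalize(
    matrix: pd.DataFrame,
    trim: float = 0.1,
    max_iter: int = 50,
    tol: float = 1e-8,
    fit_rows: int = 2000,
) -> pd.DataFrame:
    """Variance stabilization and normalization (affine calibration + glog).

    Per sample j an offset o_j and scale s_j are fitted and
    ``h_j(x) = arsinh((x - o_j)/s_j) / ln 2`` applied, putting every array on
    a common log2-like scale while damping additive noise at low
    intensities; negative inputs are handled naturally.  Parameters minimize
    a trimmed profile negative log-likelihood of the row-means model (rows
    with the largest residual variance are trimmed at fraction ``trim``).
    The fit is deterministic: rows used for fitting are an evenly spaced
    subsample of at most ``fit_rows`` rows.
    """
    if matrix.shape[1] < 2:
        raise ValueError("vsn needs >= 2 columns")
    X_full = matrix.to_numpy(float)
    n, p = X_full.shape
    idx = np.linspace(0, n - 1, min(fit_rows, n)).astype(int)
    X = X_full[np.unique(idx)]
    m = X.shape[0]

    o = np.quantile(X, 0.25, axis=0)
    iqr = np.quantile(X, 0.75, axis=0) - o
    s = np.maximum(iqr, 1e-6 * (np.abs(o) + 1.0))
    theta0 = np.concatenate([o, np.log(s)])
    n_keep = max(2, int(np.ceil((1.0 - trim) * m)))
    trace: list[float] = []

    def transformed(theta, rows):
        o_, s_ = theta[:p], np.exp(theta[p:])
        u = (rows - o_[None, :]) / s_[None, :]
        return u, np.arcsinh(u), s_

    def nll_grad(theta, rows):
        u, H, s_ = transformed(theta, rows)
        r = H - H.mean(axis=1, keepdims=True)
        rss = float((r * r).sum())
        w2 = 1.0 + u * u
        # -sum log h' = sum(log s + 0.5 log(1+u^2)) up to constants
        pen = rows.shape[0] * np.log(s_).sum() + 0.5 * np.log(w2).sum()
        mtot = rows.size
        rss_safe = max(rss, 1e-300)
        obj = 0.5 * mtot * np.log(rss_safe) + pen
        sqw = np.sqrt(w2)
        dH_do = -1.0 / (s_[None, :] * sqw)
        dH_dt = -u / sqw
        coef = mtot / rss_safe
        g_o = coef * (r * dH_do).sum(axis=0) + (-u / (s_[None, :] * w2)).sum(axis=0)
        g_t = coef * (r * dH_dt).sum(axis=0) + (1.0 / w2).sum(axis=0)
        return obj, np.concatenate([g_o, g_t])

    theta = theta0
    kept = np.arange(m)
    for _outer in range(3):
        rows = X[kept]
        res = optimize.minimize(
            nll_grad, theta, args=(rows,), jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol},
        )
        if not np.isfinite(res.fun):
            raise VsnConvergenceError(trace + [res.fun])
        theta = res.x
        trace.append(float(res.fun))
        _, H, _ = transformed(theta, X)
        row_rss = ((H - H.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        kept = np.argsort(row_rss, kind="stable")[:n_keep]

    o_, s_ = theta[:p], np.exp(theta[p:])
    out = np.arcsinh((X_full - o_[None, :]) / s_[None, :]) / np.log(2.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# BeadStudio-style normalizations (original scale)
# ---------------------------------------------------------------------------

def average_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each column so its mean equals the grand mean of column means."""
    means = matrix.mean(axis=0)
    if (means <= 0).any():
        bad = means.index[means <= 0].tolist()
        raise ValueError(f"non-positive column means: {bad}")
    return matrix * (means.mean() / means)


def rank_invariant_normalize(
    matrix: pd.DataFrame,
    rank_tolerance: float = 0.05,
    window: tuple[float, float] = (0.05, 0.95),
    min_invariant: int = 20,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Rank-invariant normalization against the mean-closest reference column.

    Probes whose rank differs from the reference rank by less than
    ``rank_tolerance * n_probes`` inside the mid-intensity rank ``window``
    form the invariant set; a monotone smooth of column-vs-reference fitted
    on that set maps all probes.
    """
    if matrix.shape[1] < 2:
        raise ValueError("rank-invariant normalization needs >= 2 columns")
    A = matrix.to_numpy(float)
    n = A.shape[0]
    means = A.mean(axis=0)
    ref_idx = int(np.argmin(np.abs(means - means.mean())))
    ref = A[:, ref_idx]
    ref_rank = sps.rankdata(ref, method="average")
    lo, hi = window[0] * n, window[1] * n
    out = A.copy()
    for j in range(A.shape[1]):
        if j == ref_idx:
            continue
        col = A[:, j]
        col_rank = sps.rankdata(col, method="average")
        inv = (
            (np.abs(col_rank - ref_rank) < rank_tolerance * n)
            & (ref_rank >= lo)
            & (ref_rank <= hi)
        )
        if inv.sum() < min_invariant:
            raise ValueError(
                f"invariant set for column {matrix.columns[j]!r} has only "
                f"{int(inv.sum())} probes; increase rank_tolerance"
            )
        x, y = col[inv], ref[inv]
        order = np.argsort(x, kind="stable")
        bins = np.array_split(order, min(n_bins, max(2, inv.sum() // 5)))
        bx = np.array([x[b].mean() for b in bins if len(b)])
        by = np.array([y[b].mean() for b in bins if len(b)])
        out[:, j] = _monotone_map(bx, by)(col)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def cubic_spline_normalize(matrix: pd.DataFrame, n_anchors: int = 100) -> pd.DataFrame:
    """Cubic-spline normalization through matched quantile anchors.

    ``n_anchors`` quantiles (equally spaced in rank) are computed per
    column; reference anchors are the geometric means across columns
    (arithmetic mean where any column's anchor is non-positive).  Each
    column is mapped through a monotone spline fitted on its anchor pairs,
    with linear extrapolation outside the anchor range.
    """
    if n_anchors > matrix.shape[0]:
        raise ValueError("more anchors than probes")
    A = matrix.to_numpy(float)
    q = np.linspace(0.0, 1.0, n_anchors)
    anchors = np.column_stack([np.quantile(A[:, j], q) for j in range(A.shape[1])])
    ref = np.empty(n_anchors)
    pos = (anchors > 0).all(axis=1)
    ref[pos] = np.exp(np.log(anchors[pos]).mean(axis=1))
    ref[~pos] = anchors[~pos].mean(axis=1)
    ref = np.maximum.accumulate(ref)
    out = A.copy()
    for j in range(A.shape[1]):
        out[:, j] = _monotone_map(anchors[:, j], ref)(A[:, j])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Pipeline execution
# ---------------------------------------------------------------------------

_NORM_FUNCS = {
    "quantile": quantile_normalize,
    "rsn": rsn_normalize,
    "loess": loess_normalize,
    "average": average_normalize,
    "rankInvariant": rank_invariant_normalize,
    "cubicSpline": cubic_spline_normalize,
}


def _stage(stage_name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {stage_name!r} failed: {exc}") from exc


def run_pipeline(
    spec: PipelineSpec,
    profile: ProbeProfileTable,
    controls: ControlProfile | None = None,
) -> pd.DataFrame:
    """Execute one named pipeline; output is always on a log2-like scale.

    Stage order is background -> positivity -> transform -> normalization
    for R-style pipelines.  BeadStudio-style pipelines normalize on the
    original scale and log2-transform afterwards (with an automatic
    force-positive shift when background subtraction left negatives, as the
    plain log pipelines also do for unnormalized data).
    """
    if isinstance(spec, str):
        spec = parse_pipeline_name(spec)
    if spec.background == "bg":
        if controls is None:
            raise ValueError(f"pipeline {spec.name} needs a negative-control profile")
        working = _stage("background", subtract_background, profile, controls)
    else:
        working = profile
    matrix = working.avg_signal.astype(float)

    if spec.normalization == "vsn":
        return _stage("vsn", vsn_normalize, matrix)

    if spec.is_beadstudio:
        matrix = _stage(spec.normalization, _NORM_FUNCS[spec.normalization], matrix)
        matrix = force_positive(matrix)
        return _stage("log2", log2_transform, matrix)

    if spec.positivity == "forcePos":
        matrix = _stage("forcePos", force_positive, matrix)
    elif spec.positivity == "rma":
        matrix = _stage("rma", rma_background, matrix)

    if spec.transform == "log":
        if spec.positivity == "none":
            matrix = force_positive(matrix)  # lumiT-style auto fix
        matrix = _stage("log2", log2_transform, matrix)
    elif spec.transform == "vst":
        matrix = _stage("vst", vst_transform, working, matrix)

    if spec.normalization == "none":
        return matrix
    return _stage(spec.normalization, _NORM_FUNCS[spec.normalization], matrix)
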