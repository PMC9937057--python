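"""Learning-curve modeling: standardization, exponential fits, features, QC.

Each participant's per-metric trial series ``I(t)`` is summarized by the
decreasing exponential ``f(t) = a + c*exp(-b*t)`` fitted by least squares
over the non-missing trials, with the rate constrained to ``b >= 0``.
Two quantities per metric feed the downstream prediction stage:

* ``a`` — the asymptotic performance level (the plateau of the decay), and
* ``e = c*exp(-b)`` — the learning feature, the curve's elevation above the
  plateau after the first trial, which summarizes how much and how fast the
  learner improves.

Because raw metric magnitudes span many orders (jerk vs. duration), all
series are z-scored per metric, pooled over every participant's training
trials, before fitting; transfer targets are z-scored across participants.
Pooled (rather than per-group) standardization keeps the groups on one
scale so their prediction errors stay comparable.

The optimizer profiles out the linear parameters (a, c) — for a fixed rate
``b`` they solve a 2x2 linear system — leaving a one-dimensional search over
``b >= 0`` on a coarse log grid refined by golden section. Missing values
are simply dropped from the objective, never imputed. A fit is flagged
non-converged when the optimizer runs down the ``b -> 0`` ridge (which
linear-trend-like, non-exponential series produce, sending ``|a|``, ``|c|``
above 1e6) or produces non-finite parameters; participants with any
non-converged metric are excluded from the feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .constants import (
    FEATURE_COLUMNS,
    METRICS,
    TARGET_COLUMNS,
    TARGET_METRICS,
    ConfigurationError,
)
from .groupstats import kruskal_wallis, mann_whitney_u

__all__ = [
    "MetricSeries",
    "ExpFit",
    "FeatureMatrix",
    "FitQCReport",
    "StandardizationParams",
    "standardize",
    "fit_exponential",
    "extract_features",
    "flag_divergent",
    "build_feature_matrix",
    "fit_qc",
]

logger = logging.getLogger(__name__)

#: Fits whose |a| or |c| exceed this are treated as divergent.
DIVERGENCE_BOUND = 1e6

_MIN_POINTS = 4

# coarse rate grid: log-spaced plus the conventional starting rates
_B_GRID = np.unique(
    np.concatenate([np.geomspace(1e-4, 20.0, 40), [0.01, 0.05, 0.2, 1.0]])
)


@dataclass(frozen=True)
class MetricSeries:
    """One participant's per-trial values of one metric over global index t."""

    participant: str
    metric: str
    t: np.ndarray
    values: np.ndarray  # nan marks a missing trial

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("t and values must be 1-D arrays of equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))

    @property
    def n_observed(self) -> int:
        return int(np.isfinite(self.values).sum())


@dataclass(frozen=True)
class ExpFit:
    """Fitted exponential parameters for one (participant, metric) series.

    ``e`` is always stored as exactly ``c*exp(-b)``; ``mse`` is the mean
    squared residual over the observed points.
    """

    a: float
    b: float
    c: float
    mse: float
    converged: bool
    n_points: int
    e: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "e", self.c * float(np.exp(-self.b)))


@dataclass(frozen=True)
class StandardizationParams:
    """Per-metric and per-target affine transforms, invertible."""

    metric_loc: Mapping[str, float]
    metric_scale: Mapping[str, float]
    target_loc: Mapping[str, float]
    target_scale: Mapping[str, float]

    def apply_series(self, series: MetricSeries) -> MetricSeries:
        loc = self.metric_loc[series.metric]
        scale = self.metric_scale[series.metric]
        return MetricSeries(
            series.participant, series.metric, series.t, (series.values - loc) / scale
        )

    def invert_series(self, series: MetricSeries) -> MetricSeries:
        loc = self.metric_loc[series.metric]
        scale = self.metric_scale[series.metric]
        return MetricSeries(
            series.participant, series.metric, series.t, series.values * scale + loc
        )


def standardize(
    series: Sequence[MetricSeries],
    transfer: pd.DataFrame | None = None,
) -> tuple[list[MetricSeries], pd.DataFrame | None, StandardizationParams]:
    """Z-score series per metric (pooled over participants) and targets per column.

    Returns the transformed series and transfer table together with the
    transform parameters so the mapping can be inverted. Missing markers are
    preserved. A metric with zero pooled SD is a configuration error.
    """
    metric_loc: dict[str, float] = {}
    metric_scale: dict[str, float] = {}
    by_metric: dict[str, list[np.ndarray]] = {}
    for s in series:
        by_metric.setdefault(s.metric, []).append(s.values)
    for m, chunks in by_metric.items():
        pooled = np.concatenate(chunks)
        pooled = pooled[np.isfinite(pooled)]
        if pooled.size == 0:
            raise ConfigurationError(f"metric {m}: no observed values to standardize")
        loc = float(pooled.mean())
        scale = float(pooled.std())
        if scale == 0:
            raise ConfigurationError(f"metric {m}: zero variance, cannot standardize")
        metric_loc[m] = loc
        metric_scale[m] = scale

    target_loc: dict[str, float] = {}
    target_scale: dict[str, float] = {}
    new_transfer = None
    if transfer is not None:
        new_transfer = transfer.copy()
        for col in TARGET_COLUMNS:
            if col not in transfer.columns:
                continue
            vals = transfer[col].to_numpy(dtype=float)
            loc = float(np.mean(vals))
            scale = float(np.std(vals))
            if scale == 0:
                raise ConfigurationError(f"target {col}: zero variance")
            target_loc[col] = loc
            target_scale[col] = scale
            new_transfer[col] = (vals - loc) / scale

    params = StandardizationParams(metric_loc, metric_scale, target_loc, target_scale)
    new_series = [params.apply_series(s) for s in series]
    return new_series, new_transfer, params


def fit_exponential(series: MetricSeries, tol: float = 1e-10) -> ExpFit:
    """Least-squares exponential fit over the observed points of one series.

    Requires at least 4 observed points. A constant series returns the
    ``a = mean, b = 0, c = 0`` convention with zero MSE. The fitted MSE
    never exceeds that of the best constant model (the constant model is a
    fallback candidate).
    """
    mask = np.isfinite(series.values)
    n = int(mask.sum())
    if n < _MIN_POINTS:
        raise ValueError(
            f"{series.participant}/{series.metric}: {n} observed points, "
            f"need >= {_MIN_POINTS} to fit"
        )
    tt = np.ascontiguousarray(series.t[mask], dtype=float)
    vv = np.ascontiguousarray(series.values[mask], dtype=float)

    var = float(np.var(vv))
    if var == 0.0:
        return ExpFit(a=float(vv[0]), b=0.0, c=0.0, mse=0.0, converged=True, n_points=n)

    a, b, c, sse = _kernels.fit_exp(tt, vv, _B_GRID, tol)
    mse = sse / n
    if var <= mse:  # optimizer never beats the flat model: take the convention
        return ExpFit(a=float(vv.mean()), b=0.0, c=0.0, mse=var, converged=True, n_points=n)
    converged = bool(
        np.isfinite([a, b, c, mse]).all()
        and max(abs(a), abs(c)) <= DIVERGENCE_BOUND
    )
    return ExpFit(a=float(a), b=float(b), c=float(c), mse=float(mse),
                  converged=converged, n_points=n)


def extract_features(fit: ExpFit) -> tuple[float, float]:
    """The (a, e) feature pair of a converged fit."""
    if not fit.converged:
        raise ValueError("cannot extract features from a non-converged fit")
    return fit.a, fit.e


def flag_divergent(fits: Mapping[str, ExpFit], participant: str = "?") -> bool:
    """True (keep) iff every metric's fit converged; logs the offending metric."""
    keep = True
    for m, f in fits.items():
        if not f.converged:
            logger.info("excluding %s: %s fit diverged", participant, m)
            keep = False
    return keep


@dataclass(frozen=True)
class FeatureMatrix:
    """The n x 8 design, three targets and group labels, aligned by row."""

    X: pd.DataFrame  # columns FEATURE_COLUMNS, index participant
    y: pd.DataFrame  # columns TARGET_COLUMNS
    groups: pd.Series

    @property
    def n(self) -> int:
        return len(self.X)

    def rows_for_group(self, group: str) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
        idx = self.groups[self.groups == group].index
        return (
            self.X.loc[idx].to_numpy(dtype=float),
            self.y.loc[idx],
            list(idx),
        )


def build_feature_matrix(
    fits_by_participant: Mapping[str, Mapping[str, ExpFit]],
    transfer: pd.DataFrame,
    groups: Mapping[str, str],
) -> FeatureMatrix:
    """Assemble the design matrix in fixed column order from converged fits.

    Only pass participants that survived `flag_divergent`; a missing or
    non-converged metric fit is an assembly error naming the participant.
    """
    if not fits_by_participant:
        raise ValueError("no participants left to assemble a feature matrix")
    tr = transfer.set_index("participant") if "participant" in transfer.columns else transfer
    rows = {}
    for pid, fits in fits_by_participant.items():
        row = {}
        for m in METRICS:
            if m not in fits:
                raise ValueError(f"participant {pid}: no fit for metric {m}")
            a, e = extract_features(fits[m])
            row[f"a_{m}"] = a
            row[f"e_{m}"] = e
        rows[pid] = row
    X = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_COLUMNS)]
    X.index.name = "participant"
    missing_targets = [p for p in X.index if p not in tr.index]
    if missing_targets:
        raise ValueError(f"no transfer targets for participants: {missing_targets}")
    y = tr.loc[X.index, list(TARGET_COLUMNS)].astype(float)
    grp = pd.Series({p: groups[p] for p in X.index}, name="group")
    return FeatureMatrix(X=X, y=y, groups=grp)


@dataclass(frozen=True)
class MetricFitQC:
    metric: str
    median_mse_complete: float | None
    median_mse_incomplete: float | None
    n_complete: int
    n_incomplete: int
    mw_u: float | None
    mw_p: float | None
    kw_h: float | None
    kw_p: float | None
    comparison_available: bool


@dataclass(frozen=True)
class FitQCReport:
    """Fit quality on complete vs incomplete tracks, per metric."""

    per_metric: tuple[MetricFitQC, ...]
    divergent: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "divergent_participants": list(self.divergent),
            "per_metric": [vars(m).copy() for m in self.per_metric],
        }


def fit_qc(
    fits_by_participant: Mapping[str, Mapping[str, ExpFit]],
    complete_by_participant: Mapping[str, Mapping[str, bool]],
    divergent: Iterable[str] = (),
) -> FitQCReport:
    """Compare fit MSE distributions between complete and incomplete tracks.

    Per metric: the median MSE of each subset plus Mann-Whitney and
    Kruskal-Wallis comparisons of the two MSE samples. With one subset
    empty the comparison is flagged unavailable.
    """
    out = []
    for m in METRICS:
        mse_c, mse_i = [], []
        for pid, fits in fits_by_participant.items():
            if m not in fits:
                continue
            (mse_c if complete_by_participant[pid][m] else mse_i).append(fits[m].mse)
        available = bool(mse_c and mse_i)
        if available:
            mw = mann_whitney_u(np.asarray(mse_c), np.asarray(mse_i))
            kw = kruskal_wallis([np.asarray(mse_c), np.asarray(mse_i)])
            mw_u, mw_p, kw_h, kw_p = mw.u, mw.p, kw.h, kw.p
        else:
            mw_u = mw_p = kw_h = kw_p = None
        out.append(
            MetricFitQC(
                metric=m,
                median_mse_complete=float(np.median(mse_c)) if mse_c else None,
                median_mse_incomplete=float(np.median(mse_i)) if mse_i else None,
                n_complete=len(mse_c),
                n_incomplete=len(mse_i),
                mw_u=mw_u,
                mw_p=mw_p,
                kw_h=kw_h,
                kw_p=kw_p,
                comparison_available=available,
            )
        )
    return FitQCReport(per_metric=tuple(out), divergent=tuple(divergent))
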