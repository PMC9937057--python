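"""End-to-end runner: simulate -> standardize -> fit -> predict -> compare.

`run_pipeline` executes the whole workflow on a synthetic cohort and writes
every intermediate artifact (CSV/JSON) plus a report whose numbers are all
regenerable from those artifacts. `simulate_prediction_errors` is the lean
path used by replication studies: it returns only the per-group squared
prediction errors for the requested groups and targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import GROUPS, METRICS, TARGET_METRICS
from .curves import (
    ExpFit,
    FeatureMatrix,
    FitQCReport,
    MetricSeries,
    build_feature_matrix,
    fit_exponential,
    fit_qc,
    flag_divergent,
    standardize,
)
from .groupstats import ComparisonTable, compare_prediction_stability
from .io import RunConfig, write_json
from .predict import (
    TwoStageConfig,
    TwoStageResult,
    _fit_and_predict,
    loo_two_stage,
    select_lambda,
    selection_summary,
)
from .synth import SyntheticDataset, generate_dataset

__all__ = [
    "RunReport",
    "run_pipeline",
    "fit_cohort",
    "predict_cohort",
    "simulate_prediction_errors",
]

logger = logging.getLogger(__name__)

_FAILED_FIT = ExpFit(a=np.nan, b=0.0, c=np.nan, mse=np.nan, converged=False, n_points=0)


def fit_cohort(
    series: Sequence[MetricSeries],
) -> tuple[dict[str, dict[str, ExpFit]], dict[str, dict[str, bool]]]:
    """Fit every (participant, metric) series; under-observed series count as
    failed fits. Returns fits and per-series completeness flags."""
    fits: dict[str, dict[str, ExpFit]] = {}
    complete: dict[str, dict[str, bool]] = {}
    for s in series:
        try:
            fit = fit_exponential(s)
        except ValueError:
            logger.warning("%s/%s: too few observed points to fit", s.participant, s.metric)
            fit = _FAILED_FIT
        fits.setdefault(s.participant, {})[s.metric] = fit
        complete.setdefault(s.participant, {})[s.metric] = s.complete
    return fits, complete


def exclude_divergent(
    fits: Mapping[str, Mapping[str, ExpFit]],
) -> tuple[dict[str, dict[str, ExpFit]], list[str]]:
    kept, dropped = {}, []
    for pid, f in fits.items():
        if flag_divergent(f, pid):
            kept[pid] = dict(f)
        else:
            dropped.append(pid)
    return kept, dropped


def predict_cohort(
    fm: FeatureMatrix,
    config: TwoStageConfig | None = None,
    groups: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
) -> dict[str, dict[str, TwoStageResult]]:
    """Per-group, per-target two-stage LOO; groups with n < 4 are skipped."""
    config = config or TwoStageConfig()
    groups = list(groups) if groups else [g for g in GROUPS if (fm.groups == g).any()]
    targets = list(targets) if targets else list(TARGET_METRICS)
    out: dict[str, dict[str, TwoStageResult]] = {}
    for g in groups:
        Xg, yg, ids = fm.rows_for_group(g)
        if len(ids) < 4:
            logger.warning("group %s: n=%d too small for LOO, skipped", g, len(ids))
            continue
        out[g] = {}
        for m in targets:
            out[g][m] = loo_two_stage(
                Xg,
                yg[f"y_{m}"].to_numpy(dtype=float),
                config,
                participant_ids=ids,
                group=g,
                target=m,
            )
    return out


def pooled_selection(
    fm: FeatureMatrix, config: TwoStageConfig | None = None
) -> dict[str, np.ndarray]:
    """Full-cohort lasso selection masks per target (selection-table analog)."""
    config = config or TwoStageConfig()
    X = fm.X.to_numpy(dtype=float)
    masks = {}
    for m in TARGET_METRICS:
        y = fm.y[f"y_{m}"].to_numpy(dtype=float)
        lam = select_lambda(X, y, config)
        _, mask = _fit_and_predict(X, y, X[0], lam, max_selected=len(y) - 2)
        masks[m] = mask
    return masks


@dataclass(frozen=True)
class RunReport:
    """Summary of one full synthetic run, mirroring the analysis outputs."""

    seed: int
    config_hash: str
    n_simulated: int
    n_analyzed: int
    excluded: tuple[str, ...]
    qc: FitQCReport
    median_se: Mapping[str, Mapping[str, float]]  # group -> target -> median SE
    selection_table: pd.DataFrame
    comparison: ComparisonTable

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_simulated": self.n_simulated,
            "n_analyzed": self.n_analyzed,
            "excluded": list(self.excluded),
            "fit_qc": self.qc.to_dict(),
            "median_se": {g: dict(t) for g, t in self.median_se.items()},
            "selection_table": {
                str(k): {str(c): int(v) for c, v in row.items()}
                for k, row in self.selection_table.iterrows()
            },
            "comparison": self.comparison.to_dict(),
        }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow; write artifacts if `config.out_dir` is set."""
    dataset = generate_dataset(
        config.protocol,
        config.prior,
        config.linkage(),
        point_rate=config.point_rate,
        block_rate=config.block_rate,
        seed=config.seed,
    )
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        dataset.scores_frame().to_csv(out_dir / "scores.csv", index=False)
        dataset.transfer_frame().to_csv(out_dir / "transfer.csv", index=False)
        write_json(dataset.truth(), out_dir / "truth.json")

    series = _dataset_series(dataset)
    std_series, std_transfer, _ = standardize(series, dataset.transfer_frame())
    fits, complete = fit_cohort(std_series)
    kept, dropped = exclude_divergent(fits)
    qc = fit_qc(fits, complete, divergent=dropped)
    fm = build_feature_matrix(kept, std_transfer, dataset.groups())

    results = predict_cohort(fm, config.two_stage)
    errors = {
        m: {g: results[g][m].errors for g in results if m in results[g]}
        for m in TARGET_METRICS
    }
    comparison = compare_prediction_stability(errors)
    sel_table = selection_summary(pooled_selection(fm, config.two_stage))
    median_se = {
        g: {m: results[g][m].median_se for m in results[g]} for g in results
    }

    if out_dir:
        fm.X.join(fm.groups).join(fm.y).to_csv(out_dir / "features.csv")
        write_json(qc.to_dict(), out_dir / "fit_qc.json")
        pd.concat(
            [results[g][m].errors_frame() for g in results for m in results[g]],
            ignore_index=True,
        ).to_csv(out_dir / "errors.csv", index=False)
        write_json(
            {
                "pooled": {
                    str(k): row.to_dict() for k, row in sel_table.iterrows()
                },
                "per_group": {
                    g: {
                        m: {
                            "mask": results[g][m].selection_mask,
                            "lambda": results[g][m].selection_lambda,
                        }
                        for m in results[g]
                    }
                    for g in results
                },
            },
            out_dir / "selection.json",
        )
        write_json(comparison.to_dict(), out_dir / "comparison.json")

    report = RunReport(
        seed=config.seed,
        config_hash=config.config_hash(),
        n_simulated=dataset.config.n_participants,
        n_analyzed=fm.n,
        excluded=tuple(sorted(dropped)),
        qc=qc,
        median_se=median_se,
        selection_table=sel_table,
        comparison=comparison,
    )
    if out_dir:
        write_json(report.to_dict(), out_dir / "report.json")
    return report


def _dataset_series(dataset: SyntheticDataset) -> list[MetricSeries]:
    series = []
    for p in dataset.participants:
        t = np.array(
            [s.global_index for s in p.schedule if s.route_label != "transfer"],
            dtype=float,
        )
        for m in METRICS:
            series.append(MetricSeries(p.participant, m, t, p.series[m]))
    return series


def simulate_prediction_errors(
    seed: int,
    linkage,
    config=None,
    prior=None,
    point_rate: float = 0.0025,
    block_rate: float = 0.25,
    groups: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
    two_stage: TwoStageConfig | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """One simulated cohort's per-group squared prediction errors.

    Runs generate -> standardize -> fit -> exclude -> predict for just the
    requested groups and targets and returns ``{target: {group: errors}}``.
    Restricting ``groups`` restricts the simulated cohort itself, which is
    what replication studies want for speed; standardization then pools
    over exactly the groups analyzed.
    """
    from .synth import ProtocolConfig

    config = config or ProtocolConfig()
    if groups:
        config = ProtocolConfig(
            n_sessions=config.n_sessions,
            control_trials_per_session=config.control_trials_per_session,
            variant_trials_per_session=config.variant_trials_per_session,
            group_sizes={g: config.group_sizes[g] for g in groups},
            sampling_rate=config.sampling_rate,
            seed=config.seed,
        )
    dataset = generate_dataset(
        config, prior, linkage, point_rate=point_rate, block_rate=block_rate, seed=seed
    )
    series = _dataset_series(dataset)
    std_series, std_transfer, _ = standardize(series, dataset.transfer_frame())
    fits, _ = fit_cohort(std_series)
    kept, _ = exclude_divergent(fits)
    fm = build_feature_matrix(kept, std_transfer, dataset.groups())
    results = predict_cohort(fm, two_stage, groups=groups, targets=targets)
    return {
        m: {g: results[g][m].errors for g in results if m in results[g]}
        for m in (targets or TARGET_METRICS)
    }
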