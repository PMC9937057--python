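"""Nonparametric comparison of per-group prediction-error distributions.

The practice-condition question is settled on distributions of per-sample
squared prediction errors (one SE per held-out participant): a
Kruskal-Wallis H-test across the three groups per target metric, followed
by pairwise two-sided Mann-Whitney U-tests for (VP1, VP2), (VP1, CP) and
(VP2, CP). These rank tests are the appropriate choice here because the
group sizes differ and squared errors are far from normal.

Conventions (the tests themselves come from scipy.stats behind this
surface): U is reported as min(U_ab, n_a*n_b - U_ab); p-values are exact by
enumeration for tie-free samples with n_a + n_b <= 16 and otherwise use the
tie-corrected normal approximation without continuity correction, so two
identical samples give p = 1 exactly. When every pooled value is identical
the comparison is degenerate and defined as U = n_a*n_b/2, H = 0, p = 1.
No multiple-testing correction is applied by default; `holm_adjust` is
available for callers who want one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import GROUPS

__all__ = [
    "MWResult",
    "KWResult",
    "ComparisonTable",
    "TargetComparison",
    "mann_whitney_u",
    "kruskal_wallis",
    "compare_prediction_stability",
    "holm_adjust",
]

#: Group pairs compared, in reporting order.
PAIRS = (("VP1", "VP2"), ("VP1", "CP"), ("VP2", "CP"))

_EXACT_MAX_N = 16


@dataclass(frozen=True)
class MWResult:
    u: float
    p: float
    method: str


@dataclass(frozen=True)
class KWResult:
    h: float
    df: int
    p: float


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    mode: str = "auto",
) -> MWResult:
    """Two-sided Mann-Whitney U test; U reported on the min convention.

    ``mode`` is "auto" (exact when tie-free and small, else normal
    approximation), "exact" or "asymptotic".
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return MWResult(u=n1 * n2 / 2.0, p=1.0, method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (not has_ties and n1 + n2 <= _EXACT_MAX_N) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    u1 = float(res.statistic)
    return MWResult(u=min(u1, n1 * n2 - u1), p=min(float(res.pvalue), 1.0), method=method)


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with df = k - 1 and chi-square p."""
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(s.size == 0 for s in arrays):
        raise ValueError("every group must be nonempty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return KWResult(h=0.0, df=df, p=1.0)
    h, p = stats.kruskal(*arrays)
    return KWResult(h=float(h), df=df, p=float(p))


@dataclass(frozen=True)
class TargetComparison:
    target: str
    medians: Mapping[str, float]
    kw: KWResult | None
    mw: Mapping[tuple[str, str], MWResult | None]


@dataclass(frozen=True)
class ComparisonTable:
    """KW + pairwise MW over per-group squared-error distributions."""

    rows: tuple[TargetComparison, ...]

    def to_frame(self) -> pd.DataFrame:
        """Pairwise p (U) per target, one pair per row."""
        recs = []
        for row in self.rows:
            for pair, res in row.mw.items():
                recs.append(
                    {
                        "pair": f"{pair[0]} vs {pair[1]}",
                        "target": row.target,
                        "p": res.p if res else np.nan,
                        "U": res.u if res else np.nan,
                    }
                )
        frame = pd.DataFrame(recs)
        return frame.pivot(index="pair", columns="target", values=["p", "U"])

    def to_dict(self) -> dict:
        out = {}
        for row in self.rows:
            out[row.target] = {
                "medians": dict(row.medians),
                "kw": vars(row.kw).copy() if row.kw else None,
                "mw": {
                    f"{p[0]} vs {p[1]}": (vars(r).copy() if r else None)
                    for p, r in row.mw.items()
                },
            }
        return out


def compare_prediction_stability(
    errors: Mapping[str, Mapping[str, Sequence[float]]],
    pairs: Sequence[tuple[str, str]] = PAIRS,
) -> ComparisonTable:
    """Full comparison table from per-target, per-group SE samples.

    ``errors[target][group]`` is the vector of per-participant squared
    errors. A pair with a group of fewer than 2 samples is flagged
    unavailable (None); the KW row needs every listed group nonempty.
    """
    rows = []
    for target, by_group in errors.items():
        groups_present = [g for g in GROUPS if g in by_group]
        samples = {g: np.asarray(by_group[g], dtype=float) for g in groups_present}
        medians = {g: float(np.median(s)) for g, s in samples.items() if s.size}
        kw = None
        if len(groups_present) >= 2 and all(samples[g].size > 0 for g in groups_present):
            kw = kruskal_wallis([samples[g] for g in groups_present])
        mw: dict[tuple[str, str], MWResult | None] = {}
        for ga, gb in pairs:
            if (
                ga in samples
                and gb in samples
                and samples[ga].size >= 2
                and samples[gb].size >= 2
            ):
                mw[(ga, gb)] = mann_whitney_u(samples[ga], samples[gb])
            else:
                mw[(ga, gb)] = None
        rows.append(TargetComparison(target=target, medians=medians, kw=kw, mw=mw))
    return ComparisonTable(rows=tuple(rows))


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (off by default in the pipeline report)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
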