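"""Synthetic cohorts with the climbing-practice protocol structure.

The training protocol being emulated: three practice groups — constant
practice (CP, n=9), imposed-variable practice (VP1, n=9) and self-controlled
variable practice (VP2, n=12) — each complete 10 sessions for a total of 84
training trials per participant (6 trials in sessions 1 and 10, 9 in
sessions 2–9), followed by a single never-practiced *transfer* trial. CP
climbs the fixed control route throughout; the variable groups climb the
control route on the first three trials of each session and variant routes
on the rest.

Each simulated learner carries, per fluency metric, a latent exponential
learning curve ``f(t) = a + c*exp(-b*t)`` over the global trial index ``t``
plus i.i.d. Gaussian trial noise. Missingness mimics the two failure modes
of the recording equipment: isolated random dropouts in every metric and
occasional whole-session voids for the jerk metric. The transfer score is
drawn as a linear function of the learner's true curve features
``(a, e = c*exp(-b))`` with a group-dependent residual SD — the
``vp2_advantage`` preset encodes the hypothesis that the self-controlled
group's learning dynamics predict transfer most reliably; the ``null``
preset gives every group the same residual SD.

Default missingness rates are calibrated so that, out of ~33 participants,
roughly 27 have complete tracks for most metrics but only ~20 for jerk,
which is what the session-block voids produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import (
    GROUPS,
    METRICS,
    TARGET_METRICS,
    FEATURE_COLUMNS,
    ROUTE_CONTROL,
    ROUTE_TRANSFER,
    ROUTE_VARIANT,
    ConfigurationError,
)
from .fluency import Trajectory

__all__ = [
    "ProtocolConfig",
    "TrialSlot",
    "LatentPrior",
    "LearnerLatent",
    "TransferLinkage",
    "ParticipantData",
    "SyntheticDataset",
    "build_schedule",
    "sample_learners",
    "generate_metric_series",
    "inject_missingness",
    "generate_transfer",
    "generate_trajectory",
    "generate_dataset",
]

_DEFAULT_VARIANT = (3, 6, 6, 6, 6, 6, 6, 6, 6, 3)


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol arithmetic: sessions, trials per session, group sizes."""

    n_sessions: int = 10
    control_trials_per_session: int = 3
    variant_trials_per_session: tuple[int, ...] = _DEFAULT_VARIANT
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"CP": 9, "VP1": 9, "VP2": 12}
    )
    sampling_rate: float = 25.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "variant_trials_per_session", tuple(self.variant_trials_per_session)
        )
        object.__setattr__(self, "group_sizes", dict(self.group_sizes))
        if self.n_sessions < 1:
            raise ConfigurationError("n_sessions must be >= 1")
        if len(self.variant_trials_per_session) != self.n_sessions:
            raise ConfigurationError(
                "variant_trials_per_session must list one count per session "
                f"(got {len(self.variant_trials_per_session)} for "
                f"{self.n_sessions} sessions)"
            )
        if self.control_trials_per_session < 0 or any(
            v < 0 for v in self.variant_trials_per_session
        ):
            raise ConfigurationError("trial counts must be non-negative")
        if self.n_training_trials <= 0:
            raise ConfigurationError("protocol defines no training trials")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ConfigurationError(f"unknown group labels: {sorted(unknown)}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigurationError("group sizes must be non-negative")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")

    @property
    def trials_per_session(self) -> tuple[int, ...]:
        return tuple(
            self.control_trials_per_session + v
            for v in self.variant_trials_per_session
        )

    @property
    def n_training_trials(self) -> int:
        return sum(self.trials_per_session)

    @property
    def n_participants(self) -> int:
        return sum(self.group_sizes.values())


@dataclass(frozen=True)
class TrialSlot:
    """One scheduled climb: its session, position, global index and route."""

    session: int  # 1-based
    within_session_index: int  # 1-based
    global_index: int  # 0-based over training trials; transfer gets T
    route_label: str


def build_schedule(config: ProtocolConfig, group: str) -> list[TrialSlot]:
    """Chronological trial slots for one participant of `group`.

    All groups share the per-session totals; CP's slots are all on the
    control route while VP1/VP2 climb the first ``control_trials_per_session``
    trials of each session on the control route and the rest on variants.
    The single transfer slot trails the training slots.
    """
    if group not in GROUPS:
        raise ConfigurationError(f"unknown group label: {group!r}")
    slots: list[TrialSlot] = []
    t = 0
    for s in range(1, config.n_sessions + 1):
        n_control = config.control_trials_per_session
        n_variant = config.variant_trials_per_session[s - 1]
        for k in range(1, n_control + n_variant + 1):
            if group == "CP" or k <= n_control:
                route = ROUTE_CONTROL
            else:
                route = ROUTE_VARIANT
            slots.append(TrialSlot(s, k, t, route))
            t += 1
    last = slots[-1]
    slots.append(
        TrialSlot(config.n_sessions, last.within_session_index + 1, t, ROUTE_TRANSFER)
    )
    return slots


def training_slots(schedule: Sequence[TrialSlot]) -> list[TrialSlot]:
    return [s for s in schedule if s.route_label != ROUTE_TRANSFER]


@dataclass(frozen=True)
class LatentPrior:
    """Population distribution of per-metric learning-curve latents.

    Units are standardized fluency units. ``a`` (asymptote) and the raw
    draws of ``b`` (per-trial learning rate) and ``c`` (initial elevation)
    are independent Gaussians; b and c are truncated at zero, as fluency
    indicators improve by decreasing. ``noise_sd`` is the trial-level
    Gaussian noise SD around the latent curve.
    """

    a_mean: float = -0.4
    a_sd: float = 0.3
    b_mean: float = 0.05
    b_sd: float = 0.03
    c_mean: float = 1.2
    c_sd: float = 0.3
    noise_sd: float = 0.25

    def __post_init__(self):
        for name in ("a_sd", "b_sd", "c_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LearnerLatent:
    """True per-metric curve parameters for one simulated learner."""

    group: str
    a: Mapping[str, float]
    b: Mapping[str, float]
    c: Mapping[str, float]
    noise_sd: Mapping[str, float]

    def true_features(self) -> np.ndarray:
        """True (a_m, e_m = c_m*exp(-b_m)) per metric, in design-column order."""
        out = []
        for m in METRICS:
            out.append(self.a[m])
            out.append(self.c[m] * np.exp(-self.b[m]))
        return np.asarray(out)


def _trunc_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Gaussian truncated at zero, by rejection (cheap for mild truncations)."""
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0.0:
            return float(x)
    return 0.0


def _sample_latent(group: str, prior: LatentPrior, rng: np.random.Generator) -> LearnerLatent:
    a = {m: float(rng.normal(prior.a_mean, prior.a_sd)) for m in METRICS}
    b = {m: _trunc_normal(prior.b_mean, prior.b_sd, rng) for m in METRICS}
    c = {m: _trunc_normal(prior.c_mean, prior.c_sd, rng) for m in METRICS}
    noise = {m: prior.noise_sd for m in METRICS}
    return LearnerLatent(group=group, a=a, b=b, c=c, noise_sd=noise)


def sample_learners(
    config: ProtocolConfig, prior: LatentPrior, rng: np.random.Generator
) -> list[LearnerLatent]:
    """Draw one latent per participant, groups in CP, VP1, VP2 order."""
    out = []
    for g in GROUPS:
        for _ in range(config.group_sizes.get(g, 0)):
            out.append(_sample_latent(g, prior, rng))
    return out


def generate_metric_series(
    latent: LearnerLatent,
    schedule: Sequence[TrialSlot],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Noisy latent curves over the training slots, one series per metric."""
    tr = training_slots(schedule)
    if not tr:
        raise ValueError("schedule has no training slots")
    t = np.array([s.global_index for s in tr], dtype=float)
    out = {}
    for m in METRICS:
        curve = latent.a[m] + latent.c[m] * np.exp(-latent.b[m] * t)
        noise = rng.normal(0.0, latent.noise_sd[m], size=len(t)) if latent.noise_sd[m] > 0 else 0.0
        out[m] = curve + noise
    return out


_MIN_SURVIVING = 4
_MAX_REDRAWS = 100


def inject_missingness(
    series: Mapping[str, np.ndarray],
    schedule: Sequence[TrialSlot],
    rng: np.random.Generator,
    point_rate: float = 0.0025,
    block_rate: float = 0.25,
    block_metric: str = "JE",
) -> dict[str, np.ndarray]:
    """Mark values missing (nan): isolated points everywhere, session blocks for jerk.

    Every metric loses points i.i.d. at ``point_rate``; with probability
    ``block_rate`` one whole session of ``block_metric`` values is voided.
    At least 4 points per metric survive: a pattern leaving fewer is
    redrawn, and if redraws keep failing (e.g. ``point_rate`` near 1) the
    last pattern is repaired by restoring random points down to the floor.
    """
    if not (0 <= point_rate <= 1 and 0 <= block_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    tr = training_slots(schedule)
    sessions = np.array([s.session for s in tr])
    out = {}
    for m, vals in series.items():
        vals = np.asarray(vals, dtype=float)
        n = len(vals)
        floor = min(_MIN_SURVIVING, n)
        for attempt in range(_MAX_REDRAWS):
            miss = rng.random(n) < point_rate
            if m == block_metric and block_rate > 0 and rng.random() < block_rate:
                sess = rng.choice(np.unique(sessions))
                miss |= sessions == sess
            if n - miss.sum() >= floor:
                break
        else:
            short = floor - (n - miss.sum())
            if short > 0:
                restore = rng.choice(np.flatnonzero(miss), size=short, replace=False)
                miss[restore] = False
        res = vals.copy()
        res[miss] = np.nan
        out[m] = res
    return out


@dataclass(frozen=True)
class TransferLinkage:
    """Linear link from true curve features to the transfer-trial targets.

    ``weights[target]`` is an 8-vector over the design columns
    (a_GE, e_GE, ..., e_CT); the target value is
    ``intercept + weights . features + N(0, residual_sd[group])``.
    """

    weights: Mapping[str, np.ndarray]
    intercepts: Mapping[str, float]
    residual_sd: Mapping[str, float]

    def __post_init__(self):
        w = {k: np.asarray(v, dtype=float) for k, v in self.weights.items()}
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "intercepts", dict(self.intercepts))
        object.__setattr__(self, "residual_sd", dict(self.residual_sd))
        for k, v in w.items():
            if v.shape != (len(FEATURE_COLUMNS),):
                raise ConfigurationError(
                    f"weights for {k} must have {len(FEATURE_COLUMNS)} entries"
                )
        if any(sd < 0 for sd in self.residual_sd.values()):
            raise ConfigurationError("residual_sd must be non-negative")

    @staticmethod
    def _own_metric_weights() -> dict[str, np.ndarray]:
        # each target loads on its own metric's asymptote and learning feature
        w = {}
        for m in TARGET_METRICS:
            v = np.zeros(len(FEATURE_COLUMNS))
            v[FEATURE_COLUMNS.index(f"a_{m}")] = 0.8
            v[FEATURE_COLUMNS.index(f"e_{m}")] = 0.5
            w[m] = v
        return w

    @classmethod
    def vp2_advantage(cls) -> "TransferLinkage":
        """Self-controlled practice yields the most predictable transfer."""
        return cls(
            weights=cls._own_metric_weights(),
            intercepts={m: 0.0 for m in TARGET_METRICS},
            residual_sd={"CP": 1.0, "VP1": 1.0, "VP2": 0.1},
        )

    @classmethod
    def null(cls, residual_sd: float = 1.0) -> "TransferLinkage":
        """No group differs: equal residual SD everywhere."""
        return cls(
            weights=cls._own_metric_weights(),
            intercepts={m: 0.0 for m in TARGET_METRICS},
            residual_sd={g: residual_sd for g in GROUPS},
        )


def generate_transfer(
    true_features: np.ndarray,
    linkage: TransferLinkage,
    group: str,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Transfer-trial target per metric: linear in features plus group noise."""
    x = np.asarray(true_features, dtype=float)
    out = {}
    for m in TARGET_METRICS:
        mean = linkage.intercepts[m] + float(linkage.weights[m] @ x)
        out[m] = mean + float(rng.normal(0.0, linkage.residual_sd[group]))
    return out


def generate_trajectory(
    duration: float,
    sampling_rate: float = 25.0,
    n_waypoints: int = 6,
    wobble_amplitude: float = 0.15,
    pause_fraction: float = 0.0,
    climb_height: float = 3.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Stylized climbing trajectory with known fluency properties.

    A monotone ascent of ``climb_height`` meters with sinusoidal lateral
    wobble (``n_waypoints`` full cycles of amplitude ``wobble_amplitude``),
    plus one stationary interval occupying ``pause_fraction`` of the trial.
    With zero wobble and no pause the result is a constant-velocity
    straight line (GE = 0, JE ~ 0, IM = 0); the pause is constructed so
    that the immobility ratio under central-difference speeds comes out at
    ``pause_fraction`` to within one sample.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    if not 0 <= pause_fraction < 1:
        raise ValueError("pause_fraction must lie in [0, 1)")
    rng = np.random.default_rng(0) if rng is None else rng
    n = int(round(duration * sampling_rate))
    if n < 8:
        raise ValueError("duration too short for the sampling rate")
    t = np.arange(n) / sampling_rate

    n_steps = n - 1
    # stationary samples s.t. central differences see round(pf*n) zero-speed samples
    k = int(round(pause_fraction * n)) + 1 if pause_fraction > 0 else 0
    if k and k > n_steps - 2:
        k = n_steps - 2
    active = np.ones(n_steps)
    if k:
        p0 = int(rng.integers(1, n_steps - k))
        active[p0 : p0 + k] = 0.0
    s = np.concatenate([[0.0], np.cumsum(active)])
    s /= s[-1]

    y = climb_height * s
    x = wobble_amplitude * np.sin(2.0 * np.pi * n_waypoints * s)
    return Trajectory(t=t, xy=np.column_stack([x, y]))


@dataclass(frozen=True)
class ParticipantData:
    participant: str
    group: str
    latent: LearnerLatent
    schedule: tuple[TrialSlot, ...]
    series: Mapping[str, np.ndarray]  # nan marks missing, training trials only
    transfer: Mapping[str, float]
    true_features: np.ndarray


@dataclass(frozen=True)
class SyntheticDataset:
    """A full simulated cohort plus the ground truth that produced it."""

    config: ProtocolConfig
    prior: LatentPrior
    linkage: TransferLinkage
    participants: tuple[ParticipantData, ...]

    def scores_frame(self):
        """Long-format per-trial scores (one row per training trial)."""
        import pandas as pd

        rows = []
        for p in self.participants:
            for i, slot in enumerate(training_slots(p.schedule)):
                row = {
                    "participant": p.participant,
                    "group": p.group,
                    "session": slot.session,
                    "trial": slot.within_session_index,
                    "global_index": slot.global_index,
                    "route": slot.route_label,
                }
                for m in METRICS:
                    row[m] = p.series[m][i]
                rows.append(row)
        return pd.DataFrame(rows)

    def transfer_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "participant": p.participant,
                    **{f"y_{m}": p.transfer[m] for m in TARGET_METRICS},
                }
                for p in self.participants
            ]
        )

    def groups(self) -> dict[str, str]:
        return {p.participant: p.group for p in self.participants}

    def truth(self) -> dict:
        """Ground-truth latents and features, for recovery tests."""
        out = {}
        for p in self.participants:
            out[p.participant] = {
                "group": p.group,
                "a": dict(p.latent.a),
                "b": dict(p.latent.b),
                "c": dict(p.latent.c),
                "noise_sd": dict(p.latent.noise_sd),
                "true_features": [float(v) for v in p.true_features],
                "transfer": {m: float(v) for m, v in p.transfer.items()},
            }
        return out


def generate_dataset(
    config: ProtocolConfig | None = None,
    prior: LatentPrior | None = None,
    linkage: TransferLinkage | None = None,
    point_rate: float = 0.0025,
    block_rate: float = 0.25,
    seed: int | None = None,
) -> SyntheticDataset:
    """Simulate a complete cohort under the protocol.

    The seed (``config.seed`` unless overridden) feeds one root
    ``SeedSequence`` that is spawned per participant, so enlarging the
    cohort never reshuffles the participants already generated.
    """
    config = config or ProtocolConfig()
    prior = prior or LatentPrior()
    linkage = linkage or TransferLinkage.vp2_advantage()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    n_total = config.n_participants
    children = root.spawn(n_total)

    participants = []
    idx = 0
    for g in GROUPS:
        for _ in range(config.group_sizes.get(g, 0)):
            rng = np.random.default_rng(children[idx])
            pid = f"P{idx + 1:02d}"
            latent = _sample_latent(g, prior, rng)
            schedule = tuple(build_schedule(config, g))
            clean = generate_metric_series(latent, schedule, rng)
            series = inject_missingness(
                clean, schedule, rng, point_rate=point_rate, block_rate=block_rate
            )
            feats = latent.true_features()
            transfer = generate_transfer(feats, linkage, g, rng)
            participants.append(
                ParticipantData(
                    participant=pid,
                    group=g,
                    latent=latent,
                    schedule=schedule,
                    series=series,
                    transfer=transfer,
                    true_features=feats,
                )
            )
            idx += 1
    return SyntheticDataset(
        config=config, prior=prior, linkage=linkage, participants=tuple(participants)
    )
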