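"""Shared labels and column orders for the climbing-fluency pipeline."""

#: Practice groups: constant practice, imposed-variable practice,
#: self-controlled variable practice.
GROUPS = ("CP", "VP1", "VP2")

#: Per-trial fluency metrics: geometric entropy (bits), dimensionless jerk,
#: immobility ratio (fraction), climb duration (seconds).
METRICS = ("GE", "JE", "IM", "CT")

#: Metrics whose transfer-trial value is predicted (CT is a feature only).
TARGET_METRICS = ("GE", "JE", "IM")

#: Fixed design-matrix column order: (asymptote a, learning feature e) per metric.
FEATURE_COLUMNS = ("a_GE", "e_GE", "a_JE", "e_JE", "a_IM", "e_IM", "a_CT", "e_CT")

#: Transfer-target columns aligned with TARGET_METRICS.
TARGET_COLUMNS = ("y_GE", "y_JE", "y_IM")

ROUTE_CONTROL = "control"
ROUTE_VARIANT = "variant"
ROUTE_TRANSFER = "transfer"


class ConfigurationError(ValueError):
    """Raised when a run or protocol configuration is internally inconsistent."""
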