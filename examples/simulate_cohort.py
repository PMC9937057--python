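"""Generate a synthetic practice cohort and look at its structure.

The default protocol: 30 climbers (CP 9, VP1 9, VP2 12), 84 training
trials over 10 sessions, each series following a noisy decreasing
exponential with occasional missing values, plus one transfer target per
fluency metric linked to the true curve features.
"""

import numpy as np

import climblearn as cl

dataset = cl.generate_dataset(seed=42)
scores = dataset.scores_frame()
transfer = dataset.transfer_frame()

print(f"participants: {len(dataset.participants)}")
print(f"trial rows:   {len(scores)} (= 30 x 84)")
print("per-session trial counts:",
      scores[scores.participant == 'P01'].groupby('session').size().tolist())
missing = scores[list(cl.METRICS)].isna().sum()
print("missing values per metric:")
print(missing.to_string())
print("\nfirst transfer targets (standardizable downstream):")
print(transfer.head(3).round(3).to_string(index=False))
print("\nJE loses whole sessions now and then (equipment voids), the other")
print("metrics only isolated points; targets are never missing.")
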