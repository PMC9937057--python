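# climblearn

Learning-curve dynamics of climbing fluency, and whether they predict
skill transfer under different practice schedules.

## The problem

Novice climbers train on an artificial wall under one of three practice
conditions — constant practice (CP: the same route every trial),
imposed-variable practice (VP1: routes changed by the instructor each
session), and self-controlled variable practice (VP2: the learner decides
when to change routes) — and finish with a single *transfer* trial on a
route nobody practiced. Each trial is summarized by four fluency scores
computed from the hip trajectory: geometric entropy **GE** (spatial
tortuosity, bits), dimensionless jerk **JE** (spatio-temporal smoothness),
immobility ratio **IM** (fraction of time stalled) and climb duration
**CT**. The question: under which practice condition do the *dynamics of
learning* — not just the final level — carry information about transfer?

The analysis chain, aimed at researchers in motor learning and movement
science working with small-n longitudinal designs:

1. **Fluency** — per-trial scores from hip trajectories:
   `GE = log2(2L/c)` (path length over convex-hull perimeter),
   `JE = ∫‖x‴‖²dt · T⁵/L²`, sub-threshold time fraction, duration.
2. **Curves** — per participant and metric, fit the exponential learning
   model `f(t) = a + c·e^{−b t}` (t = 0..83 training trials, least squares
   over non-missing trials, b ≥ 0) and keep two features: the plateau `a`
   and the learning feature `e = c·e^{−b}`.
3. **Predict** — per group and per target `y^I` (I ∈ {GE, JE, IM}),
   leave-one-out post-lasso OLS: an inner LOO picks the lasso penalty λ on
   each training fold, lasso selects among the 8 features
   (a/e × 4 metrics), OLS refits the selection, and the held-out squared
   error `err_pr = (ŷ − y)²` measures *prediction stability*.
4. **Groupstats** — Kruskal–Wallis (df = 2) and pairwise two-sided
   Mann–Whitney tests compare the groups' `err_pr` distributions per
   target.

Because behavioral datasets of this kind are typically not
redistributable, the package includes a first-class synthetic-cohort
generator with the protocol's exact structure (group sizes 9/9/12, 84
trials in 10 sessions, two realistic missingness modes, transfer targets
linearly linked to the true curve features with group-dependent noise), so
every stage is testable end to end, including ground-truth recovery.

## Worked example

```bash
python examples/run_full_pipeline.py
```

```
simulated 30, analyzed 27 (excluded for fit divergence: ['P08', 'P16', 'P30'])

per-group median squared prediction error:
  CP: GE=0.014, JE=6.753, IM=0.450
  VP1: GE=1.763, JE=0.328, IM=5.462
  VP2: GE=0.012, JE=0.154, IM=0.077
```

One synthetic cohort under the `vp2_advantage` preset (the transfer score
of self-controlled practitioners has a 10× smaller residual SD around its
link to the learning-curve features). Three participants' series had no
decreasing-exponential structure, their fits ran off the `b → 0` ridge and
they were excluded — the same accounting a real cohort goes through. In
the report, VP2's median `err_pr` is lowest for every target: its transfer
scores are the ones its learning dynamics can predict. Every number is
regenerable from the plain CSV/JSON artifacts written to `out/full_run/`,
and a rerun with the same seed reproduces them byte for byte.

The other scripts in `examples/` each demonstrate one capability
(trajectory scoring, curve fitting, two-stage prediction, group
comparison, cohort simulation). A thin CLI mirrors the pipeline stages:

```bash
climblearn simulate --seed 7 --out run/
climblearn fit --scores run/scores.csv --transfer run/transfer.csv \
    --out run/features.csv --qc run/fit_qc.json
climblearn predict --features run/features.csv --out-dir run/
climblearn compare --errors run/errors.csv --out run/comparison.json
```

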