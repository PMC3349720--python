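# intermotion

Bout-level analysis of **intermittent animal locomotion** — the stop-and-go
movement style in which displacement bouts ("moves") alternate with
stationary bouts ("pauses") and reorientation happens mostly while paused.
The package was built around the movement of isolated desert-locust nymphs
walking in an annular arena under minimal external cues, but the machinery
applies to any planar trajectory sampled on a fixed frame grid.

It is aimed at movement ecologists and behavioural biostatisticians who
want to go from raw `(t, x, y)` tables to:

* **move/pause discretization** — displacement > 0.3 cm per 0.2 s frame is
  a move transition; edge frames (within 3 cm of the arena walls) are
  censored; per-transition clockwise/anti-clockwise labels come from the
  cross product of successive position vectors;
* **reorientation statistics** — probability of changing direction after a
  pause as a function of pause length (log-binned, 95% CIs), within-bout
  "fidgeting" proportions, and the influence of each pause scale;
* **heavy-tailed bout-length laws** — binned maximum likelihood for five
  candidate families, including the Lévy-walk workhorse: a power law
  `p(x) ∝ x^(−μ)` on `[a, θ)` with a stretched-exponential tail
  `exp[−(x/θ)^β]` beyond the cut-off θ (β = 1 exponential, smaller β
  fatter); model comparison by Akaike weights and **sequential pointwise
  model comparison** (SPWMC) across truncation points; Poisson-band model
  criticism and a parametric-bootstrap G goodness-of-fit test;
* **sequence structure** — partial autocorrelation of move and pause
  series, move–pause cross-correlation with a shuffle null, adjacent
  move/pause pair correlations;
* **behavioural modes** — a Partial-Sums (CUSUM) segmentation of the
  signed bout series into *local search* (long exploratory pauses, short
  moves) and *relocation* (long moves, short resting pauses), with
  population mode-probability curves over the experiment;
* **a synthetic trajectory generator** that realises all of the above
  structure with a ground-truth ledger, so every estimator is testable
  end-to-end without any data download.

Analysis stages are exposed as scikit-learn-style estimators
(`BoutDiscretizer`, `BoutLawMLE`, `TurnCurveEstimator`,
`PartialSumsSegmenter`) with plain-function wrappers, plus an
`intermotion` CLI over a YAML config.

## Worked example

Recover the move-length law from simulated bout durations:

```python
import numpy as np
from intermotion import BoutLawMLE, sample_bout_lengths
from intermotion.synthetic import BoutLawParams

law = BoutLawParams(mu=1.49, beta=0.55, theta=8.0)   # generating truth
d = sample_bout_lengths(law, 20_000, np.random.default_rng(0))
est = BoutLawMLE(family="pl_stretched_tail", seed=0).fit(d)
print({k: round(v, 3) for k, v in est.params_.items()})
print("power-law span: %.2f decades" % np.log10(est.params_["theta"] / 0.2))
```

prints

```
{'mu': 1.495, 'beta': 0.544, 'theta': 7.388}
power-law span: 1.57 decades
```

i.e. the Lévy exponent μ, the tail stretch β and the tail onset θ are
recovered close to the generating values, and the power-law regime spans
more than 1.5 orders of magnitude above the 0.2 s frame floor.

A full trajectory round trip:

```python
from intermotion import GeneratorConfig, simulate_trajectory, BoutDiscretizer, turn_after_pause

cfg = GeneratorConfig(duration=7200.0, seed=42)       # one 2-h individual
traj = simulate_trajectory(cfg)
seq = BoutDiscretizer().transform(traj)
moves, pauses = seq.durations("move"), seq.durations("pause")
print(f"bouts: {len(seq.bouts)}  moves: {moves.size}  pauses: {pauses.size}")
d, turned = turn_after_pause(seq)
print(f"turn-after-pause rate: {turned.mean():.3f} over {turned.size} pauses")
```

prints

```
bouts: 136  moves: 67  pauses: 67
turn-after-pause rate: 0.197 over 66 pauses
```

(66 of the 67 pauses are flanked by moves on both sides; about a fifth of
them end in a direction change, consistent with the short-pause regime of
the configured turn curve.)

The same stages run from the shell:

```bash
intermotion all --config run.yaml --outdir results/run1
```

writing trajectory/bout CSVs, fit JSONs, curve CSVs and a reproducibility
manifest per stage.

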