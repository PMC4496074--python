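# cogmaze

Exploration-based cognitive-bias analytics for mice. The package
implements, end to end, the analysis pipeline of an eight-arm
radial-maze judgement-bias study:

* **`cogmaze.maze`** — maze geometry, arm roles (positive / negative /
  near-positive / near-negative) and the session contingency engine
  (overhead light, white noise, pellet dispenser) as a pure,
  replayable transition function over timestamped events.
* **`cogmaze.tracking`** — tracking CSVs → zone assignment → arm
  visits and maze events, per-trial QC (not-found / skipped < 1%),
  and running speed.
* **`cogmaze.scoring`** — per-session occupancy and entry metrics plus
  the three difference-over-sum arm-preference scores (reference,
  positive, near-positive).
* **`cogmaze.ethogram`** — home-cage observation scheduling (first
  5 min of every 20-min interval, 30-s one-zero slots), stereotypy
  bout classification (≥10 s for bar-mouthing, ≥3 repetitions for
  twirling/flipping, ≤3 s pauses), and one-zero scoring with the
  activity / stereotypy-level summaries.
* **`cogmaze.simulate`** — a synthetic cohort generator with known
  ground truth: a semi-Markov maze agent (valence bias, ambiguity
  aversion, learning), alternating-renewal home-cage streams with
  planted stereotypy bouts, and a lightweight outcome-table generator
  for statistical calibration experiments.
* **`cogmaze.stats`** — linear mixed models (handling fixed effect,
  litter/cage random intercepts as crossed variance components,
  square-root stereotypy covariate) with Satterthwaite denominator
  df, Bonferroni-corrected paired t-tests, and the Kruskal–Wallis
  stereotypy-form comparison.
* **`cogmaze.pipeline`** — study orchestration (simulate → QC →
  visits → scores → ethogram → stats → tidy CSV bundle) behind a CLI.

## CLI

```bash
# simulate a cohort's raw data (tracks, behaviour streams, manifest)
cogmaze simulate --seed 1 --n-mice 24 --out data/

# score tracking CSVs into a tidy per-session table
cogmaze score --tracks data/tracks --out sessions.csv

# one-zero summaries from behaviour streams
cogmaze ethogram --streams data/streams/homecage.csv --out homecage.csv

# mixed-model fits from the scored tables
cogmaze stats --sessions sessions.csv --manifest data/manifest.csv \
              --homecage homecage.csv --out fits.csv

# or the whole study in one go
cogmaze run-all --seed 1 --out results/
```

`run-all` accepts a YAML config (`--config study.yaml`) covering the
maze geometry, cohort parameters, observation design, QC policy and
seeds; runs are deterministic given the config.

## File formats

All I/O is plain CSV/YAML. Tracks: `time_s, x_cm, y_cm, detected,
skipped`. Behaviour streams: `mouse_id, behaviour, start_s, end_s`.
Visits, events, session metrics and model results are tidy CSVs with
documented columns (see module docstrings).
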