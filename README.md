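# pirogue

Fishing-event detection in small-scale fishery GPS tracks.

`pirogue` turns raw GPS trip recordings from small motorized fishing boats
into per-interval behavioral labels (*fishing* vs *non-fishing*) using a
two-state hidden Markov model with gamma-distributed step lengths and von
Mises-distributed turning angles.  It bundles:

- **trackio** — GPX 1.1 / CSV trip reading and writing, landing sites, trip
  summaries (duration, great-circle distance).
- **preprocess** — landing-site buffer (3 km), speed filter (50 km/h),
  constant-speed great-circle regularization to a fixed interval (5 s),
  decimation to coarser grids, and derivation of the step/turning-angle
  observation series.
- **hmm_core** — forward-algorithm likelihood, direct maximum-likelihood
  fitting (quasi-Newton on an unconstrained reparameterization with
  jittered restarts), Viterbi decoding, one-step-ahead pseudo-residuals,
  and moment-based initialization from reference-labeled data.
- **synthetic_data** — a calibrated generator of labeled trips for seven
  gear archetypes (sardine/mullet circling gillnets, surface drifting
  gillnet, purse seine, handline, longline, bottom gillnet), including a
  99-trip default fleet, plus track corruption (spikes, gaps) for testing
  the cleaning rules.
- **evaluation** — a 7 km/h speed-threshold surrogate labeler,
  confusion-matrix measures (accuracy, sensitivity, specificity,
  fishing/non-fishing predictive values), median/MAD aggregation across
  gears, percent-time-fishing, and a sampling-interval degradation sweep
  (10 s – 10 min).
- **cli** — `pirogue` command with subcommands `simulate`, `preprocess`,
  `fit`, `decode`, `evaluate`, `sweep` and the composite `run`.

## CLI quick start

```sh
# generate a small labeled synthetic fleet
pirogue simulate --seed 1 --counts '{"PS": 3, "HL": 3}' --out tracks.csv

# fit one HMM per gear, seeded from the labels in the CSV
pirogue fit --tracks tracks.csv --params-out params.yaml --n-restarts 1

# decode and score against the truth labels
pirogue decode --tracks tracks.csv --params params.yaml --out decoded.csv
pirogue evaluate --truth tracks.csv --pred decoded.csv --out metrics.csv

# composite pipeline (simulate -> fit -> decode -> evaluate)
pirogue run --seed 1 --out-dir out/

# sampling-interval degradation experiment
pirogue sweep --seed 1 --counts '{"PS": 2}' --intervals 10,60,120 --out sweep.csv
```

`pirogue run` also accepts a YAML config (`--config cfg.yaml`) whose keys
mirror `pirogue.cli.RunConfig`; flags override the file.  All outputs are
reproducible bit-for-bit from the same config and seed.

## Notes

- All geodesy is haversine arithmetic on a 6,371 km sphere; turning angles
  are left-positive in (−π, π].
- Gear calibration numbers live in `src/pirogue/profiles.yaml`; values not
  anchored to published trip statistics are labeled assumptions there.
- Zero-length steps and observations inside recording gaps are treated as
  missing (likelihood factor 1), never as data.
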