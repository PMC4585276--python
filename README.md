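# locomep

Modular surface-EMG analysis and predictive modelling of muscle excitation
profiles (MEPs) for treadmill locomotion across speeds (1–5 km/h) and
ground elevations (−20 to +20 %).

The package implements a complete descriptive-to-predictive pipeline:

1. **`emg_processing`** — zero-phase Butterworth band-pass (30–300 Hz),
   rectification and 3 Hz low-pass envelopes; amplitude normalization by
   the cross-trial peak of a 50 ms moving average; marker-based heel-strike
   detection; cubic-spline time normalization of each gait cycle onto 200
   points.
2. **`factorization`** — motor-component extraction by multiplicative-update
   NNMF with random restarts, VAF = 1 − SSE/TSS dimensionality selection
   (threshold 85 %), factor averaging/normalization with product-preserving
   weighting rescale, and peak-time component matching.
3. **`primitives`** — Gaussian excitation primitives (XPs) fitted to the
   normalized factors, with an optional second lobe for bimodal components
   and circular-mean averaging into a generic primitive set.
4. **`weighting_model`** — additive speed/elevation regression
   `W(v, θ) = Δv(v) + Δθ(θ) + W_BL` with per-muscle/component zero-intercept
   polynomials (degree ≤ 2, chosen by adjusted R²) anchored at the baseline
   condition (3 km/h, 0 %).
5. **`predictor`** — end-to-end MEP prediction `mep = W · XP(t)` in
   subject-generic (SGM) and subject-specific (SSM) modes, plus the two
   train/test scenarios (scenario 1: 3×3 condition training grid, 16
   held-out test conditions; scenario 2: full 5×5 grid).
6. **`evaluation`** — shift-compensated circular cross-correlation, time
   shift in % gait cycle, RMSE, per-component weighting similarity, and
   median/IQR/histogram summaries.
7. **`synthetic_data`** — a ground-truth generator producing datasets with
   exactly the modular structure the model assumes (4 primitives, additive
   weighting trends, cycle jitter, envelope noise, subject effects), used
   for validation of every stage; includes a raw-EMG emission mode.
8. **`cli_io`** — delimited-text trial/marker formats, versioned JSON model
   bundles, and the `locomep` command-line interface.

## CLI

```sh
# generate a synthetic dataset on disk (deterministic per seed)
locomep simulate --seed 7 --out data/

# extract motor components from one or more trial files
locomep extract data/s00_v3_e0.csv --restarts 50 --out components.json

# fit the predictive model (scenario 1 or 2) and predict a condition
locomep fit --scenario 1 --seed 7 --out model.json
locomep predict --model model.json --speed 4 --elevation 10 \
    --mode sgm --out mep.csv
# subject-specific mode needs a baseline weighting matrix (muscles x k CSV)
locomep predict --model model.json --speed 4 --elevation 10 \
    --mode ssm --baseline baseline.csv --out mep_ssm.csv

# compare two MEP matrices / run a full replication scenario
locomep evaluate --predicted mep.csv --reference ref.csv --out metrics.csv
locomep scenario --scenario 1 --seed 7 --restarts 10 --out run/
```

`scenario` writes the fitted model plus three metric tables
(`xp_metrics.csv`, `weighting_metrics.csv`, `mep_metrics.csv`: per-case
correlation, time shift in % gait cycle where applicable, and RMSE) and a
`summary.json` with the medians.

Trial files are delimited text (comma or tab) with a metadata line
`# fs=<Hz> speed=<km/h> elevation=<%>`, a muscle-label header row, and one
sample per line. Models are versioned JSON bundles; all writes are atomic.

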