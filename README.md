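# sepsishorizon

Early-warning sepsis prediction from irregular ICU event streams, with
channel-level Shapley explanations.

Intensive-care databases record vitals and laboratory results as timed
events — minutes since admission, at irregular, per-variable rates.  This
package turns such streams into fixed hourly matrices ending a chosen
*prediction horizon* (4, 8 or 12 h) before the sepsis onset anchor, trains
sequence classifiers on them, and attributes each prediction to the
clinical variables driving it.

**Who it is for:** researchers building or auditing clinical early-warning
models who need a tested, reproducible reference pipeline — alignment and
imputation with explicit masks, leakage-free splits, padding-invariant
sequence models, and exact (not approximated-only) Shapley attribution —
plus a seeded synthetic cohort generator so everything runs without
credentialed data access.

## The method

1. **Windowing.** For each patient, a uniform 1 h grid runs from the first
   recorded event to `anchor − horizon`.  Observations snap to the nearest
   grid point; gaps are forward-filled (channel means for never-observed
   channels); windows are capped at 300 rows keeping the most recent
   history and left-padded with masked zero rows otherwise.
2. **Classification.**  Five architectures behind one scikit-learn-style
   estimator: a static baseline, RNN, LSTM, and two Transformer hybrids in
   which the token embedding is replaced by an LSTM (`lstm_transformer`)
   or a 1-D convolution (`cnn_transformer`) before a self-attention
   encoder and a softmax head.  Implemented on a compact numpy autodiff
   engine; training is bit-reproducible from a seed and predictions are
   exactly invariant to padding length.
3. **Attribution.**  Feature channels are players in a cooperative game:
   the value of a coalition S is the model's sepsis probability when the
   channels outside S are swapped against a background sample.  The
   Shapley value of channel i,

   φ_i = Σ_{T ∋ i} (|T|−1)!(n−|T|)!/n! · (v(T) − v(T∖{i})),

   is computed exactly (n ≤ 15), verified against an independent
   permutation-average oracle, and estimated without enumeration by
   Monte-Carlo over arrival orders.  Efficiency holds by construction:
   y_base + Σφ_i = y_i, and the residual is reported with every
   explanation.

Synthetic cohorts carry a known ground truth — a configurable pre-onset
drift on six signature channels (heart rate, respiration, SaO2, BNP, AST,
platelets) — against which signal recovery and attribution rankings are
tested end to end.  See `docs/methods.md` for the full model description,
design decisions, and limitations.

## Worked example

```python
import numpy as np
from sepsishorizon import (CohortParams, generate_cohort, records_from_tables,
                           RunConfig, run_experiment, explain_dataset,
                           feature_ranking, assemble_dataset, standardize_dataset,
                           cohort_ground_truth)
from sepsishorizon.io import ModelConfig, TrainConfig
from sepsishorizon.models import train

# a balanced 400-patient cohort with a 2-SD, 14 h pre-onset drift
params = CohortParams(n_patients=400, prevalence=0.5, seed=3)
patients, events = generate_cohort(params)
records = records_from_tables(patients, events)

# train the LSTM-Transformer on windows ending 4 h before onset
cfg = RunConfig(horizon_hours=4, seed=0, max_timepoints=72,
                model=ModelConfig(architecture="lstm_transformer", d_model=16,
                                  n_heads=2, n_encoder_layers=1, ff_dim=32),
                train=TrainConfig(max_epochs=15, batch_size=64,
                                  learning_rate=3e-3, seed=0))
report, clf = run_experiment(records, 4, cfg)
print(f"held-out AUROC {report.auroc:.3f}  accuracy {report.accuracy:.3f}")

# explain 12 predicted-septic patients against a control background
ds = standardize_dataset(assemble_dataset(records, 4, max_timepoints=72))
model = train(ds, cfg.model, cfg.train)
cases = np.flatnonzero(ds.y == 1)[:12]
exps = explain_dataset(model, ds, record_indices=cases, n_background=8,
                       method="sampled", n_samples=50, seed=0,
                       background="control")
print(feature_ranking(exps).head(6).to_string(index=False))
print("injected signatures:", cohort_ground_truth(params))
```

Output (exact numbers; the run is seeded):

```
held-out AUROC 0.948  accuracy 0.875
    feature  mean_abs_phi  frac_positive
       sao2      0.194948       1.000000
  platelets      0.189425       1.000000
respiration      0.145354       0.916667
 heart_rate      0.113835       0.833333
        ast      0.063212       0.833333
        wbc      0.052859       0.666667
injected signatures: ['heart_rate', 'respiration', 'sao2', 'bnp', 'ast', 'platelets']
```

The held-out AUROC of 0.95 says the model recovers the injected pre-onset
drift.  Five of the six drifted (signature) channels lead the attribution
ranking with consistently positive φ — each pushes the sepsis probability
up relative to the control background.  The sixth (BNP, sampled 6-hourly)
is narrowly edged out here by white-cell count, a channel with no injected
signal: at a 400-patient scale a model does not need all six redundant
signatures, and its residual sensitivity to an uninformative channel can
rival the weakest signature's attribution.  Larger cohorts recover all six
more reliably; `docs/methods.md` quantifies this ranking-stability
limitation.

The same pipeline is scriptable from the shell:

```bash
sepsis-horizon --seed 7 --out-dir run/ simulate --n 400
sepsis-horizon --seed 7 --out-dir run/ preprocess --in-dir run/ --horizon 4
sepsis-horizon --seed 7 --out-dir run/ train --in-dir run/ --arch lstm_transformer --horizon 4
sepsis-horizon --seed 7 --out-dir run/ explain --model run/model --windows run/windows.npz
```

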