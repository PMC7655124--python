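# hippofeat

Interictal iEEG features of the epileptic hippocampus: high-frequency
oscillation (HFO) and interictal discharge (IED) detection, high-frequency
functional connectivity, per-channel feature statistics, and SVM
classification of epileptic vs non-epileptic hippocampus — plus a
synthetic stereo-EEG cohort generator with ground truth, so every stage of
the pipeline can be validated end to end without access to patient
recordings.

## Who this is for

Researchers in clinical neurophysiology who quantify interictal biomarkers
of epileptogenic tissue from depth-electrode (stereo-EEG) recordings:
ripples (R, 80–250 Hz), fast ripples (FR, 250–600 Hz), spikes, and
between-contact coupling, under resting and cognitive-task conditions.

## The methods in brief

**HFO detector.** Each channel is decomposed into 300 log-spaced
constant-Q bands between 60 and 800 Hz; the Hilbert amplitude envelope of
each band is z-scored per 10-s statistical window and thresholded at
z > 3. Suprathreshold intervals overlapping in time in adjacent bands are
joined into time–frequency blobs; a blob is kept as an event if its
duration exceeds 4 cycles at its dominant frequency and it does not touch
the 60 Hz floor band (spike-leakage guard). Events are labelled R or FR by
dominant frequency; per-channel features are the rate (per 10 min), mean
relative amplitude (envelope z), mean dominant frequency and mean duration
per band.

**IED detector.** Barkmeier-style two-band scheme: a scaling factor from
the 1–35 Hz background normalizes each channel, candidate spikes are found
in the 20–50 Hz band, and amplitude/slope thresholds on the scaled
wide-band signal confirm them. Features: spike rate and mean amplitude.

**Connectivity.** For adjacent contacts on one electrode, in
non-overlapping 1-s windows of the R- and FR-band signals:
`corr(X,Y) = cov(X,Y)/(std(X)·std(Y))` and the relative entropy
`REN(X,Y) = Σ pX·log(pX/pY)` between the windows' amplitude histograms.

**Statistics.** Paired t-tests (rest vs task within EH and NEH),
Mann–Whitney tests (EH vs NEH per condition), and ROC-AUC per feature for
rest, task, and rest−task values, with the Hanley–McNeil closed-form test
against AUC = 0.5 — per channel and per hippocampus (channel medians).

**Classifier.** Features with ROC significantly different from chance
feed a standardize → PCA → SVM pipeline with Platt-calibrated channel
probabilities, evaluated by leave-one-hippocampus-out cross-validation
with kernel/C/γ grid search; a hippocampus is called epileptic when its
channels' mean probability exceeds 0.5.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and limitations.

## Worked example

```python
from hippofeat import (
    GroupParams, generate_cohort, extract_cohort_features,
    grouped_task_reduce, run_battery, select_features,
    build_feature_matrix, grid_search,
)

# synthetic cohort: 3 epileptic + 3 non-epileptic hippocampi, 2 contacts
# each, rest + task, 60-s segments at 2 kHz
segments, truth = generate_cohort((3, 3), 2, ("rest", "task"),
                                  GroupParams.table_defaults(),
                                  duration_s=60.0, fs=2000.0, seed=7)
feats = grouped_task_reduce(extract_cohort_features(segments))
print(feats.groupby(["label", "condition"])[["r_rate", "ied_rate", "r_ren"]]
      .mean().round(2))

tests, rocs = run_battery(feats)
sel = select_features(rocs)
X, y, groups = build_feature_matrix(feats, sel)
report, table = grid_search(X, y, groups, c_grid=(1e-3, 1e-1, 10.0),
                            gamma_grid=(1e-2, 1.0), seed=7, refine=False)
print(f"best {report.kernel} C={report.C} gamma={report.gamma} "
      f"AUC={report.auc:.2f} hippocampus accuracy="
      f"{report.hippocampus_accuracy:.2f}")
```

Output:

```
                 r_rate  ied_rate  r_ren
label condition
EH    rest       150.00    151.67   0.25
      task        78.33    116.67   0.18
NEH   rest        55.00     60.00   0.10
      task        18.33     16.67   0.09
best linear C=0.001 gamma=scale AUC=1.00 hippocampus accuracy=1.00
```

Epileptic hippocampi show several-fold higher ripple and spike rates and
higher relative entropy than non-epileptic ones; cognitive-task segments
suppress rates in both groups; the cross-validated SVM separates the two
classes cleanly at this effect size. (Exact numbers vary with the seed.)

There is also a CLI mirroring the library:

```bash
hippofeat simulate --out cohort/ --n-eh 2 --n-neh 2 --duration 60 --seed 1
hippofeat detect-hfo cohort/seg000_eh1_rest_rest.npz --out hfo.csv
hippofeat features cohort/seg*.npz --out features.csv
hippofeat stats features.csv --out-prefix battery
hippofeat classify features.csv --out model.json --scope all
```

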