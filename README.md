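# sdstrip

Automated detection of spreading depolarizations (SDs) in full-band
electrocorticography using sparse (0.1 Hz) sampling.

SDs appear on a DC-coupled ECoG channel as a slow negative potential shift of
a few millivolts lasting about two minutes. `sdstrip` implements the complete
detection workflow:

1. **Preprocess** raw full-band recordings: subtract a centered 10-min moving
   median (removes the >70 mV DC offset and drift without distorting SD
   waveforms), zero-phase FIR low-pass at 0.5 Hz, decimate 256 → 1 Hz.
2. **Extract features**: 80 candidate features per 400-s segment decimated to
   0.1 Hz — 30 time-domain statistics (full segment + two 30-sample
   sub-windows) and 50 frequency-domain features from the FT magnitude and
   PSD (five most prominent peaks, absolute maxima, quadrant counts of all
   local maxima on rescaled axes, and the ten statistics applied to each
   spectrum).
3. **Train** a gradient-boosted-tree or RBF-SVM segment classifier on
   1000-s windows centered on expert marks (positives) and non-overlapping
   SD-free windows (negatives), with gain-based feature ranking and
   leave-one-patient-out cross-validation.
4. **Detect**: slide the classifier across continuous 1-Hz data in 1-s (or
   10-s) steps to produce a probability trace P_SD(t); runs with
   P_SD ≥ θ_P lasting ≥ θ_D seconds (defaults 0.5 / 50 s) become detections.
5. **Evaluate** against ground truth with the 400-s matching-window rule:
   sensitivity, precision, F1, OBJ = TP² − 2·FP², FP/day, and post-hoc
   adjudication adjustment.

Because no public ECoG dataset accompanies the method, the package includes a
seeded synthetic generator (`sdstrip.synthetic`) producing multichannel
full-band-like recordings with injected SD waveforms (configurable amplitude
/ duration distributions, inter-channel spread delays, atypical variants,
artifacts) and exact ground-truth annotations, so the entire pipeline is
testable end to end.

## CLI

```sh
sdstrip simulate   --spec spec.yaml --out-dir cohort/ --seed 17
sdstrip preprocess --in cohort/S01.h5 --out prep.h5
sdstrip extract    --in prep.h5 --annotations cohort/S01_annotations.csv --out features.csv
sdstrip train      --features features.csv --model-kind gbt --k 30 --out model.bin
sdstrip detect     --in prep.h5 --model model.bin --theta-p 0.5 --theta-d 50 --out events.csv
sdstrip evaluate   --events events.csv --annotations cohort/S01_annotations.csv \
                   --hours 24 --out report.json
```

Recordings are EDF or HDF5 (voltages normalized to mV internally);
annotations are CSV (`subject,channel,t_peak_s[,label_class]`); models are a
joblib dump plus a JSON sidecar recording the feature registry version,
selected features, and preprocessing parameters.

## Layout

- `src/sdstrip/io.py` — EDF/HDF5 recordings, CSV annotations, model files
- `src/sdstrip/preprocess.py` — moving-median baseline, FIR low-pass, decimation
- `src/sdstrip/features.py` — the 80-feature registry
- `src/sdstrip/classifier.py` — training sets, ranking, GBT/SVM, LOPO-CV, grid search
- `src/sdstrip/detector.py` — P_SD(t) sliding window + dual-threshold events
- `src/sdstrip/evaluate.py` — matching, metrics, threshold sweeps, adjudication
- `src/sdstrip/synthetic.py` — seeded synthetic ECoG cohort generator
- `tests/test_acceptance.py` — acceptance criteria, one test per criterion
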