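# pairq — pairwise combinatorial efficiency analysis for qPCR dilution series

Real-time qPCR quantification hinges on the amplification efficiency *E*, the
per-cycle fractional increase of product (E = 1 is perfect doubling:
F grows as (1+E) per cycle). The standard estimate regresses the quantification
cycle Cq on log concentration across a serial dilution and takes
E = 10^(−1/slope) − 1 — one number per dilution set, with precision limited by
the handful of Cq values available.

`pairq` implements a combinatorial alternative for researchers analysing
dilution-series runs. Inside the exponential-phase RFU window, **every pair of
fluorescence readings** across (and within) the curves of a dilution set yields
its own efficiency value

    E_ij = b ** ((log_b F_j − log_b F_i + (D2 − D1)) / (j − i)) − 1

where i, j are cycle numbers, F_i, F_j the baseline-subtracted readings, D1, D2
the dilution steps of the two wells at fold-dilution base b (D1 = D2 when both
readings sit on one curve; pairs sharing a cycle are excluded). A six-well
two-fold set typically yields 200–260 such values — enough for real
distribution diagnostics (skew, excess kurtosis, chi-square against a fitted
normal on 0.05-wide bins) and a non-parametric outlier rule: scanning outward
from the modal histogram bin, the first bin with fewer than 5 values fixes a
cutoff, and values beyond the cutoffs are discarded before averaging.

The package also provides:

* the classical calibration-curve baseline (`pairq.calibration`);
* exponential-window diagnostics: early-cycle noise profiling, a
  studentized-residual takeoff detector for the lower RFU bound, the First
  Derivative Maximum for the upper bound, per-cycle stable-E scans, and a
  Monte-Carlo grid search over candidate RFU windows (`pairq.region`);
* a Monte-Carlo precision harness that resamples replicate sets in triplets
  and compares methods by the SD of the sampling means (`pairq.precision`);
* relative quantification: F0 = F_i/(1+E)^i back-calculation, Pfaffl-style
  ratios (1+E)^ΔCq, worst-case replicate-ratio error bounds, and a
  dilution-ratio accuracy table (`pairq.quantify`);
* a synthetic-plate generator with exponential growth, logistic saturation and
  Gaussian baseline noise, for testing and power studies (`pairq.simulate`).

## Worked example

Simulate a 96-well plate (16 replicate two-fold six-step sets, true E = 0.8,
noise sd 3 RFU) and estimate per-set efficiencies in the 20–180 RFU window:

```sh
pairq simulate --seed 11 --outdir run/
pairq estimate --fluorescence run/fluorescence.csv --layout run/layout.csv
```

```
set_id  e_raw  e_final  n_total  n_retained   skew  kurtosis  cutoff_low  cutoff_high
  A1-6  0.794    0.794      233         217  0.027     3.481         0.6          1.0
 A7-12  0.800    0.799      233         223  0.444     3.320         0.6          1.0
  B1-6  0.816    0.807      232         217  0.789     3.463         0.6          1.0
 B7-12  0.773    0.772      235         226 -1.305    16.537         0.6          0.9
...
```

Each set contributed ~230 pairwise E values (`n_total`); the positive excess
kurtosis shows the leptokurtic shape typical of these arrays, and values in
histogram bins with fewer than 5 members — here below 0.60 or above ~1.0 —
were excluded (`n_retained`), moving the mean from `e_raw` to `e_final`.
Comparing precision of the two estimators over the 16 replicate sets:

```sh
pairq compare --fluorescence run/fluorescence.csv --layout run/layout.csv \
              --cq run/cq.csv --seed 4 --outdir report/
cat report/precision.csv
```

```
method,sd,e_max,e_min,range,mean_e
pairwise,0.00690,0.8128,0.7822,0.0306,0.7980
calibration,0.01335,0.8405,0.7777,0.0628,0.8066
```

Both arms recover the true E ≈ 0.80, but the Monte-Carlo SD of the pairwise
estimator (0.0069) is roughly half the calibration-curve SD (0.0134) — the
combinatorial estimate is about twice as precise on the same wells.

Analysing your own run takes three CSVs: fluorescence (`well,cycle,rfu`,
baseline-subtracted), layout (`well,set_id,dilution_step,concentration`) and
optionally Cq values (`well,cq`) for the calibration baseline.
`scripts/convert_supplementary.py` converts spreadsheet exports into these
formats; `data/` ships the standard 16×6 layout.

## Documentation

The model, its assumptions, parameter defaults and known limitations are
described in [`docs/methods.md`](docs/methods.md).
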