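# tegma

Early prediction of thromboelastography clot strength from the citrated
rapid TEG reaction time.

## The problem

During cardiac surgery with cardiopulmonary bypass, transfusion decisions
hinge on viscoelastic whole-blood assays (TEG6s). The decisive parameter —
the maximum amplitude (MA, mm), reflecting combined platelet and fibrinogen
clot strength — takes 30–60 minutes to result. The reaction time of the
citrated rapid TEG channel (CRT-R, minutes) is available within the first
few minutes of the same run. `tegma` implements the analysis that turns
CRT-R into an early warning signal for low final clot strength: it models
the inverse relationship between CRT-R and the MA parameters, derives
CRT-R cutoffs anchored at clinical MA targets, quantifies their uncertainty
by bootstrap, and evaluates them as diagnostic screens. It is aimed at
biostatisticians and perioperative researchers reproducing or extending
this kind of viscoelastic early-prediction analysis.

## The model

Each MA outcome is related to CRT-R by a three-parameter exponential decay

    y = a · e^(−b·x) + c        (b > 0)

fitted by nonlinear least squares; CRT-R vs TEG-ACT (the device-derived
activated clotting time, seconds) is linear, `crt_r = 0.0107·act − 0.5397`,
because the device computes ACT from the reaction time. A clinical MA
target `y*` (CRT-MA = 48 mm for global clot weakness, CFF-MA = 12 mm for
fibrinogen-deficient clot strength) converts to a reaction-time cutoff by
inverting the monotone curve,

    x* = −(1/b) · ln((y* − c)/a),

with a percentile bootstrap (resample pairs, refit, re-invert; 2.5/25/50/
75/97.5 percentiles) for the interquartile range and 95% CI. At a cutoff,
a run is screen-positive when `crt_r > x*` and truly positive when
`ma < y*`, giving the usual sensitivity/specificity/PPV/NPV/accuracy.

Because no patient data are distributable, the package includes a
first-class synthetic cohort generator (truncated log-normal CRT-R marginal
calibrated to median 0.7 min, IQR 0.5–0.9; published decay equations plus
RMSE-scale Gaussian noise; MCAR missingness; implausible-CRT-R outliers)
so the whole pipeline is testable end to end. See `docs/methods.md` for
assumptions and limitations.

## Worked example

Simulate the default study-condition cohort (2,453 runs), apply the
exclusion rules, fit every channel, and derive bootstrap cutoffs:

```sh
$ tegma analyze --seed 1 --n-boot 200 --out demo
records: 2453 -> 2345 (87 missing, 21 outliers excluded)
crt_ma_mm: |r|=0.5548 R2=0.3095 MAE=5.16 RMSE=6.48
ckh_r_min: |r|=0.2534 R2=0.0698 MAE=3.11 RMSE=3.82
ckh_ma_mm: |r|=0.5123 R2=0.2713 MAE=5.98 RMSE=7.44
cff_ma_mm: |r|=0.5862 R2=0.3582 MAE=3.95 RMSE=4.95
teg_act_s: |r|=1.0000 R2=1.0000 MAE=0.00 RMSE=0.00
cutoff cff_ma_mm @ 12: 1.2897 min (95% CI 1.2525-1.3353); sens 0.302 spec 0.959
cutoff crt_ma_mm @ 48: 1.2930 min (95% CI 1.2496-1.3375); sens 0.313 spec 0.966
report written to demo/report.json
```

Reading this output: of 2,453 simulated runs, 87 were dropped for a
missing field and 21 for an implausible CRT-R (> 5.5 min), leaving 2,345.
CRT-R correlates moderately and inversely with every MA channel —
strongest with the functional-fibrinogen amplitude (|r| = 0.59) — and is
an exact linear re-expression of TEG-ACT (r = 1). Inverting the fitted CFF
curve at the 12 mm target puts the early-warning threshold at ≈ 1.29 min:
a run whose CRT-R exceeds it is flagged for likely low fibrinogen-related
clot strength (here with 96% specificity and 30% sensitivity), in time to
start preparing fibrinogen therapy. The cutoff sits close to the
closed-form inversion of the generating curve (1.2841 min), as it should
on data the generator produced. `demo/` also contains the machine-readable
`report.json`, per-channel fitted-curve tables and a cutoff table.

Other entry points:

```sh
$ tegma convert-act 128
TEG-ACT 128 s -> CRT-R 0.83 min (49.8 s)
$ tegma cutoff --channel CFF-MA --target 12
CFF-MA = 12 -> CRT-R cutoff 1.2841 min
$ tegma simulate --n 500 --seed 7 --out cohort.csv   # CSV fixture
$ tegma report demo/report.json                      # re-render a report
```

The same operations are available as a library
(`tegma.simulate_cohort`, `tegma.apply_exclusions`, `tegma.fit_exp_decay`,
`tegma.bootstrap_cutoff`, `tegma.classify_at_cutoff`, …).

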