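# fmgforce

Multi-DoF isometric hand force/torque estimation from force-myography
(FMG) bands.

## The problem

Force myography senses muscle contraction as pressure changes at the
skin surface, via force-sensing resistors (FSRs) worn in bands on the
arm.  Given four such bands — wrist, forearm midway, forearm muscle
belly, upper arm; 60 sensors in total, sampled at 10 Hz — and a 6-DoF
load cell recording the forces (Fx, Fy, Fz, in N) and torques (Tx, Ty,
Tz, in Nm) a subject exerts isometrically on a fixed sphere, can the
instantaneous 6-DoF load be regressed from the FMG channel vector, and
which band placement carries the information?  This package implements
that analysis end to end for people working on wearable force sensing:
a synthetic generator for the trial/session protocol (no public
recordings exist), the preprocessing chain, the two-stage stacked
regression, cross-trial evaluation over all band combinations, and the
factorial statistics.

## The model

Stage 1 maps preprocessed FMG features x (normalized channels + first
differences) to each axis with one of three learners: a general
regression neural network (GRNN), ν-SVR with RBF kernel, or random
forest.  The GRNN is the Nadaraya–Watson kernel average with a single
spread σ,

    ŷ(x) = Σᵢ Yᵢ exp(−‖x − Xᵢ‖² / 2σ²) / Σᵢ exp(−‖x − Xᵢ‖² / 2σ²),

one pattern unit per training sample.  Stage 2 is always a multi-output
GRNN over the augmented features raw | d(raw) | ŷ⁽¹⁾ | d(ŷ⁽¹⁾) |
spherical(ŷ⁽¹⁾), exploiting the cross-axis coupling that is always
present because subjects cannot isolate a single axis.  Accuracy is the
coefficient of determination R² = 1 − SSE/SST per axis per held-out
trial (leave-one-trial-out within subject), averaged over axes and
folds; band combination × algorithm effects are tested by two-way
fixed-effects ANOVA with Tukey HSD post-hocs at α = 0.05.

See `docs/methods.md` for the full model description, parameter
defaults, and known limitations.

## Worked example

```
$ python analysis/02_stacking_gain.py
cohort 0: 0.332 -> 0.352
cohort 1: 0.289 -> 0.407
...
cohort 19: 0.365 -> 0.524
stacking wins 17/20 cohorts (sign test p = 0.0013); mean gain +0.052 R^2
```

Each line is one synthetic subject (3 trials): the single-stage mean
6-DoF R² on the held-out trial, then the final two-stage value from the
same fit.  The closing line is the sign test across cohorts: the second
stage improves the estimate in 17 of 20 cohorts, far more often than
chance, with a mean gain of about +0.05 R².

```
$ python analysis/03_band_placement.py
cohort 0: b1=0.223  b2=0.254  b3=0.326  b4=0.098
...
muscle belly (band 3) ranked first in 9/10 cohorts; upper arm (band 4) ranked last in 10/10
```

Single-band accuracies recover the structure encoded in the generator's
coupling: the forearm muscle-belly band is the most informative single
placement and the upper arm — which carries almost no torque response —
the least.

The numbered scripts under `analysis/` run the full sequence: simulate a
cohort (`01`), quantify the stacking gain (`02`), rank band placements
(`03`), and run the band × algorithm ANOVA with Tukey post-hocs (`04`).
Tables land under `results/`.  The same steps are scriptable through the
CLI:

```
fmg-bands simulate --subjects 9 --seed 1 --out scratch/data
fmg-bands run --data scratch/data/subject_01.csv --case 2 --bands 2,3 --algo svr --quick
fmg-bands sweep --data-dir scratch/data --out results/folds.csv --quick
fmg-bands report --folds results/folds.csv --out-dir results/
```

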