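# alphavar

Trial-to-trial variability of auditory alpha-band power in resting-state
MEG.

Chronic subjective tinnitus is associated with reduced ongoing alpha
(8–12 Hz) activity over auditory cortex. Beyond the *mean* level, the
moment-to-moment variability of that activity is itself informative: a
nervous system whose excitability never varies may have lost dynamic range.
`alphavar` implements the full sensor-space analysis for this question —
and, because such clinical MEG data are rarely shareable, a synthetic-cohort
generator whose planted parameters are exactly the quantities the pipeline
estimates, so every stage is testable end to end.

## The statistic and the models

For each subject, 90 randomly selected, artifact-free 2 s epochs are
Hann-tapered and Fourier-transformed (1–100 Hz, 0.5 Hz steps). The core
statistic is the coefficient of variation of spectral power across epochs,
per sensor *s* and frequency bin *f*:

    CV[s, f] = sd_t( P[t, s, f] ) / mean_t( P[t, s, f] )

a dimensionless, scale-free measure of moment-to-moment variability
(sample standard deviation over t = 1..90 epochs). Band values average
CV over the lower-alpha bins [8, 10) Hz or upper-alpha bins [10, 12) Hz and
over a temporal region of interest per hemisphere, selected once from the
group-difference topography of 8–10 Hz power and then frozen.

Group contrasts (tinnitus vs control, for ROI mean power and CV in each
band) use a linear mixed model with a random intercept per subject on the
two hemisphere observations,

    outcome ~ group + (1 | subject),

with the group effect reported as an F statistic on (1, n−2) degrees of
freedom — (1, 40) at 21 + 21 subjects. Within the tinnitus group, the
variability–duration relation is the hyperbolic model

    CV = b / duration + a,

fitted by least squares in 1/duration, complemented by a median split of
duration compared with Welch's t-test and Pearson checks against distress
and age.

## Worked example

```python
import alphavar as av

cfg = av.CohortConfig(                    # reduced frame; defaults are full scale
    n_per_group=21, n_sensors=10, n_temporal_per_side=4,
    sampling_rate=250.0, duration_s=220.0, epochs_analyzed=90, seed=3,
)
report = av.run_pipeline(av.RunConfig(cohort=cfg, target_rate=250.0))
model = av.AlphaVariabilityModel(report.summary_table)
print(model.fit().summary())
```

prints

```
Auditory alpha power and trial-to-trial variability
===================================================================
Subjects: 42   unit: subject x hemisphere ROI value

Group contrasts (mixed model, random subject intercept)
-------------------------------------------------------------------
band        outcome             F        df           p
low_alpha   mean_power       6.24    (1,40)     0.01674
low_alpha   cv              17.79    (1,40)   0.0001372
high_alpha  mean_power       0.23    (1,40)      0.6367
high_alpha  cv               1.38    (1,40)      0.2475

Tinnitus-duration association (cv = b/duration + a)
-------------------------------------------------------------------
a = 2.564 (t = 9.40, p = 1.4e-08)   b = 0.019   resid sd = 0.587
median split at 2.51 y: short mean 2.599 (n=11), long mean 2.540 (n=10), Welch t = 0.23, df = 16.1, p = 0.825
cv ~ distress: r = 0.090, p = 0.698 (n=21)
cv ~ age: r = 0.110, p = 0.635 (n=21)
```

Reading it: the planted low-alpha reductions (tinnitus power ratio 0.2, CV
offset 1.05) surface as group effects on (1, 40) degrees of freedom while
the upper band — where nothing was planted — stays null. The duration fit
recovers the planted intercept (a = 2.38) within its standard error; the
slope of a single 21-subject cohort is weakly identified (per-cohort
standard error near 0.8 against the planted b = 1), which is why the test
suite assesses recovery over 200 replicated cohorts. Single-cohort Welch
splits are similarly underpowered by design; see `docs/methods.md`.

The pipeline is also scriptable stage by stage (`alphavar simulate`,
`preprocess`, `spectra`, `cv`, `stats`, `run`, `report` on the command
line), with recordings and derived maps carried as HDF5, metadata and band
tables as TSV, configurations as YAML, and an optional FIF export.

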