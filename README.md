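# motorage

Aging biomarkers from hand/forearm inertial-sensor recordings.

Fine motor control degrades with age, but no single signal feature of a
hand-movement recording changes *gradually* across the adult lifespan —
individual features separate young from elderly, yet plateau within age
bands.  `motorage` implements a pipeline that combines hundreds of IMU
signal features into one scalar, the **LDA-value**, that both separates
eight decade-wide age groups and correlates linearly with age.  It is aimed
at researchers in movement analysis, geriatrics and digital-biomarker
development who work with wearable inertial sensors.

## The method

Recordings come from two 9-axis IMUs (accelerometer, gyroscope,
magnetometer; sensors A1/G1/M1 on the forearm, A2/G2/M2 on the hand
dorsum) sampled at 50 Hz during three tasks (rest, pinch,
pronation/supination), three trials each.  Each 3-axis stream is band-pass
filtered (1–16 Hz, 5th-order Butterworth), mean-removed, and collapsed to
the resultant magnitude R = √(s_x² + s_y² + s_z²).  Eighteen parameters —
amplitude (MAV, MAVFD, MAVSD, RMS, Peak), frequency (ZC, FMean, FPeak,
F50, F80, Power3.5–7.5), entropy (ApEn, FuzzyEn) and statistics (VAR,
RANGE, INTQ, SKEWNESS, KURTOSIS) — over 6 sensors and 3 tasks give 324
features per trial.  Trial-level outliers are screened with interquartile
fences, trials are averaged, and redundant features (|r| > 0.9) pruned.

The core step writes each participant's normalized feature vector
c ∈ [0.1, 1.1]ⁿ in hyperspherical coordinates

    p = ‖c‖,   θ_k = arctan( c_{k+1} / ‖(c_1 … c_k)‖ ),   k = 1 … n−1,

and projects it onto a rotated one-dimensional axis:

    LDA-value = p · ∏_k cos(θ_k + θ̂_k).

A real-coded genetic algorithm (roulette selection, arithmetic three-child
crossover, per-gene mutation, elitism) searches the rotation angles θ̂
maximizing the separability

    E_z = Σ_{i<j} | (x̄_i − x̄_j) / √(σ²_i + σ²_j) |

summed over all pairs of age groups.  Features whose removal changes E_z
by less than 1% are discarded and the axis is re-optimized on the
survivors.  The published 46-offset axis from the original study is
shipped as a constant for evaluating new data (`PUBLISHED_AXIS`,
`evaluate_published_axis`).

Because the study cohort is not public, the package includes a synthetic
cohort generator reproducing its structure (99 participants, eight groups
of sizes 13, 12, 13, 15, 11, 14, 13, 8 with decade-band ages) with
tremor-like oscillatory signals whose amplitude and irregularity drift
monotonically with age, plus ground-truth registries for injected
redundancy and outliers.

## Worked example

```python
from motorage import (CohortSpec, EffectModel, GAConfig,
                      simulate_feature_matrix, estimate_lda_value)

sim = simulate_feature_matrix(
    CohortSpec(seed=8),
    EffectModel(affected_fraction=0.6, slope_scale=0.02),
    n_features=40,
)
res = estimate_lda_value(
    sim.values, sim.groups.to_numpy(), ages=sim.ages.to_numpy(),
    config=GAConfig(epochs=500, seed=8),
)
print(res.summary())
```

```
LDA-value fit
==============================================
participants                    99
features in                     40
relevant features               38
GA epochs                      500
population size                 50
separability E_z          194.1195
Pearson r (age)             0.8708
  p-value                 1.12e-31
----------------------------------------------
group means (LDA-value)
  group 1:  mean    2.282e-06  sd   1.94e-06  n  13
  group 2:  mean    5.718e-06  sd   2.41e-06  n  12
  group 3:  mean    1.103e-05  sd   5.69e-06  n  13
  group 4:  mean    3.626e-05  sd   1.37e-05  n  15
  group 5:  mean    5.059e-05  sd    1.3e-05  n  11
  group 6:  mean    8.602e-05  sd   2.88e-05  n  14
  group 7:  mean    0.0001219  sd   5.28e-05  n  13
  group 8:  mean     0.000163  sd   2.42e-06  n   8
```

The 99 simulated participants carry a linear age effect in 60% of the 40
features; the fitted projection recovers it with Pearson r = 0.87 between
the LDA-value and age, and the group means rise monotonically from group 1
(20s) to group 8 (90s).  The absolute scale of the LDA-value is
meaningless (a product of many cosines); only its ordering and linearity
matter.

The same analysis is available from the shell:

```bash
motorage simulate --out sim --level features --seed 8
motorage fit --features sim/features.csv --labels sim/labels.csv \
             --epochs 500 --seed 8 --out fit.json
motorage run --seed 1 --out fullrun   # full signal-level pipeline
```

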