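# Methods

## Scientific setting

Heart-rate variability (HRV) indexes autonomic function and is reduced
during acute bipolar episodes. The quantity modelled here is night-time
lnRMSSD: the natural log of the root mean square of successive RR-interval
differences (formula below), extracted from wrist-wearable recordings, one
value per clinical assessment. Subjects are recruited at the onset of an
acute manic or depressive episode and assessed three to four times until
euthymia (scale total ≤ 7), with symptom severity tracked on the YMRS
(mania, range 0–60) or the 17-item HDRS (depression, range 0–52). Time
within an episode is clocked not in days but by fractional symptom
improvement

    I[i,t] = (score[i,0] - score[i,t]) / score[i,0],

which is 0 at onset and 1 at full resolution, making trajectories
comparable across polarities despite the different scales.

## HRV extraction

RMSSD over N RR intervals is

    RMSSD = sqrt( (1/(N-1)) * sum_i (R[i+1] - R[i])^2 ).

Per session, extraction proceeds as: (1) off-body detection — EDA samples
below 0.05 μS mark the device as not worn; maximal below-threshold runs
become masked intervals; (2) the first complete 22:00–05:00 clock window
at or after session start is the analysis night (a session starting
mid-night waits for the next complete window, so every night has the same
duration); (3) 5-minute windows advance in 1-minute steps from the night
start; (4) a window is invalid if it overlaps masked time, contains fewer
than 150 RR intervals (a ~30 bpm floor), or more than 20% of its absolute
successive differences exceed 250 ms (spike/dropout artifacts); (5) the
night value is the mean RMSSD over valid windows, reported as lnRMSSD.
The window-validity thresholds are package-defined, configurable QC rules;
upstream toolkits that perform interbeat-interval cleaning internally do
not document an equivalent rule set, so per-night invalid-window rates are
not comparable across implementations.

## The two hierarchical models

Both model variants share the observation level

    lnRMSSD[i,t] ~ Normal(beta0[i] + beta1[i] * I[i,t] + beta2 * M[i,t], sigma[i])

where M counts concurrently prescribed HRV-relevant medication classes
(16 tracked classes; only the count enters). Subject intercepts pool
through covariates — standardized age A, sex S (female = 1), baseline
severity B = onset score / scale maximum:

    beta0[i] ~ Normal(alpha0 + alpha1*A[i] + alpha2*S[i] + alpha3*B[i], 0.5)
    sigma[i] ~ InverseGamma(3, 0.5)          # shape-scale, on the sd itself
    alpha0   ~ Normal(mean observed lnRMSSD, 0.1)
    alpha1, alpha2, alpha3, beta2 ~ Normal(-0.1, 0.1)

The *two-polarities* variant lets the slope centre differ by episode
polarity:

    beta1[i] ~ Normal(gamma[polarity[i]], 0.1),  gamma_m, gamma_d ~ Uniform(-1, 1)

while the *one-disease* variant drops the polarity structure entirely:

    beta1[i] ~ Uniform(-1, 1).

Conventions the equations leave open, fixed here: every Normal second
argument is a standard deviation; the inverse gamma is shape–scale with
density ∝ x^(−shape−1) e^(−scale/x), placed on sigma (not sigma²); alpha0
takes the empirically centred prior rather than the shared coefficient
prior (the coefficient prior applies to alpha1, alpha2, alpha3, beta2).
The empirical centring of alpha0 is deliberate data-dependence
(empirical-Bayes) and is recomputed per table.

## Synthetic cohorts

The generator draws cohorts from exactly the two-polarities generative
process above (setting gamma_m = gamma_d recovers the one-disease
process), with covariates matched to the study sample the analysis was
designed around: 14 manic / 9 depressed subjects; 17 with three and 6 with
four assessments; YMRS baselines ~N(25.64, 5.09), HDRS ~N(19.11, 3.21)
(rounded, clipped to [8, scale max] so an acute episode exists); ages
~N(42.14, 12.81) / N(44.56, 13.03) clipped to [18, 85]; female fractions
5/14 and 6/9; medication counts ~ rounded N(2.86, 1.30) / N(3.78, 0.63)
clipped to [0, 16] and held constant over assessments. Score trajectories
are sampled uniformly from the strictly decreasing integer lattice ending
at a uniform euthymic total (≤ 7): monotonicity and the euthymic endpoint
are the only constraints the design imposes, so no trajectory shape is
favoured. Default true hyperparameters: alpha0 = 3.6 (RMSSD ≈ 37 ms, a
typical night value), alpha1 = alpha2 = alpha3 = −0.1 and beta2 = −0.05
(at the prior centres, matching the direction previous research reports),
gamma = 0.2 for both polarities (the size of slope the analysis targets).

Raw streams: the heart period follows a mean-reverting AR(1) around
850 ms (phi = 0.9) whose Gaussian innovations are calibrated so
E[(ΔRR)²] equals the target RMSSD², clipped to [300, 1500] ms. A pure
random walk with Gaussian steps was rejected: over a 7-hour night it
drifts far outside the physiological range and boundary clipping biases
the realized RMSSD low; mean reversion preserves the calibration while
keeping the period bounded. Artifacts are injected at a configurable
fraction of beats, half spikes (doubled interval) and half dropouts
(merged beats) — the two dominant wrist-PPG failure modes. EDA runs at
4 Hz around 1 μS with slow drift on body and below 0.05 μS in off-body
segments.

What the generator does not emulate: HRV spectra and respiratory sinus
arrhythmia, circadian modulation across the night, sleep staging,
accelerometer/temperature channels, dropout mechanics of excluded
subjects, and any nonlinearity in symptom–HRV coupling. Passing tests
therefore demonstrate that the pipeline recovers the assumed generative
process at study scale — not that real recordings satisfy these
assumptions.

Seeding: each config carries one base seed; per-subject, per-session and
per-replicate streams are spawned from it via `numpy.random.SeedSequence`,
so any subset regenerates identically in isolation.

## Inference

No probabilistic-programming framework is part of the dependency set; the
sampler is a self-contained multinomial No-U-Turn HMC implementation over
the exact joint densities above, with analytic gradients. Bounded
parameters are transformed to unconstrained space (log for sigma, scaled
logistic for interval-bounded slopes and gamma) with the log-Jacobian
included. Warmup combines dual-averaging step-size adaptation toward the
target acceptance statistic with windowed estimation of the mass matrix;
windows follow the standard expanding schedule, and the metric switches
from diagonal to dense (full covariance, shrunk toward the unit matrix)
once a window holds at least twice as many draws as there are parameters
— the intercept/medication-coefficient correlation in this design makes
the dense metric markedly more efficient at study scale, while short
warmups stay diagonal because small-sample covariance estimates are
noisier than their diagonal. Chains initialize at the prior means with
uniform ±0.05 jitter in unconstrained space. Transitions with energy
error above 1000 are flagged divergent; a fit whose divergence rate
exceeds 1% carries a warning in its result. The default configuration is
the study's: 4 chains × (2000 tune + 2000 draws), target acceptance 0.99,
maximum tree depth 10.

Diagnostics use the rank-normalized split-chain formulations of bulk ESS
and R-hat (via ArviZ), and per-chain BFMI = mean squared energy
difference / energy variance, with the per-draw Hamiltonian of the
selected trajectory state recorded as the energy. Replicate-based
simulation checks (parameter recovery, model-selection consistency, HDI
exclusion rates) run at a scaled-down configuration — 2 chains,
150–400 tune, 150–400 draws, target 0.8–0.9, diagonal metric — chosen as
the package's standard replicate budget; pooled-slope summaries were
verified to be insensitive to the extra precision of the full
configuration (matching means across weak and strong settings on shared
cohorts).

## Posterior summaries and decision rules

The pooled improvement slope concatenates every chain, draw and subject
of beta1. Probability of direction is the percentage of draws sharing the
median's sign (zero draws count toward neither sign; an exactly zero
median reports 50%). The HDI-95 is the narrowest window of
ceil(0.95 · n) consecutive sorted draws; width ties resolve to the lowest
lower bound. The ROPE defaults to [−0.05, 0.05] on the lnRMSSD-slope
scale — a multiplicative RMSSD change between e^−0.05 = 0.951 and
e^0.05 = 1.051 per full symptom resolution — and the decision rule is:
reject the ROPE if the HDI and ROPE are disjoint, accept equivalence if
the HDI lies inside the ROPE, otherwise withhold. WAIC is reported on the
deviance scale, waic = −2(lppd − p_waic), with p_waic the population
variance of the pointwise log likelihood over draws, so lower is better;
models are comparable only on identical observation sets. The
prior-predictive KL divergence between the two variants is a shared-
support histogram estimate (100 bins spanning both samples, 1e-10
additive regularization, clipped at zero). Prior predictive checks use
a configurable physiological plausibility range of lnRMSSD ∈ [1.0, 5.5]
(RMSSD ≈ 2.7–245 ms).

## Numerical and degenerate-input choices

Quantiles use linear interpolation. Age standardization uses the included
(post-filter) subjects with the n−1 sd; constant ages are an error, as is
an onset score of zero (no acute episode). RMSSD needs at least two
intervals; a night with no valid window, or a zero mean RMSSD, is an
error rather than a silent NaN. Off-body detection assigns each
below-threshold sample the span of one median sampling period. Windows
bind RR intervals by onset time, half-open [start, end). Parameter values
outside prior support give a log joint of −inf; the sampler never visits
them because its transforms keep draws in the interior.

## Known limitations

* The per-subject slope prior of the one-disease variant is uniform, so
  per-subject slope posteriors do not shrink toward a common centre; with
  three observations per subject the pooled slope sample is accordingly
  wide under the default noise level, and simulated HDI-exclusion rates
  are conservative. The bounded support also pulls the pooled posterior
  mean slightly toward zero for true slopes away from zero.
* The two variants are not "pooled vs unpooled" versions of one another:
  the two-polarities model's N(gamma, 0.1) slope prior is far tighter
  than the one-disease model's U(-1, 1). Data whose slopes cluster around
  a common centre — including cohorts generated here with equal gamma for
  both polarities — is therefore often *better* predicted by the
  two-polarities variant, and an information-criterion preference between
  them reflects prior structure as much as any polarity dependence.
* BFMI depends on the tail weight of the energy distribution, which the
  heavy-tailed subject noise scales (inverse gamma on sigma) inflate;
  min-BFMI on synthetic cohorts sits near the 0.75 boundary and varies by
  seed.
* The dense-metric NUTS implementation targets this model family's scale
  (tens to low hundreds of parameters); it makes no claims of efficiency
  for very high-dimensional targets.
* Sleep detection is out of scope: supplied sleep intervals are honoured,
  otherwise the whole 22:00–05:00 window counts as sleep.
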