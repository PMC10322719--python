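# Methods

This note documents the models, procedures, numerical choices and
limitations of `patchpop`. The package reimplements, on synthetic data, an
analysis pipeline for (a) classifying hypothalamus→habenula (LHA–LHb)
projection neurons from whole-cell current-clamp recordings and (b)
quantifying aversive-state signals in prefrontal-cortex (PFC) population
recordings collected during a four-block head-fixed task.

## 1. Synthetic current-clamp sweeps (`patchpop.simulate`)

Real neurons are not available here, so every sweep is generated by an
adaptive exponential integrate-and-fire (AdEx) model with a stereotyped
action-potential (AP) waveform template spliced in at each spike-trigger
crossing. The subthreshold dynamics are

    C dV/dt = −g_L (V − E_L) + g_L Δ_T exp((V − V_T)/Δ_T) − w + I(t)
    τ_w dw/dt = a (V − E_L) − w,   w → w + b at each spike,

with two optional transient currents recruited at the onset of a
depolarizing step: an inward current (amplitude `burst_g_pa`, decay
`burst_tau_ms`) that produces doublet/triplet onsets in the bursting
archetype, and an outward current (`latency_g_pa`, `latency_tau_ms`) that
delays the first spike in the late-spiking archetypes. A bare
integrate-and-fire trace has no AP shape, but half of the extracted
parameters are waveform parameters (half-width, up/downstroke,
afterpotentials); the template supplies them. The template is a
cosine-shaped rise and fall followed by either a monotone ("convex")
afterhyperpolarization or an afterdepolarization (ADP) hump and a deeper
("concave") AHP, with exponential recovery; its tail is cross-faded into
the underlying AdEx trace so trains remain continuous.

Six archetypes (FA-Bk, Burst, RS-N, LS-N, LS-W, RS-W) are defined by the
parameter table in `simulate.ARCHETYPES`. The qualitative phenotypes — fast
adaptation with deep fast AHP, onset bursting with ADP, regular spiking
with narrow or wide APs, late spiking — and spontaneous tonic firing of
every type are the constraints; the numeric values (capacitance 55–100 pF,
leak 2.5–4.5 nS, thresholds −45 to −41 mV, adaptation increments 8–60 pA,
tonic rates 3–10 Hz, AP rise/fall 0.35–1.7 ms) are the package's own
choices, tuned once so that rheobase falls in 60–140 pA from a −70 mV
holding potential and the depolarizing ladder (20–320 pA in 20 pA steps)
contains rheobase, twice rheobase and a maximal-frequency sweep for every
type. Per-neuron variability: multiplicative jitter (CV 0.07) on scale
parameters and additive jitter (s.d. 1.2 mV) on voltage parameters.

The spontaneous (cell-attached-like) trace is a gamma-renewal pacemaker
(ISI CV 0.25) at the neuron's tonic rate with the same AP template spliced
onto a noisy baseline; the AdEx equations are used for all current-step
sweeps. Integration is forward Euler at the protocol's sampling interval
(default 20 kHz, dt = 0.05 ms) with the exponential term clipped at 8 Δ_T
and a 1.5 ms absolute refractory period; a test verifies spike-count
agreement against an independent pure-Python integration at 10× finer dt.
All randomness flows through one `numpy` generator per call, so identical
seed and configuration give bit-identical traces and serialized files.

## 2. Intrinsic-feature extraction (`patchpop.features`)

Definitions follow standard current-clamp practice:

* spike detection: voltage peak above −10 mV with a dV/dt excursion above
  10 mV/ms in the preceding 2 ms; peaks within 1 ms merge;
* AP threshold: first sample (searching backward from the peak) at which
  dV/dt ≥ 10 mV/ms (central differences);
* rise time: threshold→peak; half-width: width at threshold + amplitude/2
  with linear interpolation at the crossings; up/downstroke: extrema of the
  derivative;
* afterpotentials: analyzed on the 30 ms after the peak (truncated at the
  next spike), lightly smoothed (Gaussian, 0.15 ms). A rebound of ≥ 0.5 mV
  above the running minimum that is itself followed by a ≥ 0.5 mV decline
  is an ADP followed by a concave AHP (ADP measured fast-trough→ADP-peak,
  concave AHP ADP-peak→subsequent trough); otherwise the segment is a
  convex AHP measured from the AP threshold to the segment minimum. The
  reference points for the two AHP amplitudes are a package choice;
* input resistance: least-squares slope of steady-state ΔV (mean over the
  last 100 ms of the step, a package choice — the transient has decayed for
  τ ≤ 25 ms) against ΔI over the ±20 pA sweeps;
* membrane τ: single-exponential fit (Levenberg–Marquardt) to the averaged
  −40 pA onset transient (first 150 ms); failures are flagged, not zeroed;
* train features: rheobase = smallest ladder amplitude evoking ≥ 1 AP; AP
  counts split at 500 ms of the 1-s step; first/second ISIs reported as
  instantaneous frequencies at twice rheobase and at the maximal-count
  sweep; adaptation ratios oriented last/first and last/second (the
  orientation is configurable since the verbal definition is ambiguous);
  firing frequency = spike count per second at twice rheobase; post-step
  deflection = mean voltage in the 150 ms after step offset minus the
  pre-step baseline.

Missing features are NaN plus a flag; imputation (absence → 0) is an
explicit opt-in step before clustering, never a default.

## 3. Consensus cell typing (`patchpop.celltypes`)

Normalization (dataset-level, column-wise): shift positive by the minimum,
divide by the column sum and scale by 10,000, log(1 + x), z-score.
Constant columns would be 0/0 and are set to all-zero with a warning.
PCA (deterministic sign: largest-magnitude loading positive) retains four
components. Two labelings are computed: a Ward tree cut into six flat
clusters, and communities of a shared-nearest-neighbor graph (k = 20,
Jaccard edge weights, ties broken by index order) found by a seeded
resolution-1.5 modularity partition (Leiden implementation of the
Louvain-family objective; the pure-Louvain package is not a dependency).
Graph labels are mapped onto tree labels by maximum-overlap Hungarian
matching on the contingency table; cells on which the two labelings agree
keep the consensus label, all others are DISCARDED (−1).

Agreement with a reference labeling is the percentage of (non-discarded)
cells matching after one Hungarian alignment; the chance level shuffles the
labels 10,000 times and re-scores them **under the fixed alignment** — this
makes the expected chance equal the closed form Σᵢ pᵢ qᵢ for independent
labelings, which re-matching per shuffle would inflate. The 2-D t-SNE
embedding (perplexity 30, seeded, PCA initialization) is for reporting
only and falls back to PC1/PC2 below 3 × perplexity points.

Soma morphometry: E = X/Y over the two perpendicular major axes, T =
Ymajor/Yminor over the 25%/75% axes; T ≥ 1.2 → triangular, otherwise
E ≥ 1.8 → elongated, else round.

## 4. Synthetic population recordings

A four-block task is simulated: 200-ms tone at trial start (blocks 1–3), a
500-ms optogenetic train starting 500 ms after tone end (block 2 only), a
200-ms blue-noise sound (block 4) followed 500 ms later by a 50-ms air
puff. Default block sizes 50/100/50/50 trials. Each unit is an
inhomogeneous Poisson process whose rate is baseline × block-multiplier ×
Π(event gains over active windows) — i.e. the log-rate is linear in the
event indicators, exactly the generative form the event GLM assumes.
Spikes are drawn exactly (per-segment Poisson counts, uniform times within
segments), then thinned with a 2.5-ms absolute refractory period so that
synthetic units satisfy the pipeline's own ISI-violation criterion; the
thinning costs ~1–3% of spikes at typical rates and can be disabled
(`refractory_s=0`) where an exact Poisson process is required. Ground-truth
gains and block multipliers are stored for recovery tests. What this
generator does **not** emulate: bursting/autocorrelated spike trains, rate
drift within blocks, correlated noise across units, and electrode artifacts
— calibration results transfer to real data only insofar as those features
do not dominate.

## 5. Single-unit tuning (`patchpop.tuning`)

QC keeps units with mean rate > 0.1 Hz and < 1% of ISIs below a 2-ms
refractory bound (the bound is configurable; the criterion states only the
percentage). Clock drift between acquisition devices is removed by a
least-squares linear map fitted on sync-event pairs.

The event GLM bins spikes at 100 ms and regresses counts on four indicator
regressors (tone, 200 ms; opto, 500 ms; blue noise, 200 ms; air puff,
500 ms — windows from each event onset; fractional bin coverage at window
borders) with a Poisson family, log link and intercept, via statsmodels.
The surrogate null circularly rotates the **binned count vector** by a
uniform random offset per surrogate (counts, marginals and autocorrelation
preserved; event alignment broken) and refits; 1,000 surrogates per unit.
Because 1,000 statsmodels fits per unit are prohibitively slow, the
surrogate refits use an in-package batched Newton/IRLS solver that fits all
rotated responses against the shared design in a few BLAS products per
iteration; it is verified against statsmodels to 1e-7 and freezes converged
columns. Surrogates with complete separation on a sparse regressor (MLE at
−∞) stop at the iteration cap with a very negative coefficient — this only
affects the extreme negative tail of the null.

Tuning score = (β − null mean)/null s.d.; a unit is positively tuned iff
β exceeds the 99.9th percentile of its own null and negatively iff below
the 0.01th percentile (the flag is percentile-based, not z-based);
primary/secondary tuning rank |score|; comodulated = primary and secondary
are the opto and air-puff regressors, both significant. By rank
exchangeability the positive rule fires on unmodulated units at ≈ 0.1%,
which the suite verifies on 2,000 simulated units (on a scaled-down
25-trial session — the calibration is session-size free).

Conditioned units: four paired Wilcoxon signed-rank tests (tone and opto in
block 2; blue noise and air puff in block 4), each comparing the 500-ms
pre-sound baseline rate to the 500-ms post-event rate over 50 trials; the
block-2 pool is brought to 50-trial parity by deterministically keeping
every other trial. Conditioned in a block iff both of its tests pass the
Bonferroni-corrected α = 0.001/4.

Optotagging: tagged iff (a) a spike occurs in the 10-ms bin after > 10% of
pulses, (b) the spike-latency test is significant at 1%, and (c) mean
evoked and spontaneous waveforms correlate at r > 0.9. The latency test is
an in-package permutation test (the published stimulus-associated latency
test is external software): statistic = mean first-spike latency after each
pulse capped at 50 ms; null = circular rotations of the spike train
(equivalently, of the pulses). With the default 199 permutations the
smallest attainable p is 1/200 = 0.005, so the 1% test is conservative by
construction — expected false-positive rate 0.5% — rather than sitting
exactly at its nominal level; the suite measures ≤ 1% on 2,000
laser-independent units.

## 6. Population dynamics (`patchpop.popdyn`)

Activity matrices are trial-averaged rates per block on a half-open bin
grid aligned to trial onset (default (−0.1 s, 3 s) at 10 ms → 310 bins),
Gaussian-smoothed along time (σ in bins; reflect boundary; the smoothing
equals explicit convolution with a normalized 4σ-truncated kernel to
1e-12), then normalized per the calling analysis: global per-unit z-score
(activity clustering, PC trajectories), per-unit mean subtraction (modes),
or per-block baseline z (reporting only).

Activity clustering excludes units with fewer than 200 bins at ≥ 0.5 Hz
("active" is read as at-or-above the rate threshold, since the verbatim
inequality as printed would exclude almost everything), applies PCA, Ward
linkage on the top-20 PC scores, and cuts the tree into a configurable
number of flat clusters (default 15, matching the reported cluster count;
the alternative "depth of ten children" reading of the cut rule is
documented but not the default because a flat-cluster count is reproducible
and parameterized). Clusters are named by the dominant primary tuning of
their units, overridden to "state" when the cluster's pre-sound baseline
rates shift significantly across blocks (Wilcoxon, Bonferroni over blocks).

Activity modes: on a 50-ms-bin, mean-subtracted matrix whose window covers
a 1-s pre-sound baseline, one linear SVM (C = 1, class-balanced,
hinge-loss family; libsvm implementation for determinism) is trained per
contrast on time-bin samples: sound (200 ms post-onset vs the 200 ms
before, blocks 1–3), aversive (either pooled opto+air-puff epochs vs
baseline — the "OR" mode, default — or opto epoch vs air-puff epoch, the
"AND" mode; the source description is ambiguous between the two, so both
are implemented), and state (1-s baselines of block 1 vs block 4). The
three weight vectors are orthogonalized by QR (signs oriented along the raw
vectors); projections are WᵀX per block, with unit-row restriction for
per-genotype/region readouts. WᵀW = I to 1e-8 by construction.

Decoding: spike counts in (−2.1, −0.1) s before trial onset at 100 ms,
concatenated across the two blocks, z-scored within unit, units with no
baseline spikes removed; for each subset size (5–150, truncated at the
population), 50 repeats of a stratified twofold split over time bins with
an L2 logistic regression (default regularization), both folds scored and
averaged. Chance is 50%; the suite verifies chance-level accuracy on
statistically identical blocks at every subset size.

PC trajectories: per block, PCA (3 components) on the pooled units × time
matrix (balanced random subsets of 550 units per genotype when available,
else all with a warning); per-genotype trajectories re-project each
genotype's activity on its own rows of the loading matrix. Trajectories
are checked for stability across subsampling seeds.

## 7. Estimation statistics (`patchpop.stats`)

`bootstrap_mean_difference` resamples both groups with replacement (5,000
resamples), reports the percentile 95% CI of mean(b) − mean(a), and a
two-sided permutation p — the fraction of group-label shuffles whose mean
difference is at least as extreme as the observed one. The alternative
"proportion of shuffled comparisons outside the CI" reading was rejected:
it is not uniform under the null (it concentrates near 0.05) and it would
approach 1, not 0, for a strong effect; the implemented p satisfies both
requirements and is the standard estimation-graphics companion statistic.
Coverage of the CI is verified over 1,000 Gaussian simulations; note that
percentile bootstrap intervals for a mean difference undercover mildly at
n = 20 per group (~93–94% observed), a known small-sample property of the
bootstrap rather than an implementation artifact.

The stress index (SI) combines marble burying, looming-evoked aversive
time and forced-swim immobility. No formula is published for it; the
package uses the equal-weight mean of the three component z-scores against
the control cohort (weights configurable), which is monotone in every
component. Whether normalization is pooled or within-sex is exposed as a
switch (`by="sex"`); no claim is made about the original choice.

## 8. Problem sizes and determinism

Default study sizes were chosen once: cohorts of 40 neurons per archetype
(240 cells) for typing; 40–150 units and 50–100 trials per block for
population analyses; 1,000 surrogates per unit; 2,000 units for the two
false-positive calibrations (the surrogate-GLM calibration uses a 25-trial
session, since its guarantee does not depend on session length); 1,000
simulations for bootstrap coverage. Every stochastic routine takes a seed
and threads it through a single `numpy` generator; serialized outputs are
byte-identical across runs with the same seed.

## 9. Known limitations

* The AdEx + template generator reproduces phenotypes, not biophysics; its
  parameters are not fitted to any recorded neuron, and conclusions about
  classifier accuracy on real LHA–LHb recordings do not follow.
* The latency permutation test replaces the published external latency
  test; it is calibrated (≤ 1% false positives) but not equivalent.
* Poisson surrogate units are renewal processes; heavily bursty real units
  would widen circular-shift nulls and change flag rates.
* The "20 PCA-selected parameters" used for typing in the original study
  are not enumerated anywhere; the package computes the full parameter set
  and exposes feature selection as configuration.
* t-SNE coordinates are for visualization; no quantitative claim depends
  on them.
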