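# patchpop

Multimodal classification of patch-clamp-recorded neurons and analysis of
aversive-state signals in population spike recordings — implemented end to
end on synthetic data.

## The problem

Excitatory projections from the lateral hypothalamic area (LHA) to the
lateral habenula (LHb) drive aversive behavior, and the pathway contains
several electrophysiologically distinct neuron types (fast-adapting,
bursting, regular- and late-spiking with narrow or wide action potentials).
Classifying these types requires extracting a standardized panel of
intrinsic parameters from current-clamp sweeps — tonic rate, input
resistance, membrane time constant, AP threshold/rise/half-width/strokes,
afterpotential amplitudes, rheobase-anchored train statistics — and
combining two unsupervised clusterings (Ward hierarchy and graph
communities on a shared-nearest-neighbor graph, both on the first four PCs
of the normalized feature matrix) into a consensus: cells on which the two
methods disagree are discarded.

Downstream, prefrontal-cortex population recordings during a four-block
task (tone / tone + optogenetic drive of the pathway / tone / noise + air
puff) are analyzed per unit with a Poisson event GLM whose coefficients are
scored against circular-shift surrogate nulls (tuning score
z = (β − null mean)/null s.d., significance at the 99.9th/0.01th null
percentiles), and per population with activity-mode decomposition (linear
SVM weight vectors for sound / aversive / state contrasts, orthogonalized
by QR into W, read out as WᵀX), cross-validated logistic-regression
decoding of block identity from pre-trial baselines, and PC trajectories.
Bootstrap mean-difference estimation (Gardner–Altman style) and a
behavioral stress-index composite round out the statistics.

No recorded data ship with the package: a fully specified generator
produces AdEx-based current-clamp sweeps for six archetypes (with spliced
AP waveform templates so waveform features are defined), block-structured
Poisson spike trains whose log-rate is linear in the event indicators
(matching the GLM's assumption), and soma-axis tables. Every analysis is
validated against these generators — recovery of known labels and gains,
and calibration of every significance rule. See `docs/methods.md` for the
models and all numerical choices.

## Worked example

Simulate a cohort of 120 neurons (20 per archetype), extract the intrinsic
feature panel, and run the consensus typing:

```python
from patchpop.calibration import archetype_recovery

print(archetype_recovery(seed=0, n_per_type=20))
```

```
{'ari': 0.9240075211977152, 'n_discarded': 1, 'n_cells': 120}
```

The consensus labels match the generative archetypes with an adjusted Rand
index of 0.92; one cell of 120 is discarded because the two clustering
methods disagree on it.

Simulate a 20-unit population in which 8 units carry a multiplicative
optogenetic gain of e^0.9 in block 2, then run the tuning pipeline (GLM +
1,000 circular-shift surrogates per unit):

```python
import numpy as np
from patchpop.simulate import PopulationDesign, simulate_population
from patchpop.tuning import tune_units

gains = np.ones((20, 4)); gains[:8, 1] = np.exp(0.9)
ds = simulate_population(PopulationDesign(
    n_units=20, block_trials=(10, 20, 10, 10), trial_length_s=4.0,
    pre_s=2.5, baseline_hz=6.0, gains=gains, seed=0))
run = tune_units(ds, n_surrogates=1000, seed=0)
print(run.table.loc[[0, 12], ["unit_id", "beta_opto", "score_opto",
                              "pos_opto", "primary"]].to_string(index=False))
```

```
 unit_id  beta_opto  score_opto  pos_opto primary
       0   0.778729    3.925542      True    opto
      12   0.046974    0.380086     False  sound1
```

Unit 0 (a true opto unit) recovers β ≈ 0.78 for a true log-gain of 0.9,
scores ~3.9 null standard deviations above its surrogate null and is
flagged positively tuned; unit 12 (untuned) is not. Exactly the 8
modulated units are flagged in this run.

A command-line interface mirrors the library
(`patchpop sim traces|population|soma`, `patchpop features`,
`patchpop cluster`, `patchpop tune`, `patchpop modes`, `patchpop decode`,
`patchpop effect`, `patchpop stress-index`); all inputs and outputs are
delimited text plus JSON manifests.

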