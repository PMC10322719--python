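"""Calibration and recovery studies run on the package's own generators.

These functions reproduce the pipeline's statistical guarantees under fully
specified synthetic conditions: chance-level decoding when no signal exists,
bootstrap CI coverage, false-positive rates of the optotag latency test and
of the circular-shift tuning rule, GLM coefficient recovery, and archetype
recovery by consensus clustering.  They are what the validation suite and
the reproduction script execute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .celltypes import DISCARDED, ConsensusClusterer, normalize_features
from .features import extract_feature_table
from .popdyn import decode_block_identity
from .simulate import (ARCHETYPES, PopulationDesign, ProtocolSpec, archetype,
                       simulate_population, simulate_sweep_set)
from .stats import bootstrap_mean_difference
from .tuning import (batched_poisson_irls, bin_spikes, build_design,
                     circular_shift_null, fit_event_glm, latency_test)

__all__ = [
    "decoding_chance",
    "bootstrap_coverage",
    "optotag_false_positive_rate",
    "tuning_null_false_positive_rate",
    "glm_opto_recovery",
    "archetype_recovery",
]


def decoding_chance(seed: int = 0, n_units: int = 40, n_trials: int = 50,
                    baseline_hz: float = 5.0, subset_sizes=range(5, 41, 5),
                    repeats: int = 50) -> pd.DataFrame:
    """Block-identity decoding when the two blocks are statistically
    identical: homogeneous Poisson baselines, no events in the decoded
    baseline window.  Returns the accuracy curve (chance = 0.5)."""
    design = PopulationDesign(n_units=n_units,
                              block_trials=(n_trials, n_trials, 2, 2),
                              trial_length_s=6.0, pre_s=3.0,
                              baseline_hz=baseline_hz, seed=seed)
    ds = simulate_population(design)
    return decode_block_identity(ds, blocks=(1, 2),
                                 subset_sizes=list(subset_sizes),
                                 repeats=repeats, seed=seed)


def bootstrap_coverage(seed: int = 0, n_sim: int = 1000, n: int = 20,
                       delta: float = 1.0, sigma: float = 1.0,
                       n_boot: int = 5000) -> float:
    """Fraction of simulations whose bootstrap 95% CI covers the true mean
    difference (Gaussian groups)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        a = rng.normal(0.0, sigma, n)
        b = rng.normal(delta, sigma, n)
        est = bootstrap_mean_difference(a, b, n_boot=n_boot, n_perm=0,
                                        seed=int(rng.integers(2**31)))
        hits += int(est.ci_low <= delta <= est.ci_high)
    return hits / n_sim


def optotag_false_positive_rate(seed: int = 0, n_units: int = 2000,
                                duration_s: float = 1200.0,
                                n_pulses: int = 100, n_perm: int = 199,
                                alpha: float = 0.01) -> float:
    """Latency-test flag rate on units whose homogeneous Poisson spiking
    (rates 1-10 Hz) is independent of the laser pulses."""
    rng = np.random.default_rng(seed)
    flagged = 0
    for _ in range(n_units):
        rate = rng.uniform(1.0, 10.0)
        n_sp = rng.poisson(rate * duration_s)
        spikes = np.sort(rng.uniform(0.0, duration_s, n_sp))
        pulses = np.sort(rng.uniform(5.0, duration_s - 5.0, n_pulses))
        p = latency_test(spikes, pulses, duration_s, n_perm=n_perm,
                         seed=int(rng.integers(2**31)))
        flagged += int(p < alpha)
    return flagged / n_units


def tuning_null_false_positive_rate(seed: int = 0, n_units: int = 2000,
                                    n_surrogates: int = 1000,
                                    baseline_hz: float = 5.0,
                                    regressor: str = "opto") -> float:
    """Positive-flag rate of the 99.9th-percentile circular-shift rule on
    unmodulated units (no event tuning)."""
    design = PopulationDesign(n_units=1, block_trials=(5, 10, 5, 5),
                              trial_length_s=2.5, pre_s=1.0,
                              baseline_hz=baseline_hz, seed=seed)
    ds = simulate_population(design)
    edges, X, names = build_design(ds)
    j = names.index(regressor)
    rng = np.random.default_rng(seed)
    flagged = 0
    for _ in range(n_units):
        n_sp = rng.poisson(baseline_hz * ds.duration_s)
        spikes = np.sort(rng.uniform(0.0, ds.duration_s, n_sp))
        y = bin_spikes(spikes, edges)
        beta, _ = batched_poisson_irls(y, X)
        null = circular_shift_null(y, X, n=n_surrogates,
                                   seed=int(rng.integers(2**31)))
        flagged += int(beta[1 + j, 0] > np.nanpercentile(null[:, j], 99.9))
    return flagged / n_units


def glm_opto_recovery(seed: int = 0, n_units: int = 100,
                      log_gain: float = 0.8,
                      baseline_hz: float = 6.0) -> dict:
    """Recover the true multiplicative opto gain e^log_gain from simulated
    units; returns the mean recovered coefficient and its standard error."""
    gains = np.ones((n_units, 4))
    gains[:, 1] = np.exp(log_gain)
    design = PopulationDesign(n_units=n_units, block_trials=(10, 20, 10, 10),
                              trial_length_s=3.0, pre_s=1.0,
                              baseline_hz=baseline_hz, gains=gains,
                              refractory_s=0.0, seed=seed)
    ds = simulate_population(design)
    edges, X, names = build_design(ds)
    j = names.index("opto")
    betas = np.empty(n_units)
    for u in range(n_units):
        fit = fit_event_glm(bin_spikes(ds.spikes[u], edges), X)
        betas[u] = fit["beta"][j]
    return {"mean": float(betas.mean()),
            "sem": float(betas.std(ddof=1) / np.sqrt(n_units)),
            "true": log_gain}


def archetype_recovery(seed: int = 0, n_per_type: int = 40,
                       protocol: ProtocolSpec | None = None,
                       jitter_scale: float = 1.0) -> dict:
    """Simulate a full cohort, extract features, run consensus clustering and
    score recovery of the generative archetype labels (ARI on retained
    cells)."""
    protocol = protocol or ProtocolSpec()
    rng = np.random.default_rng(seed)
    sets, labels = [], []
    for name in ARCHETYPES:
        for _ in range(n_per_type):
            sets.append(simulate_sweep_set(archetype(name), protocol,
                                           seed=int(rng.integers(2**31)),
                                           jitter_scale=jitter_scale))
            labels.append(name)
    df = extract_feature_table(sets, labels=labels)
    X = normalize_features(df.drop(columns="label").fillna(0.0).to_numpy())
    cc = ConsensusClusterer(random_state=seed).fit(X)
    ref = pd.Categorical(df["label"]).codes
    keep = cc.labels_ != DISCARDED
    ari = adjusted_rand_score(ref[keep], cc.labels_[keep]) if keep.any() else 0.0
    return {"ari": float(ari), "n_discarded": cc.n_discarded_,
            "n_cells": len(labels)}
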