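"""Estimation statistics: bootstrap mean-difference effect sizes
(Gardner–Altman style) and the behavioral stress-index composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

__all__ = ["EffectEstimate", "bootstrap_mean_difference", "stress_index"]


@dataclass
class EffectEstimate:
    """Bootstrap estimate of a two-group mean difference."""

    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    bootstrap: np.ndarray
    n_a: int
    n_b: int
    n_boot: int
    ci_level: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"mean_difference": self.mean_difference, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "p_value": self.p_value,
                "n_a": self.n_a, "n_b": self.n_b, "n_boot": self.n_boot,
                "ci_level": self.ci_level, "seed": self.seed}


def bootstrap_mean_difference(a, b, n_boot: int = 5000, ci: float = 95.0,
                              n_perm: int = 5000,
                              seed: int | None = 0) -> EffectEstimate:
    """Bootstrap the mean difference mean(b) − mean(a).

    Groups are resampled with replacement independently; the percentile
    interval of the ``n_boot`` resampled differences gives the CI.  The
    p-value is the two-sided permutation proportion: the fraction of
    group-label shuffles whose mean difference is at least as extreme as the
    observed one (``n_perm=0`` skips it, p = NaN).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("each sample needs n >= 3")
    rng = np.random.default_rng(seed)
    obs = float(b.mean() - a.mean())
    boots = (b[rng.integers(0, len(b), size=(n_boot, len(b)))].mean(axis=1)
             - a[rng.integers(0, len(a), size=(n_boot, len(a)))].mean(axis=1))
    lo, hi = np.percentile(boots, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    n_a = len(a)
    if n_perm > 0:
        pooled = np.concatenate([a, b])
        perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
        perm_diffs = perms[:, n_a:].mean(axis=1) - perms[:, :n_a].mean(axis=1)
        p = float(np.mean(np.abs(perm_diffs) >= abs(obs)))
    else:
        p = float("nan")
    return EffectEstimate(mean_difference=obs, ci_low=float(lo), ci_high=float(hi),
                          p_value=p, bootstrap=boots, n_a=n_a, n_b=len(b),
                          n_boot=n_boot, ci_level=ci, seed=seed)


STRESS_COMPONENTS = ("marble_burying", "looming_aversive_s", "fst_immobility_s")


def stress_index(components: pd.DataFrame, reference: pd.DataFrame,
                 columns=STRESS_COMPONENTS, weights=None,
                 by: str | None = None) -> pd.Series:
    """Composite stress index: weighted mean of component z-scores.

    Each behavioral component (marble burying count, looming-evoked aversive
    time, forced-swim immobility) is z-scored against the reference (control)
    cohort; the SI is the weighted mean of the z-scores (equal weights by
    default), so it is monotonically non-decreasing in every component.
    ``by`` optionally normalizes within a grouping column (e.g. sex) present
    in both tables.  Animals with a missing component get NaN.
    """
    cols = list(columns)
    for c in cols:
        if c not in components or c not in reference:
            raise InsufficientDataError(f"missing component column {c!r}")
    w = np.ones(len(cols)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(cols) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with a positive sum")
    w = w / w.sum()

    def _si(comp: pd.DataFrame, ref: pd.DataFrame) -> pd.Series:
        mu = ref[cols].mean()
        sd = ref[cols].std(ddof=1).replace(0.0, np.nan)
        z = (comp[cols] - mu) / sd
        return z.mul(w, axis=1).sum(axis=1, skipna=False)

    if by is None:
        return _si(components, reference).rename("stress_index")
    out = pd.Series(np.nan, index=components.index, name="stress_index")
    for g, comp_g in components.groupby(by):
        ref_g = reference[reference[by] == g]
        if len(ref_g) < 2:
            raise InsufficientDataError(f"reference cohort for group {g!r} too small")
        out.loc[comp_g.index] = _si(comp_g, ref_g)
    return out
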