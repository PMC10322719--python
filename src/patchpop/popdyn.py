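"""Population-level analyses: trial-averaged activity matrices, activity
clustering, activity-mode decomposition, block-identity decoding and PC
trajectories.

Conventions: spikes are binned per trial relative to trial onset (half-open
bins), averaged across the trials of each block, optionally smoothed with a
Gaussian kernel and normalized per unit.  Activity modes are linear-SVM
weight vectors for task contrasts, orthogonalized jointly by QR; population
activity is read out as the projection WᵀX.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter1d
from scipy.stats import wilcoxon
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .errors import InsufficientDataError
from .simulate import SpikeDataset

__all__ = [
    "ActivityMatrix",
    "build_activity_matrix",
    "activity_cluster",
    "ModeSet",
    "ActivityModes",
    "compute_activity_modes",
    "decode_block_identity",
    "pca_trajectories",
    "gaussian_smooth",
]


def gaussian_smooth(x: np.ndarray, sigma_bins: float, axis: int = -1) -> np.ndarray:
    """Gaussian smoothing along one axis (truncated at 4σ, reflect padding)."""
    if sigma_bins <= 0:
        return np.asarray(x, dtype=float)
    return gaussian_filter1d(np.asarray(x, dtype=float), sigma_bins, axis=axis,
                             mode="reflect")


@dataclass
class ActivityMatrix:
    """Trial-averaged rates: units × blocks × time bins, plus metadata."""

    data: np.ndarray          # (n_units, n_blocks, n_bins) after normalization
    rates: np.ndarray         # raw trial-averaged rates (Hz), same shape
    bin_s: float
    window_s: tuple
    sigma_bins: float
    normalization: str
    unit_ids: list
    units: pd.DataFrame
    blocks: list

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    def flat(self) -> np.ndarray:
        """units × (blocks·bins) view of the normalized data."""
        return self.data.reshape(self.n_units, -1)

    def time_axis(self) -> np.ndarray:
        return self.window_s[0] + (np.arange(self.n_bins) + 0.5) * self.bin_s


def build_activity_matrix(dataset: SpikeDataset, unit_ids=None,
                          window_s: tuple = (-0.1, 3.0), bin_s: float = 0.01,
                          sigma_bins: float = 2.0,
                          normalization: str = "zscore",
                          blocks=None) -> ActivityMatrix:
    """Trial-averaged activity matrix aligned to trial onsets.

    ``normalization``: ``"zscore"`` (per unit across all blocks, after
    smoothing), ``"mean-sub"`` (subtract the per-unit mean across blocks, the
    activity-mode convention), ``"baseline-z"`` (z to the per-block
    pre-onset baseline, reporting convention) or ``"none"``.
    """
    if unit_ids is None:
        unit_ids = dataset.unit_ids
    if blocks is None:
        blocks = sorted(dataset.trials["block"].unique())
    blocks = list(blocks)
    n_bins = int(round((window_s[1] - window_s[0]) / bin_s))
    edges = window_s[0] + np.arange(n_bins + 1) * bin_s
    rates = np.zeros((len(unit_ids), len(blocks), n_bins))
    for bi, b in enumerate(blocks):
        onsets = dataset.trials.loc[dataset.trials["block"] == b, "t_start_s"].to_numpy()
        if len(onsets) == 0:
            raise InsufficientDataError(f"block {b} has no trials")
        for ui, uid in enumerate(unit_ids):
            sp = dataset.spikes[uid]
            counts = np.zeros(n_bins)
            for t0 in onsets:
                idx0 = np.searchsorted(sp, t0 + edges)
                counts += np.diff(idx0)
            rates[ui, bi] = counts / (len(onsets) * bin_s)
    smoothed = gaussian_smooth(rates, sigma_bins, axis=2) if sigma_bins > 0 else rates
    if normalization == "zscore":
        flat = smoothed.reshape(len(unit_ids), -1)
        mu = flat.mean(axis=1, keepdims=True)
        sd = flat.std(axis=1, keepdims=True)
        data = ((flat - mu) / np.where(sd > 0, sd, 1.0)).reshape(smoothed.shape)
    elif normalization == "mean-sub":
        flat = smoothed.reshape(len(unit_ids), -1)
        data = (flat - flat.mean(axis=1, keepdims=True)).reshape(smoothed.shape)
    elif normalization == "baseline-z":
        n_base = max(int(round(-window_s[0] / bin_s)), 1)
        base = smoothed[:, :, :n_base]
        mu = base.mean(axis=2, keepdims=True)
        sd = base.std(axis=2, keepdims=True)
        data = (smoothed - mu) / np.where(sd > 0, sd, 1.0)
    elif normalization == "none":
        data = smoothed.copy()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    units = dataset.units[dataset.units["unit_id"].isin(unit_ids)].reset_index(drop=True)
    return ActivityMatrix(data=data, rates=rates, bin_s=bin_s, window_s=window_s,
                          sigma_bins=sigma_bins, normalization=normalization,
                          unit_ids=list(unit_ids), units=units, blocks=blocks)


# ---------------------------------------------------------------------------
# activity clustering
# ---------------------------------------------------------------------------


def activity_cluster(matrix: ActivityMatrix, tuning_table: pd.DataFrame | None = None,
                     n_clusters: int = 15, n_pcs: int = 20,
                     min_active_bins: int = 200, active_rate_hz: float = 0.5,
                     baseline_alpha: float = 0.05) -> dict:
    """Ward clustering of per-unit activity profiles on top PC loadings.

    Units with fewer than ``min_active_bins`` bins at or above
    ``active_rate_hz`` (raw trial-averaged rate) are excluded first.  The
    Ward tree over the top ``n_pcs`` PC scores is cut into ``n_clusters``
    flat clusters.  When a tuning table is supplied, each cluster is named by
    the dominant primary tuning of its units; clusters whose units show a
    significant cross-block baseline shift (Wilcoxon signed-rank, Bonferroni
    over blocks) are named ``state``.
    """
    active = (matrix.rates >= active_rate_hz).reshape(matrix.n_units, -1).sum(axis=1)
    keep = active >= min_active_bins
    if keep.sum() < max(n_pcs, 20):
        raise InsufficientDataError(
            f"only {int(keep.sum())} units pass the activity filter; need >= {max(n_pcs, 20)}")
    X = matrix.flat()[keep]
    n_pcs_eff = min(n_pcs, X.shape[0] - 1, X.shape[1])
    scores = PCA(n_components=n_pcs_eff, svd_solver="full").fit_transform(X)
    if np.allclose(scores, 0):
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        labels = fcluster(linkage(scores, method="ward"), t=n_clusters,
                          criterion="maxclust") - 1
    out = {"kept": keep, "labels": labels, "unit_ids":
           [u for u, k in zip(matrix.unit_ids, keep) if k]}
    if tuning_table is not None:
        out["names"] = _name_clusters(matrix, out, tuning_table, baseline_alpha)
    return out


def _name_clusters(matrix: ActivityMatrix, clust: dict,
                   tuning_table: pd.DataFrame, alpha: float) -> dict:
    """Name clusters by dominant primary tuning; 'state' overrides when the
    cluster's baseline rates differ significantly across blocks."""
    tt = tuning_table.set_index("unit_id") if "unit_id" in tuning_table else tuning_table
    n_base = max(int(round(-matrix.window_s[0] / matrix.bin_s)), 1)
    kept_idx = np.nonzero(clust["kept"])[0]
    names = {}
    n_blocks = matrix.rates.shape[1]
    n_tests = n_blocks - 1
    for c in np.unique(clust["labels"]):
        rows = kept_idx[clust["labels"] == c]
        uids = [matrix.unit_ids[i] for i in rows]
        base = matrix.rates[rows, :, :n_base].mean(axis=2)  # units x blocks
        state = False
        for b in range(1, n_blocks):
            d = base[:, b] - base[:, 0]
            if len(d) >= 5 and not np.allclose(d, 0):
                try:
                    p = wilcoxon(d).pvalue
                except ValueError:
                    continue
                if p < alpha / n_tests:
                    state = True
                    break
        if state:
            names[int(c)] = "state"
            continue
        prim = [tt.loc[u, "primary"] for u in uids if u in tt.index
                and isinstance(tt.loc[u, "primary"], str)]
        names[int(c)] = (pd.Series(prim).mode().iloc[0] if prim else "unnamed")
    return names


# ---------------------------------------------------------------------------
# activity modes
# ---------------------------------------------------------------------------


@dataclass
class ModeSet:
    """Orthogonalized mode weights and projections."""

    W: np.ndarray                 # (n_units, n_modes), WᵀW = I
    mode_names: list
    raw_vectors: np.ndarray       # pre-QR SVM weight vectors (n_units, n_modes)
    projections: dict             # block -> (n_modes, n_bins)
    bin_s: float
    unit_ids: list
    meta: dict = field(default_factory=dict)

    def project(self, matrix: ActivityMatrix, rows=None) -> dict:
        """WᵀX per block; ``rows`` restricts units (weight rows + data rows)."""
        W = self.W if rows is None else self.W[rows]
        out = {}
        for bi, b in enumerate(matrix.blocks):
            X = matrix.data[:, bi, :] if rows is None else matrix.data[rows, bi, :]
            out[b] = W.T @ X
        return out


class ActivityModes(BaseEstimator):
    """Activity-mode decomposition (sklearn-style estimator).

    Fits one linear SVM per task contrast on time bins of the trial-averaged
    (mean-subtracted, smoothed) activity, then orthogonalizes the chosen
    weight vectors with a QR decomposition into ``W_``.

    Contrasts (on a 50-ms-bin activity matrix whose window covers a 1-s
    pre-sound baseline):

    * ``sound`` — 200 ms following sound onset vs. the 200 ms before it;
    * ``aversive`` — the 500 ms following opto onset (block 2) vs. the
      500 ms following air-puff onset (block 4); with ``aversive="or"`` the
      two epochs pooled are discriminated from baseline bins instead;
    * ``state`` — 1-s pre-sound baseline bins of block 1 vs. block 4.
    """

    def __init__(self, aversive: str = "or", svm_c: float = 1.0,
                 sound_onset_s: float = 0.0, sound_dur_s: float = 0.2,
                 aversive_onset_s: float = 0.7, aversive_dur_s: float = 0.5,
                 baseline_s: float = 1.0):
        self.aversive = aversive
        self.svm_c = svm_c
        self.sound_onset_s = sound_onset_s
        self.sound_dur_s = sound_dur_s
        self.aversive_onset_s = aversive_onset_s
        self.aversive_dur_s = aversive_dur_s
        self.baseline_s = baseline_s

    def _bins(self, matrix: ActivityMatrix, t0: float, t1: float) -> np.ndarray:
        t = matrix.time_axis()
        return np.nonzero((t >= t0) & (t < t1))[0]

    def _svm_weights(self, Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        X = np.hstack([Xa, Xb]).T          # samples = time bins
        y = np.r_[np.zeros(Xa.shape[1]), np.ones(Xb.shape[1])]
        if len(np.unique(y)) < 2 or min(Xa.shape[1], Xb.shape[1]) == 0:
            raise InsufficientDataError("single-class epoch labels for SVM contrast")
        svm = SVC(kernel="linear", C=self.svm_c, class_weight="balanced")
        svm.fit(X, y)
        return svm.coef_.ravel()

    def fit(self, matrix: ActivityMatrix, y=None):
        if matrix.window_s[0] > -self.baseline_s:
            raise InsufficientDataError(
                "activity-matrix window must include the 1-s pre-sound baseline")
        blocks = {b: matrix.data[:, i, :] for i, b in enumerate(matrix.blocks)}
        base_bins = self._bins(matrix, -self.baseline_s, self.sound_onset_s)
        snd_bins = self._bins(matrix, self.sound_onset_s,
                              self.sound_onset_s + self.sound_dur_s)
        pre_snd = self._bins(matrix, self.sound_onset_s - self.sound_dur_s,
                             self.sound_onset_s)
        av_bins = self._bins(matrix, self.aversive_onset_s,
                             self.aversive_onset_s + self.aversive_dur_s)
        sound_vec = self._svm_weights(
            np.hstack([blocks[b][:, pre_snd] for b in (1, 2, 3) if b in blocks]),
            np.hstack([blocks[b][:, snd_bins] for b in (1, 2, 3) if b in blocks]))
        opto_epoch = blocks[2][:, av_bins]
        puff_epoch = blocks[4][:, av_bins]
        if self.aversive == "and":
            aversive_vec = self._svm_weights(opto_epoch, puff_epoch)
        else:  # "or": pooled aversive epochs vs baseline
            aversive_vec = self._svm_weights(
                np.hstack([blocks[2][:, base_bins], blocks[4][:, base_bins]]),
                np.hstack([opto_epoch, puff_epoch]))
        state_vec = self._svm_weights(blocks[1][:, base_bins],
                                      blocks[4][:, base_bins])
        V = np.column_stack([sound_vec, aversive_vec, state_vec])
        Q, R = np.linalg.qr(V)
        Q = Q * np.sign(np.diag(R))[None, :]  # orient modes along raw vectors
        self.raw_vectors_ = V
        self.W_ = Q
        self.mode_names_ = ["sound",
                            "opto-OR-airpuff" if self.aversive == "or"
                            else "opto-AND-airpuff",
                            "state"]
        return self

    def transform(self, matrix: ActivityMatrix) -> dict:
        return {b: self.W_.T @ matrix.data[:, i, :]
                for i, b in enumerate(matrix.blocks)}


def compute_activity_modes(matrix: ActivityMatrix, aversive: str = "or",
                           **kw) -> ModeSet:
    """Fit :class:`ActivityModes` and bundle weights + per-block projections."""
    am = ActivityModes(aversive=aversive, **kw).fit(matrix)
    proj = am.transform(matrix)
    return ModeSet(W=am.W_, mode_names=am.mode_names_, raw_vectors=am.raw_vectors_,
                   projections=proj, bin_s=matrix.bin_s, unit_ids=matrix.unit_ids)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------


def _baseline_counts(dataset: SpikeDataset, unit_ids, blocks,
                     window_s=(-2.1, -0.1), bin_s=0.1):
    """Per-unit baseline spike counts: (n_units, n_total_bins) with labels."""
    n_bins = int(round((window_s[1] - window_s[0]) / bin_s))
    edges = window_s[0] + np.arange(n_bins + 1) * bin_s
    cols, labels = [], []
    for b in blocks:
        onsets = dataset.trials.loc[dataset.trials["block"] == b, "t_start_s"].to_numpy()
        for t0 in onsets:
            cols.append(t0 + edges)
            labels.extend([b] * n_bins)
    X = np.zeros((len(unit_ids), len(labels)))
    for ui, uid in enumerate(unit_ids):
        sp = dataset.spikes[uid]
        row = []
        for e in cols:
            row.append(np.diff(np.searchsorted(sp, e)))
        X[ui] = np.concatenate(row)
    return X, np.asarray(labels)


def decode_block_identity(dataset: SpikeDataset, blocks: tuple = (1, 2),
                          subset_sizes=None, repeats: int = 50,
                          seed: int | None = 0, window_s=(-2.1, -0.1),
                          bin_s: float = 0.1, unit_ids=None) -> pd.DataFrame:
    """Repeated twofold cross-validated logistic-regression decoding of block
    identity from pre-trial baseline activity.

    Baseline spike counts (100-ms bins in the 2-s window before trial onset)
    are concatenated across the two blocks and z-scored within unit; units
    with no baseline spikes are removed.  For each subset size, ``repeats``
    random unit subsets are drawn; each repeat splits the time bins into
    stratified halves, trains on one and tests on the other, both ways.
    Returns a table of mean ± s.d. accuracy per subset size (curve truncated
    at the number of available units); chance is 50%.
    """
    if unit_ids is None:
        unit_ids = dataset.unit_ids
    X, labels = _baseline_counts(dataset, unit_ids, blocks, window_s, bin_s)
    keep = X.sum(axis=1) > 0
    X = X[keep]
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    X = (X - mu) / np.where(sd > 0, sd, 1.0)
    n_units = X.shape[0]
    if n_units < 5:
        raise InsufficientDataError("need >= 5 units with baseline spikes")
    if subset_sizes is None:
        subset_sizes = list(range(5, 151, 5))
    subset_sizes = [s for s in subset_sizes if s <= n_units]
    rng = np.random.default_rng(seed)
    y = (labels == blocks[1]).astype(int)
    idx_by_class = [np.nonzero(y == c)[0] for c in (0, 1)]
    rows = []
    for size in subset_sizes:
        accs = np.empty(repeats)
        for r in range(repeats):
            units = rng.choice(n_units, size=size, replace=False)
            # stratified twofold split over time bins
            train = np.zeros(len(y), dtype=bool)
            for cls_idx in idx_by_class:
                perm = rng.permutation(cls_idx)
                train[perm[:len(perm) // 2]] = True
            fold_accs = []
            for tr_mask in (train, ~train):
                clf = LogisticRegression(max_iter=1000)
                clf.fit(X[np.ix_(units, np.nonzero(tr_mask)[0])].T, y[tr_mask])
                fold_accs.append(clf.score(
                    X[np.ix_(units, np.nonzero(~tr_mask)[0])].T, y[~tr_mask]))
            accs[r] = np.mean(fold_accs)
        rows.append({"n_units": size, "accuracy_mean": accs.mean(),
                     "accuracy_sd": accs.std(), "n_repeats": repeats})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PC trajectories
# ---------------------------------------------------------------------------


def pca_trajectories(matrix: ActivityMatrix, n_units: int = 550, n_pcs: int = 3,
                     seed: int | None = 0) -> dict:
    """Per-block population trajectories in a common PC space.

    For each block, PCA (``n_pcs`` components) is fitted on the pooled
    units × time matrix (a balanced random subset of ``n_units`` per
    genotype when available, else all units with a warning); per-genotype
    trajectories re-project each genotype's activity on its own rows of the
    loading matrix.
    """
    rng = np.random.default_rng(seed)
    geno = matrix.units["genotype"].to_numpy()
    sel = []
    for g in pd.unique(geno):
        idx = np.nonzero(geno == g)[0]
        if len(idx) > n_units:
            idx = rng.choice(idx, size=n_units, replace=False)
        else:
            warnings.warn(f"genotype {g}: only {len(idx)} units available "
                          f"(< {n_units}); using all")
        sel.append(idx)
    sel = np.concatenate(sel)
    out = {"blocks": {}, "selected_units": sel}
    for bi, b in enumerate(matrix.blocks):
        X = matrix.data[sel, bi, :]              # N x T
        pca = PCA(n_components=min(n_pcs, X.shape[0]), svd_solver="full")
        pca.fit(X.T)                              # samples = time bins
        L = pca.components_.T                     # N x n_pcs loadings
        common = (X - X.mean(axis=1, keepdims=True)).T @ L
        per_geno = {}
        for g in pd.unique(geno[sel]):
            gsel = geno[sel] == g
            Xg = X[gsel]
            per_geno[g] = (Xg - Xg.mean(axis=1, keepdims=True)).T @ L[gsel]
        out["blocks"][b] = {"common": common, "per_genotype": per_geno,
                            "explained_variance": pca.explained_variance_ratio_}
    return out
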