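"""Intrinsic electrophysiological feature extraction from current-clamp sweeps.

Definitions implemented here:

* spike detection — voltage peak above −10 mV preceded (within 2 ms) by a
  dV/dt crossing of 10 mV/ms; peaks closer than 1 ms are merged;
* AP threshold — voltage at the first sample (searching backward from the AP
  peak) where dV/dt reaches 10 mV/ms;
* AP rise time — threshold-to-peak interval; half-width — trace width at
  threshold + amplitude/2, linearly interpolated between samples; up/down
  stroke — extrema of the central-difference derivative;
* afterpotentials — ADP measured from the fast-repolarization trough to the
  ADP peak; convex AHP from threshold to the AHP trough, concave AHP from the
  ADP peak to the subsequent trough;
* input resistance — least-squares slope of steady-state ΔV (mean over the
  last 100 ms of the step) against ΔI over the ±20 pA sweeps;
* membrane time constant — single-exponential fit to the averaged −40 pA
  onset transient;
* firing features — rheobase, AP counts in each half of the 1-s rheobase
  step, first/second ISIs (as instantaneous frequencies) at twice rheobase
  and at the maximal-frequency sweep, adaptation ratios (last ISI / first and
  second ISI), firing frequency at twice rheobase, and the mean post-step
  voltage deviation over the 150 ms after step offset.

Missing features are returned as NaN and flagged — never silently zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import InsufficientDataError, SingularFitError
from .simulate import SweepSet

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_UNITS",
    "detect_spikes",
    "tonic_rate",
    "input_resistance",
    "membrane_time_constant",
    "ap_threshold",
    "ap_waveform",
    "afterpotentials",
    "firing_features",
    "extract_features",
    "extract_feature_table",
]

DVDT_THRESHOLD = 10.0  # mV/ms
PEAK_MIN_MV = -10.0
MERGE_MS = 1.0

FEATURE_UNITS = {
    "tonic_rate_hz": "Hz",
    "input_resistance_mohm": "MOhm",
    "tau_ms": "ms",
    "ap_threshold_mv": "mV",
    "ap_rise_ms": "ms",
    "ap_halfwidth_ms": "ms",
    "ap_upstroke_mv_ms": "mV/ms",
    "ap_downstroke_mv_ms": "mV/ms",
    "adp_mv": "mV",
    "adp_rise_ms": "ms",
    "ahp_convex_mv": "mV",
    "ahp_concave_mv": "mV",
    "ahp_rise_ms": "ms",
    "rheo_first_half_aps": "count",
    "rheo_second_half_aps": "count",
    "isi1_2x_hz": "Hz",
    "isi2_2x_hz": "Hz",
    "isi1_max_hz": "Hz",
    "isi2_max_hz": "Hz",
    "adapt_1_last": "ratio",
    "adapt_2_last": "ratio",
    "firing_freq_hz": "Hz",
    "firing_poststep_mv": "mV",
    "rheobase_pa": "pA",
}
FEATURE_NAMES = list(FEATURE_UNITS)


def _dvdt(v: np.ndarray, fs_hz: float) -> np.ndarray:
    """Central-difference derivative in mV/ms."""
    return np.gradient(v) * fs_hz / 1000.0


def detect_spikes(v: np.ndarray, fs_hz: float) -> np.ndarray:
    """Indices of AP peaks (above −10 mV, preceded by a fast upstroke)."""
    dist = max(int(round(MERGE_MS * fs_hz / 1000.0)), 1)
    peaks, _ = find_peaks(v, height=PEAK_MIN_MV, distance=dist)
    if not len(peaks):
        return peaks.astype(np.int64)
    dv = _dvdt(v, fs_hz)
    look = max(int(round(2.0 * fs_hz / 1000.0)), 1)
    keep = [p for p in peaks if np.max(dv[max(p - look, 0):p + 1]) >= DVDT_THRESHOLD]
    return np.asarray(keep, dtype=np.int64)


def tonic_rate(trace_mv: np.ndarray, fs_hz: float) -> float:
    """Spontaneous firing rate (Hz) = spike count / trace duration."""
    duration = len(trace_mv) / fs_hz
    if duration < 1.0:
        raise InsufficientDataError(f"trace of {duration:.3f} s is too short (< 1 s)")
    return len(detect_spikes(trace_mv, fs_hz)) / duration


def input_resistance(sweeps, fs_hz: float, steady_ms: float = 100.0) -> float:
    """Input resistance (MΩ): least-squares slope of steady-state ΔV vs ΔI.

    The steady-state voltage is the mean over the last ``steady_ms`` of the
    step; ΔV is referenced to the pre-step baseline of each sweep.
    """
    if len(sweeps) < 2:
        raise InsufficientDataError("need >= 2 subthreshold sweeps")
    amps = np.array([s.amp_pa for s in sweeps], dtype=float)
    if np.ptp(amps) == 0:
        raise SingularFitError("all step amplitudes identical")
    dv = np.empty(len(sweeps))
    for i, s in enumerate(sweeps):
        i_on = int(round(s.t_on_s * fs_hz))
        i_off = int(round(s.t_off_s * fs_hz))
        n_ss = int(round(steady_ms * fs_hz / 1000.0))
        base = float(np.mean(s.v_mv[:i_on])) if i_on > 0 else float(s.v_mv[0])
        dv[i] = float(np.mean(s.v_mv[i_off - n_ss:i_off])) - base
    slope = np.polyfit(amps, dv, 1)[0]  # mV/pA = GOhm
    return float(slope * 1000.0)


def membrane_time_constant(sweeps, fs_hz: float, fit_ms: float = 150.0) -> float:
    """Membrane τ (ms) from a single-exponential fit to the averaged
    hyperpolarizing onset transient.  Returns NaN if the fit fails."""
    if not sweeps:
        raise InsufficientDataError("need >= 1 hyperpolarizing response")
    i_on = int(round(sweeps[0].t_on_s * fs_hz))
    n_fit = int(round(fit_ms * fs_hz / 1000.0))
    segs = [s.v_mv[i_on:i_on + n_fit] for s in sweeps]
    n = min(map(len, segs))
    mean_v = np.mean([s[:n] for s in segs], axis=0)
    t_ms = np.arange(n) / fs_hz * 1000.0

    def model(t, v_inf, a, tau):
        return v_inf + a * np.exp(-t / tau)

    a0 = mean_v[0] - mean_v[-1]
    try:
        popt, _ = curve_fit(model, t_ms, mean_v,
                            p0=[mean_v[-1], a0, max(fit_ms / 8.0, 1.0)],
                            maxfev=5000)
    except RuntimeError:
        return float("nan")
    tau = float(popt[2])
    return tau if 0 < tau < 10 * fit_ms else float("nan")


def ap_threshold(v: np.ndarray, fs_hz: float, peak_idx: int) -> tuple:
    """(threshold mV, threshold index): first sample, searching backward from
    the AP peak, at which dV/dt reaches 10 mV/ms.  Returns (nan, -1) if the
    derivative never reaches the criterion."""
    dv = _dvdt(v, fs_hz)
    look = max(int(round(3.0 * fs_hz / 1000.0)), 2)
    i = int(peak_idx)
    # step back into the upstroke (region with dV/dt >= criterion)
    while i > max(peak_idx - look, 0) and dv[i] < DVDT_THRESHOLD:
        i -= 1
    if dv[i] < DVDT_THRESHOLD:
        return float("nan"), -1
    # then back to the first sample of that region
    while i > 0 and dv[i - 1] >= DVDT_THRESHOLD:
        i -= 1
    return float(v[i]), int(i)


def _interp_crossing(v: np.ndarray, level: float, i0: int, i1: int,
                     rising: bool) -> float:
    """Fractional sample index where v crosses `level` between i0..i1."""
    seg = v[i0:i1 + 1]
    if rising:
        above = seg >= level
        k = int(np.argmax(above))
    else:
        below = seg <= level
        k = int(np.argmax(below))
    if k == 0:
        return float(i0)
    x0, x1 = seg[k - 1], seg[k]
    frac = (level - x0) / (x1 - x0) if x1 != x0 else 0.0
    return i0 + k - 1 + float(frac)


def ap_waveform(v: np.ndarray, fs_hz: float, thr_idx: int, peak_idx: int) -> dict:
    """Rise time, half-width (interpolated), and up/downstroke of one AP."""
    dt_ms = 1000.0 / fs_hz
    thr_v = v[thr_idx]
    peak_v = v[peak_idx]
    amp = peak_v - thr_v
    half = thr_v + amp / 2.0
    i_up = _interp_crossing(v, half, thr_idx, peak_idx, rising=True)
    n_after = min(len(v) - 1, peak_idx + int(round(8.0 * fs_hz / 1000.0)))
    i_down = _interp_crossing(v, half, peak_idx, n_after, rising=False)
    dv = _dvdt(v, fs_hz)
    up = float(np.max(dv[thr_idx:peak_idx + 1]))
    down = float(np.min(dv[peak_idx:n_after + 1]))
    partial = bool(v[n_after] > half)  # clipped before repolarizing
    return {"ap_rise_ms": (peak_idx - thr_idx) * dt_ms,
            "ap_halfwidth_ms": (i_down - i_up) * dt_ms,
            "ap_upstroke_mv_ms": up, "ap_downstroke_mv_ms": down,
            "partial": partial}


def afterpotentials(v: np.ndarray, fs_hz: float, peak_idx: int,
                    thr_v: float, end_idx: int | None = None,
                    window_ms: float = 30.0, min_deflect_mv: float = 0.5,
                    smooth_ms: float = 0.15) -> dict:
    """Afterpotential amplitudes on the inter-spike segment after one AP.

    The repolarization is followed to its fast trough; a rebound of at least
    ``min_deflect_mv`` that is itself followed by a decline of the same size
    classifies the segment as ADP-then-concave-AHP, otherwise it is a simple
    convex AHP (amplitude from AP threshold to the segment minimum).  The
    analysis window is capped at ``window_ms`` after the peak and at
    ``end_idx`` (e.g. the next spike).
    """
    out = {"adp_mv": np.nan, "adp_rise_ms": np.nan, "ahp_convex_mv": np.nan,
           "ahp_concave_mv": np.nan, "ahp_rise_ms": np.nan, "shape": "none"}
    n = peak_idx + int(round(window_ms * fs_hz / 1000.0))
    if end_idx is not None:
        n = min(n, int(end_idx))
    seg = v[peak_idx:min(n, len(v))].astype(float)
    if len(seg) < 5:
        return out
    if smooth_ms > 0:
        sigma = smooth_ms * fs_hz / 1000.0
        if sigma >= 0.5:
            seg = gaussian_filter1d(seg, sigma, mode="nearest")
    dt_ms = 1000.0 / fs_hz
    runmin = np.minimum.accumulate(seg)
    rebound = np.nonzero(seg - runmin >= min_deflect_mv)[0]
    if len(rebound):
        i_reb = int(rebound[0])
        fast_trough_i = int(np.argmin(seg[:i_reb]))
        adp_peak_i = fast_trough_i + int(np.argmax(seg[fast_trough_i:]))
        adp_amp = float(seg[adp_peak_i] - seg[fast_trough_i])
        trough2_i = adp_peak_i + int(np.argmin(seg[adp_peak_i:]))
        concave = float(seg[adp_peak_i] - seg[trough2_i])
        if adp_amp >= min_deflect_mv and concave >= min_deflect_mv \
                and adp_peak_i < len(seg) - 2:
            out["adp_mv"] = adp_amp
            out["adp_rise_ms"] = (adp_peak_i - fast_trough_i) * dt_ms
            out["ahp_concave_mv"] = concave
            out["ahp_rise_ms"] = (trough2_i - adp_peak_i) * dt_ms
            out["shape"] = "adp-concave-ahp"
            return out
    trough_i = int(np.argmin(seg))
    out["ahp_convex_mv"] = float(thr_v - seg[trough_i])
    out["ahp_rise_ms"] = trough_i * dt_ms
    out["shape"] = "convex-ahp"
    return out


def _isi_features(spike_t: np.ndarray) -> dict:
    """First/second ISIs as instantaneous frequencies plus adaptation ratios
    (last ISI over first and over second)."""
    out = {"isi1_hz": np.nan, "isi2_hz": np.nan,
           "adapt_1_last": np.nan, "adapt_2_last": np.nan}
    isis = np.diff(spike_t)
    if len(isis) >= 1:
        out["isi1_hz"] = 1.0 / isis[0]
        out["adapt_1_last"] = isis[-1] / isis[0]
    if len(isis) >= 2:
        out["isi2_hz"] = 1.0 / isis[1]
        out["adapt_2_last"] = isis[-1] / isis[1]
    return out


def firing_features(ladder, fs_hz: float, post_window_ms: float = 150.0) -> dict:
    """Rheobase-anchored train features over the 1-s depolarizing ladder."""
    out = {k: np.nan for k in ("rheobase_pa", "rheo_first_half_aps",
                               "rheo_second_half_aps", "isi1_2x_hz", "isi2_2x_hz",
                               "isi1_max_hz", "isi2_max_hz", "adapt_1_last",
                               "adapt_2_last", "firing_freq_hz",
                               "firing_poststep_mv")}
    flags: list[str] = []
    counts = {}
    spike_times = {}
    for s in sorted(ladder, key=lambda s: s.amp_pa):
        idx = detect_spikes(s.v_mv, fs_hz)
        t = idx / fs_hz
        t = t[(t >= s.t_on_s) & (t < s.t_off_s)]
        counts[s.amp_pa] = len(t)
        spike_times[s.amp_pa] = t - s.t_on_s
    firing_amps = [a for a, c in sorted(counts.items()) if c >= 1]
    if not firing_amps:
        flags.append("rheobase-undefined")
        return {**out, "flags": flags}
    rheo = firing_amps[0]
    out["rheobase_pa"] = rheo
    step_s = ladder[0].t_off_s - ladder[0].t_on_s
    half = step_s / 2.0
    t_rheo = spike_times[rheo]
    out["rheo_first_half_aps"] = float(np.sum(t_rheo < half))
    out["rheo_second_half_aps"] = float(np.sum(t_rheo >= half))
    # 2x rheobase (nearest available amplitude)
    amps = np.array(sorted(counts))
    a2 = float(amps[np.argmin(np.abs(amps - 2 * rheo))])
    if a2 != 2 * rheo:
        flags.append("no-exact-2x-rheobase")
    isi2x = _isi_features(spike_times[a2])
    out["isi1_2x_hz"], out["isi2_2x_hz"] = isi2x["isi1_hz"], isi2x["isi2_hz"]
    out["adapt_1_last"], out["adapt_2_last"] = isi2x["adapt_1_last"], isi2x["adapt_2_last"]
    out["firing_freq_hz"] = counts[a2] / step_s
    a_max = max(counts, key=lambda a: counts[a])
    isim = _isi_features(spike_times[a_max])
    out["isi1_max_hz"], out["isi2_max_hz"] = isim["isi1_hz"], isim["isi2_hz"]
    # post-step voltage deviation on the rheobase sweep
    s_rheo = next(s for s in ladder if s.amp_pa == rheo)
    i_on = int(round(s_rheo.t_on_s * fs_hz))
    i_off = int(round(s_rheo.t_off_s * fs_hz))
    n_post = int(round(post_window_ms * fs_hz / 1000.0))
    base = float(np.mean(s_rheo.v_mv[:i_on]))
    out["firing_poststep_mv"] = float(np.mean(s_rheo.v_mv[i_off:i_off + n_post]) - base)
    return {**out, "flags": flags}


def extract_features(sweep_set: SweepSet) -> pd.Series:
    """Full intrinsic-parameter vector for one neuron.

    Missing values are NaN; ``series.attrs['flags']`` records why.
    """
    fs = sweep_set.sampling_rate_hz
    vals = {k: np.nan for k in FEATURE_NAMES}
    flags: list[str] = []

    if sweep_set.spontaneous_mv is not None and len(sweep_set.spontaneous_mv) >= fs:
        vals["tonic_rate_hz"] = tonic_rate(sweep_set.spontaneous_mv, fs)
    else:
        flags.append("no-spontaneous-trace")

    res_sweeps = sweep_set.by_kind("resistance")
    if len(res_sweeps) >= 2:
        try:
            vals["input_resistance_mohm"] = input_resistance(res_sweeps, fs)
        except SingularFitError:
            flags.append("resistance-singular")
    else:
        flags.append("no-resistance-sweeps")

    tau_sweeps = sweep_set.by_kind("tau")
    if tau_sweeps:
        tau = membrane_time_constant(tau_sweeps, fs)
        vals["tau_ms"] = tau
        if np.isnan(tau):
            flags.append("tau-fit-failed")
    else:
        flags.append("no-tau-sweeps")

    ladder = sweep_set.ladder
    if ladder:
        ff = firing_features(ladder, fs)
        flags.extend(ff.pop("flags"))
        vals.update({k: ff[k] for k in ff})
        rheo = vals["rheobase_pa"]
        if not np.isnan(rheo):
            s = next(s for s in ladder if s.amp_pa == rheo)
            peaks = detect_spikes(s.v_mv, fs)
            t = peaks / fs
            peaks = peaks[(t >= s.t_on_s) & (t < s.t_off_s)]
            if len(peaks):
                p0 = int(peaks[0])
                thr_v, thr_i = ap_threshold(s.v_mv, fs, p0)
                if thr_i >= 0:
                    vals["ap_threshold_mv"] = thr_v
                    wf = ap_waveform(s.v_mv, fs, thr_i, p0)
                    if wf.pop("partial"):
                        flags.append("partial-ap")
                    vals.update(wf)
                    end = int(peaks[1]) if len(peaks) > 1 else int(round(s.t_off_s * fs))
                    ahp = afterpotentials(s.v_mv, fs, p0, thr_v, end_idx=end)
                    ahp.pop("shape")
                    vals.update(ahp)
                else:
                    flags.append("no-threshold-crossing")
    else:
        flags.append("no-ladder-sweeps")

    out = pd.Series(vals, index=FEATURE_NAMES, dtype=float)
    out.attrs["flags"] = flags
    return out


def extract_feature_table(sweep_sets, labels=None) -> pd.DataFrame:
    """Stack per-neuron feature vectors into a neurons × parameters table."""
    rows = [extract_features(ss) for ss in sweep_sets]
    df = pd.DataFrame(rows).reset_index(drop=True)
    if labels is not None:
        df.insert(0, "label", list(labels))
    return df
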