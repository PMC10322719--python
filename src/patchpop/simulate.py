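"""Synthetic data generators for the whole pipeline.

Three generators live here:

* :func:`simulate_sweep_set` — current-clamp sweeps for a single neuron drawn
  from one of six electrophysiological archetypes (fast-adapting, bursting,
  regular/late-spiking with narrow/wide action potentials).  The subthreshold
  dynamics are an adaptive exponential integrate-and-fire (AdEx) model with
  optional burst (transient inward) and latency (transient outward) currents;
  a stereotyped action-potential waveform template is spliced into the trace
  at every spike-trigger crossing so that waveform-shape features (half-width,
  up/downstroke, afterpotentials) are defined.
* :func:`simulate_population` — block-structured spike trains for a population
  of units recorded during a four-block task (tone / tone+opto / tone /
  noise+air-puff).  Each unit is an inhomogeneous Poisson process whose
  log-rate is a linear combination of event indicators, i.e. exactly the
  generative form assumed by the event GLM, plus block-wise baseline
  multipliers emulating slow state shifts.
* :func:`simulate_soma` — soma axis measurements (two perpendicular major axes
  and 25%/75% minor axes) for round / elongated / triangular soma shapes.

All randomness flows through one ``numpy.random.Generator`` seeded per call;
identical seed and configuration give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .errors import InvalidDesignError, InvalidProtocolError

__all__ = [
    "ArchetypeSpec",
    "ProtocolSpec",
    "EventSpec",
    "PopulationDesign",
    "Sweep",
    "SweepSet",
    "SpikeDataset",
    "ARCHETYPES",
    "archetype",
    "simulate_sweep_set",
    "simulate_population",
    "simulate_soma",
    "default_events",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

ARCHETYPE_NAMES = ("FA-Bk", "Burst", "RS-N", "LS-N", "LS-W", "RS-W")


@dataclass
class ArchetypeSpec:
    """Generative parameters of one electrophysiological archetype.

    Membrane parameters follow the AdEx convention: capacitance ``c_pf`` (pF),
    leak conductance ``g_leak_ns`` (nS), resting potential ``e_rest_mv`` (mV),
    soft threshold ``v_t_mv`` with spike-initiation sharpness ``delta_t_mv``
    (mV), subthreshold adaptation coupling ``adapt_a_ns`` (nS), spike-triggered
    adaptation increment ``adapt_b_pa`` (pA) with time constant
    ``adapt_tau_ms``.  ``burst_*`` is a transient inward current switched on at
    step onset (doublet/triplet onsets); ``latency_*`` is a transient outward
    current delaying the first spike (late-spiking phenotypes).  ``tonic_*``
    set the spontaneous (cell-attached) firing statistics; every neuron fires
    spontaneously.  The ``ap_*`` parameters shape the spliced AP waveform
    template; ``adp_amp_mv == 0`` yields a simple convex AHP, ``> 0`` an ADP
    followed by a concave AHP.
    """

    name: str
    c_pf: float
    g_leak_ns: float
    e_rest_mv: float
    v_t_mv: float
    delta_t_mv: float
    adapt_a_ns: float
    adapt_b_pa: float
    adapt_tau_ms: float
    v_reset_mv: float
    burst_g_pa: float = 0.0
    burst_tau_ms: float = 50.0
    latency_g_pa: float = 0.0
    latency_tau_ms: float = 200.0
    tonic_rate_hz: float = 5.0
    tonic_rate_sd_hz: float = 1.5
    tonic_isi_cv: float = 0.25
    # AP waveform template
    ap_amp_mv: float = 80.0
    ap_rise_ms: float = 0.5
    ap_fall_ms: float = 0.8
    fast_trough_mv: float = 10.0
    adp_amp_mv: float = 0.0
    adp_rise_ms: float = 4.0
    ahp_amp_mv: float = 4.0
    ahp_rise_ms: float = 3.0
    ahp_tau_ms: float = 50.0
    # jitter: multiplicative CV on scale parameters, additive s.d. (mV) on voltages
    jitter_cv: float = 0.07
    jitter_mv: float = 1.2

    def __post_init__(self) -> None:
        for attr in ("c_pf", "g_leak_ns", "delta_t_mv", "adapt_tau_ms",
                     "burst_tau_ms", "latency_tau_ms", "ap_amp_mv",
                     "ap_rise_ms", "ap_fall_ms", "ahp_tau_ms"):
            if getattr(self, attr) <= 0:
                raise InvalidDesignError(f"{attr} must be > 0, got {getattr(self, attr)}")
        if self.tonic_rate_hz <= 0:
            raise InvalidDesignError("tonic_rate_hz must be > 0 (all neurons fire spontaneously)")
        if self.adapt_a_ns < 0 or self.adapt_b_pa < 0:
            raise InvalidDesignError("adaptation parameters must be >= 0")

    def jittered(self, rng: np.random.Generator, scale: float = 1.0) -> "ArchetypeSpec":
        """Draw a per-neuron parameter set around this archetype.

        ``scale`` multiplies both jitter magnitudes (0 disables jitter).
        """
        cv = self.jitter_cv * scale
        sd_mv = self.jitter_mv * scale
        out = dataclasses.replace(self)

        def mult(x: float) -> float:
            return float(x * max(0.05, 1.0 + cv * rng.standard_normal())) if x > 0 else x

        for attr in ("c_pf", "g_leak_ns", "delta_t_mv", "adapt_a_ns", "adapt_b_pa",
                     "adapt_tau_ms", "burst_g_pa", "latency_g_pa", "ap_amp_mv",
                     "ap_rise_ms", "ap_fall_ms", "fast_trough_mv", "adp_amp_mv",
                     "ahp_amp_mv", "ahp_tau_ms"):
            setattr(out, attr, mult(getattr(out, attr)))
        for attr in ("e_rest_mv", "v_t_mv", "v_reset_mv"):
            setattr(out, attr, float(getattr(out, attr) + sd_mv * rng.standard_normal()))
        # keep reset safely below threshold
        out.v_reset_mv = min(out.v_reset_mv, out.v_t_mv - 0.5)
        return out


def _arch(**kw) -> ArchetypeSpec:
    return ArchetypeSpec(**kw)


#: The six archetypes.  Values are the package's own choices, tuned to produce
#: the qualitative phenotypes (fast adaptation, onset bursting, delayed first
#: spike, narrow vs. wide APs) and spontaneous tonic firing; each pair of
#: archetypes differs in at least four generative parameters.
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "FA-Bk": _arch(name="FA-Bk", c_pf=60, g_leak_ns=2.5, e_rest_mv=-58, v_t_mv=-42,
                   delta_t_mv=1.5, adapt_a_ns=0.8, adapt_b_pa=60, adapt_tau_ms=150,
                   v_reset_mv=-50, tonic_rate_hz=10, tonic_rate_sd_hz=3,
                   ap_amp_mv=82, ap_rise_ms=0.35, ap_fall_ms=0.55, fast_trough_mv=14,
                   adp_amp_mv=0.0, ahp_amp_mv=6, ahp_tau_ms=40),
    "Burst": _arch(name="Burst", c_pf=75, g_leak_ns=3.0, e_rest_mv=-56, v_t_mv=-44,
                   delta_t_mv=2.0, adapt_a_ns=0.5, adapt_b_pa=20, adapt_tau_ms=120,
                   v_reset_mv=-46, burst_g_pa=60, burst_tau_ms=50,
                   tonic_rate_hz=4, tonic_rate_sd_hz=1.5,
                   ap_amp_mv=78, ap_rise_ms=0.55, ap_fall_ms=0.9, fast_trough_mv=8,
                   adp_amp_mv=4.0, adp_rise_ms=4.0, ahp_amp_mv=4, ahp_tau_ms=60),
    "RS-N": _arch(name="RS-N", c_pf=70, g_leak_ns=3.5, e_rest_mv=-57, v_t_mv=-43,
                  delta_t_mv=2.0, adapt_a_ns=1.0, adapt_b_pa=25, adapt_tau_ms=200,
                  v_reset_mv=-52, tonic_rate_hz=8, tonic_rate_sd_hz=2,
                  ap_amp_mv=85, ap_rise_ms=0.4, ap_fall_ms=0.65, fast_trough_mv=11,
                  adp_amp_mv=0.0, ahp_amp_mv=3, ahp_tau_ms=50),
    "LS-N": _arch(name="LS-N", c_pf=55, g_leak_ns=2.5, e_rest_mv=-59, v_t_mv=-41,
                  delta_t_mv=1.5, adapt_a_ns=0.5, adapt_b_pa=10, adapt_tau_ms=150,
                  v_reset_mv=-54, latency_g_pa=80, latency_tau_ms=180,
                  tonic_rate_hz=5, tonic_rate_sd_hz=1.5,
                  ap_amp_mv=83, ap_rise_ms=0.45, ap_fall_ms=0.7, fast_trough_mv=10,
                  adp_amp_mv=0.0, ahp_amp_mv=4, ahp_tau_ms=45),
    "LS-W": _arch(name="LS-W", c_pf=90, g_leak_ns=3.0, e_rest_mv=-60, v_t_mv=-45,
                  delta_t_mv=2.5, adapt_a_ns=0.3, adapt_b_pa=8, adapt_tau_ms=250,
                  v_reset_mv=-55, latency_g_pa=60, latency_tau_ms=220,
                  tonic_rate_hz=3, tonic_rate_sd_hz=1,
                  ap_amp_mv=75, ap_rise_ms=0.9, ap_fall_ms=1.7, fast_trough_mv=6,
                  adp_amp_mv=2.5, adp_rise_ms=6.0, ahp_amp_mv=2.5, ahp_tau_ms=80),
    "RS-W": _arch(name="RS-W", c_pf=100, g_leak_ns=4.5, e_rest_mv=-56, v_t_mv=-44,
                  delta_t_mv=2.5, adapt_a_ns=0.7, adapt_b_pa=12, adapt_tau_ms=300,
                  v_reset_mv=-53, tonic_rate_hz=6, tonic_rate_sd_hz=2,
                  ap_amp_mv=80, ap_rise_ms=0.8, ap_fall_ms=1.5, fast_trough_mv=7,
                  adp_amp_mv=3.0, adp_rise_ms=5.0, ahp_amp_mv=2, ahp_tau_ms=70),
}


def archetype(name: str) -> ArchetypeSpec:
    """Return the canonical spec of a named archetype (copy)."""
    try:
        return dataclasses.replace(ARCHETYPES[name])
    except KeyError:
        raise KeyError(f"unknown archetype {name!r}; choose from {ARCHETYPE_NAMES}") from None


@dataclass
class ProtocolSpec:
    """Current-clamp stimulation protocol.

    The depolarizing ladder uses 1-s steps (so rheobase / 2x-rheobase / max
    features are defined on the same time base), preceded by short ±20 pA
    steps for input resistance and repeated −40 pA steps for the membrane
    time constant.
    """

    sampling_rate_hz: float = 20_000.0
    step_duration_s: float = 1.0
    ladder_pa: tuple = tuple(range(20, 321, 20))
    resistance_steps_pa: tuple = (-20.0, 20.0)
    resistance_duration_s: float = 0.5
    tau_step_pa: float = -40.0
    tau_n_repeats: int = 20
    tau_duration_s: float = 0.3
    pre_s: float = 0.2
    post_s: float = 0.3
    post_window_ms: float = 150.0
    holding_mv: float = -70.0
    spontaneous_duration_s: float = 10.0
    noise_sd_pa: float = 2.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise InvalidProtocolError("sampling rate must be positive")
        if self.step_duration_s <= 0 or self.resistance_duration_s <= 0:
            raise InvalidProtocolError("step durations must be positive")
        if self.tau_n_repeats < 1:
            raise InvalidProtocolError("tau_n_repeats must be >= 1")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz


# ---------------------------------------------------------------------------
# AdEx integration (numba core)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _adex_core(dt_ms, i_inj, c_pf, g_ns, el, vt, dT, a_ns, b_pa, tau_w,
               v_reset, v_cut, v0, w0, burst_g, burst_tau, lat_g, lat_tau,
               step_on_idx, refract_steps):  # pragma: no cover - compiled
    n = i_inj.shape[0]
    v = np.empty(n)
    spikes = np.empty(n, dtype=np.int64)
    n_sp = 0
    vi = v0
    w = w0
    sb = 0.0
    sl = 0.0
    refr = 0
    for k in range(n):
        if k == step_on_idx:
            sb = 1.0
            sl = 1.0
        sb *= np.exp(-dt_ms / burst_tau)
        sl *= np.exp(-dt_ms / lat_tau)
        if refr > 0:
            refr -= 1
            vi = v_reset
            w += -w * dt_ms / tau_w + a_ns * (vi - el) * dt_ms / tau_w
            v[k] = vi
            continue
        arg = (vi - vt) / dT
        if arg > 8.0:
            arg = 8.0
        i_exp = g_ns * dT * np.exp(arg)
        i_tr = burst_g * sb - lat_g * sl
        dv = (-g_ns * (vi - el) + i_exp - w + i_inj[k] + i_tr) / c_pf * dt_ms
        vi = vi + dv
        w += (a_ns * (vi - el) - w) * dt_ms / tau_w
        if vi >= v_cut:
            spikes[n_sp] = k
            n_sp += 1
            vi = v_reset
            w += b_pa
            refr = refract_steps
        v[k] = vi
    return v, spikes[:n_sp]


def _holding_current(spec: ArchetypeSpec, v_hold: float) -> float:
    """Constant current (pA) holding the steady-state membrane at ``v_hold``."""
    arg = min((v_hold - spec.v_t_mv) / spec.delta_t_mv, 8.0)
    i_exp = spec.g_leak_ns * spec.delta_t_mv * np.exp(arg)
    w_ss = spec.adapt_a_ns * (v_hold - spec.e_rest_mv)
    return spec.g_leak_ns * (v_hold - spec.e_rest_mv) - i_exp + w_ss


def ap_template(spec: ArchetypeSpec, fs_hz: float) -> np.ndarray:
    """Stereotyped AP waveform (mV, relative to the spike-trigger voltage).

    Cosine-shaped rise and fall, then either a monotone (convex) AHP or an
    ADP hump followed by a deeper (concave) AHP, recovering exponentially.
    """
    dt = 1000.0 / fs_hz

    def cosine(n, y0, y1):
        x = np.linspace(0.0, 1.0, max(n, 2) + 1)[1:]
        return y0 + (y1 - y0) * 0.5 * (1 - np.cos(np.pi * x))

    n_rise = max(int(round(spec.ap_rise_ms / dt)), 2)
    n_fall = max(int(round(spec.ap_fall_ms / dt)), 2)
    parts = [cosine(n_rise, 0.0, spec.ap_amp_mv),
             cosine(n_fall, spec.ap_amp_mv, -spec.fast_trough_mv)]
    if spec.adp_amp_mv > 0.25:
        n_adp = max(int(round(spec.adp_rise_ms / dt)), 2)
        adp_peak = -spec.fast_trough_mv + spec.adp_amp_mv
        trough2 = adp_peak - spec.ahp_amp_mv
        n_fall2 = max(int(round(2 * spec.adp_rise_ms / dt)), 2)
        parts += [cosine(n_adp, -spec.fast_trough_mv, adp_peak),
                  cosine(n_fall2, adp_peak, trough2)]
        tail_start = trough2
    else:
        n_ahp = max(int(round(spec.ahp_rise_ms / dt)), 2)
        trough = -(spec.fast_trough_mv + spec.ahp_amp_mv)
        parts.append(cosine(n_ahp, -spec.fast_trough_mv, trough))
        tail_start = trough
    n_tail = max(int(round(min(4 * spec.ahp_tau_ms, 50.0) / dt)), 2)
    t = np.arange(1, n_tail + 1) * dt
    parts.append(tail_start * np.exp(-t / spec.ahp_tau_ms))
    return np.concatenate([[0.0], *parts])


def _splice_spikes(v: np.ndarray, spike_idx: np.ndarray, trigger_mv: float,
                   template: np.ndarray) -> np.ndarray:
    """Overlay the AP template at each trigger crossing, cross-fading its tail
    into the underlying subthreshold trace."""
    out = v.copy()
    n = len(out)
    for j, i0 in enumerate(spike_idx):
        stop = n
        if j + 1 < len(spike_idx):
            stop = min(stop, int(spike_idx[j + 1]))
        seg = min(len(template), stop - i0)
        if seg <= 0:
            continue
        tmpl = trigger_mv + template[:seg]
        n_fade = max(seg // 4, 1)
        lam = np.zeros(seg)
        lam[-n_fade:] = np.linspace(0.0, 1.0, n_fade)
        out[i0:i0 + seg] = (1 - lam) * tmpl + lam * out[i0:i0 + seg]
    return out


# ---------------------------------------------------------------------------
# sweep sets
# ---------------------------------------------------------------------------


@dataclass
class Sweep:
    """One current-clamp sweep: voltage trace plus step metadata."""

    v_mv: np.ndarray
    amp_pa: float
    t_on_s: float
    t_off_s: float
    kind: str  # "ladder" | "resistance" | "tau"
    spike_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def spike_times_s(self, fs_hz: float) -> np.ndarray:
        return self.spike_idx / fs_hz


@dataclass
class SweepSet:
    """A neuron's full current-clamp protocol plus a spontaneous trace."""

    sampling_rate_hz: float
    sweeps: list
    spontaneous_mv: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def by_kind(self, kind: str) -> list:
        return [s for s in self.sweeps if s.kind == kind]

    @property
    def ladder(self) -> list:
        return self.by_kind("ladder")


def _simulate_one_sweep(spec: ArchetypeSpec, protocol: ProtocolSpec, amp_pa: float,
                        duration_s: float, kind: str, rng: np.random.Generator,
                        template: np.ndarray) -> Sweep:
    fs = protocol.sampling_rate_hz
    dt = protocol.dt_ms
    n_pre = int(round(protocol.pre_s * fs))
    n_step = int(round(duration_s * fs))
    n_post = int(round(protocol.post_s * fs))
    n = n_pre + n_step + n_post
    i_hold = _holding_current(spec, protocol.holding_mv)
    i_inj = np.full(n, i_hold)
    i_inj[n_pre:n_pre + n_step] += amp_pa
    if protocol.noise_sd_pa > 0:
        i_inj = i_inj + protocol.noise_sd_pa * rng.standard_normal(n)
    v_cut = spec.v_t_mv + 5.0
    refract = max(int(round(1.5 / dt)), 1)
    # burst/latency transients are recruited by depolarization only
    onset_idx = n_pre if amp_pa > 0 else -1
    v, spike_idx = _adex_core(dt, i_inj, spec.c_pf, spec.g_leak_ns, spec.e_rest_mv,
                              spec.v_t_mv, spec.delta_t_mv, spec.adapt_a_ns,
                              spec.adapt_b_pa, spec.adapt_tau_ms, spec.v_reset_mv,
                              v_cut, protocol.holding_mv, spec.adapt_a_ns *
                              (protocol.holding_mv - spec.e_rest_mv),
                              spec.burst_g_pa, spec.burst_tau_ms,
                              spec.latency_g_pa, spec.latency_tau_ms,
                              onset_idx, refract)
    if len(spike_idx):
        v = _splice_spikes(v, spike_idx, v_cut, template)
    return Sweep(v_mv=v, amp_pa=amp_pa, t_on_s=protocol.pre_s,
                 t_off_s=protocol.pre_s + duration_s, kind=kind, spike_idx=spike_idx)


def _simulate_spontaneous(spec: ArchetypeSpec, protocol: ProtocolSpec,
                          rng: np.random.Generator, template: np.ndarray) -> np.ndarray:
    """Cell-attached-like trace: noisy baseline with spliced APs from a
    gamma-renewal pacemaker at the neuron's tonic rate."""
    fs = protocol.sampling_rate_hz
    dur = protocol.spontaneous_duration_s
    rate = max(spec.tonic_rate_hz + spec.tonic_rate_sd_hz * rng.standard_normal(), 0.2)
    cv = spec.tonic_isi_cv
    shape = 1.0 / cv ** 2
    n_max = int(rate * dur * 3 + 20)
    isis = rng.gamma(shape, 1.0 / (rate * shape), size=n_max)
    t_sp = np.cumsum(isis) + rng.uniform(0, 1.0 / rate)
    t_sp = t_sp[t_sp < dur - 0.1]
    n = int(round(dur * fs))
    v = spec.e_rest_mv + 0.35 * rng.standard_normal(n)
    idx = np.asarray(np.round(t_sp * fs), dtype=np.int64)
    return _splice_spikes(v, idx, spec.v_t_mv + 5.0, template)


def simulate_sweep_set(spec: ArchetypeSpec, protocol: ProtocolSpec | None = None,
                       seed: int | np.random.Generator = 0, *,
                       jitter_scale: float = 1.0) -> SweepSet:
    """Simulate one neuron's full protocol.

    Parameters are jittered around the archetype (``jitter_scale`` scales the
    archetype's jitter; 0 disables it), then the resistance steps, the
    membrane-time-constant repeats, the 1-s depolarizing ladder and a
    spontaneous trace are generated with a single seeded generator.
    """
    protocol = protocol or ProtocolSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cell = spec.jittered(rng, scale=jitter_scale) if jitter_scale > 0 else dataclasses.replace(spec)
    template = ap_template(cell, protocol.sampling_rate_hz)
    sweeps: list[Sweep] = []
    for amp in protocol.resistance_steps_pa:
        sweeps.append(_simulate_one_sweep(cell, protocol, amp,
                                          protocol.resistance_duration_s,
                                          "resistance", rng, template))
    for _ in range(protocol.tau_n_repeats):
        sweeps.append(_simulate_one_sweep(cell, protocol, protocol.tau_step_pa,
                                          protocol.tau_duration_s, "tau", rng, template))
    for amp in protocol.ladder_pa:
        sweeps.append(_simulate_one_sweep(cell, protocol, float(amp),
                                          protocol.step_duration_s, "ladder",
                                          rng, template))
    spont = _simulate_spontaneous(cell, protocol, rng, template)
    meta = {"archetype": spec.name, "params": dataclasses.asdict(cell)}
    return SweepSet(sampling_rate_hz=protocol.sampling_rate_hz, sweeps=sweeps,
                    spontaneous_mv=spont, meta=meta)


# ---------------------------------------------------------------------------
# population spike trains
# ---------------------------------------------------------------------------


@dataclass
class EventSpec:
    """A task event: onset/duration relative to trial start, active blocks."""

    name: str
    onset_s: float
    duration_s: float
    blocks: tuple

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidDesignError(f"event {self.name}: duration must be > 0")
        if self.onset_s < 0:
            raise InvalidDesignError(f"event {self.name}: onset must be >= 0")


def default_events() -> list:
    """The four-block task: 200 ms tone at trial start in blocks 1-3; 500 ms
    optogenetic train starting 500 ms after tone end in block 2; 200 ms blue
    noise then a 50 ms air puff 500 ms after noise end in block 4."""
    return [
        EventSpec("sound1", 0.0, 0.2, (1, 2, 3)),
        EventSpec("opto", 0.7, 0.5, (2,)),
        EventSpec("sound2", 0.0, 0.2, (4,)),
        EventSpec("airpuff", 0.7, 0.05, (4,)),
    ]


@dataclass
class PopulationDesign:
    """Design of a simulated block-structured population recording.

    ``gains`` is the per-unit multiplicative rate gain for each event
    (units x events; 1 = untuned).  ``block_baseline`` multiplies the baseline
    rate per block (units x blocks; models state shifts).  The log-rate is
    thus linear in the event indicators, matching the event-GLM assumption.
    """

    n_units: int = 40
    block_trials: tuple = (50, 100, 50, 50)
    trial_length_s: float = 6.0
    pre_s: float = 3.0  # session time before the first trial onset
    events: list | None = None
    baseline_hz: float | np.ndarray = 5.0
    gains: np.ndarray | None = None
    block_baseline: np.ndarray | None = None
    regions: list | None = None
    genotypes: list | None = None
    #: absolute refractory period imposed by thinning (0 = exact Poisson)
    refractory_s: float = 0.0025
    seed: int = 0

    def resolve(self) -> "PopulationDesign":
        d = dataclasses.replace(self)
        d.events = list(self.events) if self.events is not None else default_events()
        base = np.broadcast_to(np.asarray(self.baseline_hz, dtype=float),
                               (self.n_units,)).copy()
        if np.any(base < 0):
            raise InvalidDesignError("baseline rates must be >= 0")
        d.baseline_hz = base
        n_ev = len(d.events)
        d.gains = (np.ones((self.n_units, n_ev)) if self.gains is None
                   else np.asarray(self.gains, dtype=float))
        if d.gains.shape != (self.n_units, n_ev):
            raise InvalidDesignError("gains must have shape (n_units, n_events)")
        if np.any(d.gains < 0):
            raise InvalidDesignError("gains must be >= 0")
        n_blocks = len(self.block_trials)
        d.block_baseline = (np.ones((self.n_units, n_blocks)) if self.block_baseline is None
                            else np.asarray(self.block_baseline, dtype=float))
        if d.block_baseline.shape != (self.n_units, n_blocks):
            raise InvalidDesignError("block_baseline must have shape (n_units, n_blocks)")
        if np.any(d.block_baseline < 0):
            raise InvalidDesignError("block baselines must be >= 0")
        d.regions = list(self.regions) if self.regions is not None else ["PL"] * self.n_units
        d.genotypes = list(self.genotypes) if self.genotypes is not None else ["Esr1"] * self.n_units
        # events must not overlap within any block's trial
        for b in range(1, n_blocks + 1):
            ivs = sorted((e.onset_s, e.onset_s + e.duration_s) for e in d.events
                         if b in e.blocks)
            for (s0, e0), (s1, _e1) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise InvalidDesignError(f"events overlap in block {b}")
            if ivs and ivs[-1][1] > self.trial_length_s:
                raise InvalidDesignError("event extends past trial end")
        return d


@njit(cache=True)
def _refractory_mask(t, refractory_s):  # pragma: no cover - compiled
    keep = np.ones(t.shape[0], dtype=np.bool_)
    last = t[0]
    for i in range(1, t.shape[0]):
        if t[i] - last < refractory_s:
            keep[i] = False
        else:
            last = t[i]
    return keep


@dataclass
class SpikeDataset:
    """Per-unit spike times plus trial/event tables and unit metadata."""

    spikes: dict  # unit_id -> sorted np.ndarray of spike times (s)
    trials: pd.DataFrame  # trial_id, block, t_start_s
    events: pd.DataFrame  # trial_id, block, event, onset_s (absolute), duration_s
    units: pd.DataFrame  # unit_id, region, genotype, baseline_hz
    duration_s: float
    event_names: list
    ground_truth: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def unit_ids(self) -> list:
        return list(self.units["unit_id"])


def simulate_population(design: PopulationDesign) -> SpikeDataset:
    """Draw the population's spike trains as exact piecewise-constant-rate
    Poisson processes (per-segment Poisson counts with uniform times)."""
    d = design.resolve()
    rng = np.random.default_rng(design.seed)
    n_trials = int(np.sum(d.block_trials))
    t_starts = d.pre_s + np.arange(n_trials) * d.trial_length_s
    blocks = np.repeat(np.arange(1, len(d.block_trials) + 1), d.block_trials)
    duration = d.pre_s + n_trials * d.trial_length_s

    trials = pd.DataFrame({"trial_id": np.arange(n_trials), "block": blocks,
                           "t_start_s": t_starts})
    ev_rows = []
    for tid, (t0, b) in enumerate(zip(t_starts, blocks)):
        for e in d.events:
            if b in e.blocks:
                ev_rows.append((tid, int(b), e.name, t0 + e.onset_s, e.duration_s))
    events = pd.DataFrame(ev_rows, columns=["trial_id", "block", "event",
                                            "onset_s", "duration_s"])

    # shared segmentation of the session into constant-rate intervals
    bounds = {0.0, duration}
    bounds.update(t_starts)  # block/trial boundaries for baseline multipliers
    for _, r in events.iterrows():
        bounds.add(r["onset_s"])
        bounds.add(r["onset_s"] + r["duration_s"])
    bounds = np.array(sorted(bounds))
    seg_lo, seg_hi = bounds[:-1], bounds[1:]
    seg_len = seg_hi - seg_lo
    mid = (seg_lo + seg_hi) / 2
    # per-segment block index (0 before first trial -> use block of next trial)
    seg_trial = np.clip(np.searchsorted(t_starts, mid, side="right") - 1, 0, n_trials - 1)
    seg_block = blocks[seg_trial]
    # per-segment event activation matrix
    n_ev = len(d.events)
    active = np.zeros((len(mid), n_ev), dtype=bool)
    for j, e in enumerate(d.events):
        rel = mid - t_starts[seg_trial]
        in_win = (rel >= e.onset_s) & (rel < e.onset_s + e.duration_s)
        in_block = np.isin(seg_block, e.blocks)
        before_first = mid < t_starts[0]
        active[:, j] = in_win & in_block & ~before_first

    spikes: dict[int, np.ndarray] = {}
    for u in range(d.n_units):
        rate = d.baseline_hz[u] * d.block_baseline[u, seg_block - 1]
        gain = np.prod(np.where(active, d.gains[u][None, :], 1.0), axis=1)
        lam = rate * gain * seg_len
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            spikes[u] = np.empty(0)
            continue
        lo = np.repeat(seg_lo, counts)
        ln = np.repeat(seg_len, counts)
        t = np.sort(lo + ln * rng.uniform(size=total))
        if d.refractory_s > 0 and len(t) > 1:
            t = t[_refractory_mask(t, d.refractory_s)]
        spikes[u] = t

    units = pd.DataFrame({"unit_id": np.arange(d.n_units), "region": d.regions,
                          "genotype": d.genotypes, "baseline_hz": d.baseline_hz})
    gt = {"gains": pd.DataFrame(d.gains, columns=[e.name for e in d.events]),
          "block_baseline": d.block_baseline.copy()}
    return SpikeDataset(spikes=spikes, trials=trials, events=events, units=units,
                        duration_s=duration, event_names=[e.name for e in d.events],
                        ground_truth=gt, meta={"seed": design.seed})


# ---------------------------------------------------------------------------
# soma fixtures
# ---------------------------------------------------------------------------

_SOMA_SHAPES = {
    # shape -> (X/Y ratio, Ymajor/Yminor ratio)
    "round": (1.0, 1.0),
    "elongated": (2.4, 1.0),
    "triangular": (1.3, 1.5),
}


def simulate_soma(shape: str, size_um: float = 15.0, n: int = 1,
                  seed: int | np.random.Generator = 0,
                  jitter: float = 0.06) -> pd.DataFrame:
    """Soma axis table (X, Y, Ymajor, Yminor, area in um / um^2) for a shape.

    ``jitter`` is the lognormal sigma applied per axis (0 = exact ratios).
    """
    if size_um <= 0:
        raise InvalidDesignError("size_um must be > 0")
    if shape not in _SOMA_SHAPES:
        raise InvalidDesignError(f"shape must be one of {sorted(_SOMA_SHAPES)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e_ratio, t_ratio = _SOMA_SHAPES[shape]
    y = size_um * np.exp(jitter * rng.standard_normal(n)) if jitter else np.full(n, size_um)
    x = e_ratio * size_um * np.exp(jitter * rng.standard_normal(n)) if jitter \
        else np.full(n, e_ratio * size_um)
    yminor = 0.8 * size_um * np.exp(jitter * rng.standard_normal(n)) if jitter \
        else np.full(n, 0.8 * size_um)
    ymajor = t_ratio * yminor * np.exp(jitter * rng.standard_normal(n)) if jitter \
        else t_ratio * yminor
    area = np.pi / 4.0 * x * y
    return pd.DataFrame({"X": x, "Y": y, "Ymajor": ymajor, "Yminor": yminor,
                         "area": area})
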