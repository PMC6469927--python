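"""Generative simulator of mouse behaviour in the virtual burrow assay.

The simulator produces position/force traces with the phenomenology seen in
the real assay — ~2 Hz downward breathing deflections, short-latency full
ingress, biphasic flinch transients, high-frequency trembling, ~1 s egress
bouts, per-stimulus habituation of response probability, and decaying
pullback-resistance force bouts — together with a ground-truth event log so
the controller and detection pipeline can be tested without hardware.

Two entry points:

* :func:`simulate_session` synthesises an open-loop session (no controller)
  from a stimulus protocol, fully vectorised.
* :class:`VirtualMouse` is the stateful per-sample model used when the
  closed-loop controller is in the loop (see :mod:`vburrow.controller`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import SessionTrace

__all__ = [
    "StimulusResponse",
    "MouseParams",
    "GroundTruthEvent",
    "GroundTruthLog",
    "StimulusSpec",
    "simulate_session",
    "simulate_trial_table",
    "simulate_extinction_table",
    "VirtualMouse",
]

# time from the 5%-amplitude point to the logistic midpoint, in units of the
# logistic time constant, when rise_time is defined as the 5% -> 95% duration
_LOGISTIC_5_95 = 2.0 * math.log(19.0)


@dataclass(frozen=True)
class StimulusResponse:
    """Response model for one stimulus id.

    ``kind`` is the behaviour the stimulus elicits when the animal responds;
    the per-presentation response probability follows the habituation law
    ``p_n = p0 * exp(-decay * (n - 1))`` with ``n`` counted separately per
    stimulus id, so a never-seen id starts back at ``p0`` (novelty reset).
    """

    kind: str = "ingress"  # ingress | flinch | tremble | egress_bout
    p0: float = 1.0
    decay: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be a probability")
        if self.decay < 0:
            raise ValueError("decay must be nonnegative")
        if self.kind not in ("ingress", "flinch", "tremble", "egress_bout"):
            raise ValueError(f"unknown response kind {self.kind!r}")

    def probability(self, n: int) -> float:
        """Response probability on the n-th presentation (1-based)."""
        return self.p0 * math.exp(-self.decay * (n - 1))


@dataclass(frozen=True)
class MouseParams:
    """Generative parameters of the virtual mouse.

    Defaults reproduce the strong-air-puff regime: full ingress of ~15 mm
    reached with an onset latency of 18.5 ms (cv 0.07), breathing as
    downward-only ~2 Hz deflections of ~0.3 mm, and pullback resistance of
    0.4–1 N decaying within tens of seconds.  The drawn latency is defined
    as the time at which the ingress displacement reaches 5% of its final
    amplitude (the movement-onset reference used by the detector's 0.75 mm
    criterion at the default 15 mm amplitude).
    """

    breathing_rate: float = 2.0        # Hz
    breathing_amp: float = 0.3         # mm, downward-only
    ingress_amp: float = 15.0          # mm
    ingress_latency_mean: float = 0.0185   # s
    ingress_latency_cv: float = 0.07
    ingress_rise_time: float = 0.05    # s, 5% -> 95% of amplitude
    ingress_hold: float = 15.0         # s at full ingress before relaxing
    ingress_release_tau: float = 0.3   # s
    initial_ingress_duration: float = 10.0  # s of struggle at first pullback
    flinch_amp: float = 1.0            # mm
    flinch_duration: float = 0.2       # s (one biphasic cycle)
    flinch_latency: float = 0.02       # s
    tremble_freq: float = 20.0         # Hz
    tremble_amp: float = 0.5           # mm
    tremble_duration: float = 3.0      # s
    tremble_latency: float = 0.5       # s
    egress_bout_depth: float = 22.0    # mm (animals can egress up to ~30)
    egress_bout_duration: float = 1.0  # s
    egress_bout_latency: float = 0.3   # s
    resist_force_amp: float = 700.0    # mN, within the observed 400-1000
    resist_rise: float = 0.1           # s
    resist_decay: float = 5.0          # s (resistance bouts end within 30 s)
    noise_sd: float = 0.02             # mm, sensor noise
    spont_ingress_rate: float = 0.02   # Hz hazard of spontaneous ingress
    spont_ingress_duration: float = 1.0  # s
    responses: dict = field(default_factory=dict)  # stimulus_id -> StimulusResponse
    default_response: StimulusResponse = StimulusResponse()

    def __post_init__(self) -> None:
        for name in ("breathing_rate", "breathing_amp", "ingress_amp",
                     "ingress_latency_mean", "ingress_rise_time",
                     "flinch_amp", "flinch_duration", "tremble_freq",
                     "tremble_amp", "egress_bout_depth",
                     "egress_bout_duration", "resist_force_amp",
                     "resist_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ingress_latency_cv < 0 or self.noise_sd < 0:
            raise ValueError("cv and noise_sd must be nonnegative")

    def response_for(self, stimulus_id: int) -> StimulusResponse:
        return self.responses.get(stimulus_id, self.default_response)


@dataclass(frozen=True)
class StimulusSpec:
    """One protocol entry: stimulus id, onset time and duration (seconds)."""

    stimulus_id: int
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.stimulus_id <= 0:
            raise ValueError("stimulus_id must be a positive integer (0 = none)")
        if self.duration <= 0 or self.onset < 0:
            raise ValueError("need onset >= 0 and duration > 0")


@dataclass(frozen=True)
class GroundTruthEvent:
    """True emitted behaviour for one stimulus presentation."""

    trial_index: int            # 1-based, per stimulus id
    stimulus_id: int
    onset_time: float           # stimulus onset, session seconds
    kind: str                   # ingress | flinch | tremble | egress_bout | none
    latency: float              # s from stimulus onset to movement onset; nan if none
    peak_displacement: float    # mm, signed (negative for egress bouts)


@dataclass
class GroundTruthLog:
    """One record per stimulus presentation, plus generation metadata."""

    events: list[GroundTruthEvent] = field(default_factory=list)
    seed: int | None = None

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of_kind(self, kind: str) -> list[GroundTruthEvent]:
        return [e for e in self.events if e.kind == kind]


def _span(t_lo: float, t_hi: float, fs: float, n: int) -> tuple[int, int]:
    """Clamped sample range covering [t_lo, t_hi]."""
    return (max(0, int(t_lo * fs)), min(n, int(t_hi * fs) + 1))


def _validate_protocol(protocol: list[StimulusSpec]) -> None:
    prev_end = -math.inf
    prev_onset = -math.inf
    for s in protocol:
        if s.onset < prev_onset:
            raise ValueError("protocol onsets must be nondecreasing")
        if s.onset < prev_end:
            raise ValueError("stimulus epochs must not overlap")
        prev_onset, prev_end = s.onset, s.onset + s.duration


def _draw_latency(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Gaussian latency with given mean and cv, truncated at zero."""
    sd = cv * mean
    for _ in range(100):
        lat = rng.normal(mean, sd)
        if lat >= 0:
            return lat
    return 0.0


def _ingress_waveform(t: np.ndarray, t_on: float, latency: float,
                      p: MouseParams) -> np.ndarray:
    """Logistic rise to ingress_amp, clipped to zero before stimulus onset.

    Parameterised so the waveform crosses 5% of amplitude exactly at
    ``t_on + latency`` and 95% one rise time later; holds at full amplitude
    for ``ingress_hold`` then relaxes exponentially.
    """
    tau = p.ingress_rise_time / _LOGISTIC_5_95
    t_mid = t_on + latency + tau * math.log(19.0)
    x = np.clip((t - t_mid) / tau, -500, 500)
    w = p.ingress_amp / (1.0 + np.exp(-x))
    w[t < t_on] = 0.0
    t_rel = t - (t_mid + p.ingress_hold)
    release = t_rel > 0
    w[release] *= np.exp(-t_rel[release] / p.ingress_release_tau)
    return w


def _flinch_waveform(t: np.ndarray, t_on: float, p: MouseParams) -> np.ndarray:
    """Biphasic transient: one full sine cycle, zero net displacement."""
    t0 = t_on + p.flinch_latency
    w = np.zeros_like(t)
    m = (t >= t0) & (t < t0 + p.flinch_duration)
    w[m] = p.flinch_amp * np.sin(2 * np.pi * (t[m] - t0) / p.flinch_duration)
    return w


def _tremble_waveform(t: np.ndarray, t_on: float, p: MouseParams) -> np.ndarray:
    """Amplitude-modulated (Hann-enveloped) sinusoid at tremble_freq."""
    t0 = t_on + p.tremble_latency
    w = np.zeros_like(t)
    m = (t >= t0) & (t < t0 + p.tremble_duration)
    tt = t[m] - t0
    env = 0.5 * (1 - np.cos(2 * np.pi * tt / p.tremble_duration))
    w[m] = p.tremble_amp * env * np.sin(2 * np.pi * p.tremble_freq * tt)
    return w


def _egress_bout_waveform(t: np.ndarray, t_on: float, p: MouseParams) -> np.ndarray:
    """Downward smooth pulse: the animal briefly exits, then re-ingresses."""
    t0 = t_on + p.egress_bout_latency
    edge = min(0.1, 0.25 * p.egress_bout_duration)
    w = np.zeros_like(t)
    m = (t >= t0) & (t < t0 + p.egress_bout_duration)
    tt = t[m] - t0
    rise = np.clip(tt / edge, 0, 1)
    fall = np.clip((p.egress_bout_duration - tt) / edge, 0, 1)
    shape = np.minimum(rise, fall)
    w[m] = -p.egress_bout_depth * (3 * shape**2 - 2 * shape**3)
    return w


def _breathing(t: np.ndarray, p: MouseParams, phase: float) -> np.ndarray:
    """Downward-only breathing deflections: half-rectified sine pulses."""
    return -p.breathing_amp * np.maximum(
        0.0, np.sin(2 * np.pi * p.breathing_rate * t + phase))


def simulate_session(params: MouseParams, protocol: list[StimulusSpec],
                     sample_rate: float = 1000.0, seed: int = 0,
                     duration: float | None = None,
                     tail: float = 4.0) -> tuple[SessionTrace, GroundTruthLog]:
    """Synthesise an open-loop session from a stimulus protocol.

    The tether is slack throughout (actuator parked at the ingress-permitting
    position, zero force): this is the open-loop configuration in which
    stimulus-response phenomenology is measured.  Identical
    ``(params, protocol, seed)`` give bitwise-identical output.

    Returns the session trace and a ground-truth log with one record per
    stimulus presentation.
    """
    protocol = list(protocol)
    _validate_protocol(protocol)
    if duration is None:
        last = max((s.onset + s.duration for s in protocol), default=0.0)
        duration = last + tail
    n = int(round(duration * sample_rate))
    if n < 1:
        raise ValueError("session duration spans no samples")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / sample_rate

    phase = rng.uniform(0, 2 * np.pi)
    breathing = _breathing(t, params, phase)
    ingress_wave = np.zeros(n)
    other_wave = np.zeros(n)
    stimulus = np.zeros(n, dtype=np.int64)

    log = GroundTruthLog(seed=seed)
    n_seen: dict[int, int] = {}
    for spec in protocol:
        n_seen[spec.stimulus_id] = n_seen.get(spec.stimulus_id, 0) + 1
        presentation = n_seen[spec.stimulus_id]
        resp = params.response_for(spec.stimulus_id)
        p_n = resp.probability(presentation)
        responded = rng.random() < p_n
        i0 = int(math.floor(spec.onset * sample_rate + 1e-9))
        i1 = min(n, int(math.floor((spec.onset + spec.duration) * sample_rate + 1e-9)))
        stimulus[i0:i1] = spec.stimulus_id

        if not responded:
            log.events.append(GroundTruthEvent(
                presentation, spec.stimulus_id, spec.onset, "none",
                math.nan, 0.0))
            continue
        # waveforms are bounded in time; only touch the affected slice
        if resp.kind == "ingress":
            lat = _draw_latency(rng, params.ingress_latency_mean,
                                params.ingress_latency_cv)
            t_hi = (spec.onset + lat + params.ingress_rise_time
                    + params.ingress_hold + 12 * params.ingress_release_tau)
            j0, j1 = _span(spec.onset, t_hi, sample_rate, n)
            ingress_wave[j0:j1] += _ingress_waveform(t[j0:j1], spec.onset,
                                                     lat, params)
            peak = params.ingress_amp
        elif resp.kind == "flinch":
            lat = params.flinch_latency
            j0, j1 = _span(spec.onset, spec.onset + lat
                           + params.flinch_duration, sample_rate, n)
            other_wave[j0:j1] += _flinch_waveform(t[j0:j1], spec.onset, params)
            peak = params.flinch_amp
        elif resp.kind == "tremble":
            lat = params.tremble_latency
            j0, j1 = _span(spec.onset, spec.onset + lat
                           + params.tremble_duration, sample_rate, n)
            other_wave[j0:j1] += _tremble_waveform(t[j0:j1], spec.onset, params)
            peak = params.tremble_amp
        else:  # egress_bout
            lat = params.egress_bout_latency
            j0, j1 = _span(spec.onset, spec.onset + lat
                           + params.egress_bout_duration, sample_rate, n)
            other_wave[j0:j1] += _egress_bout_waveform(t[j0:j1], spec.onset,
                                                       params)
            peak = -params.egress_bout_depth
        log.events.append(GroundTruthEvent(
            presentation, spec.stimulus_id, spec.onset, resp.kind, lat, peak))

    # whole-body ingress movement overrides the breathing micro-deflections:
    # breathing fades out as the ingress passes its movement-onset reference
    suppress = np.clip(
        1.0 - ingress_wave / (0.05 * params.ingress_amp), 0.0, 1.0)
    position = breathing * suppress + ingress_wave + other_wave
    if params.noise_sd > 0:
        position += rng.normal(0.0, params.noise_sd, n)

    trace = SessionTrace(
        sample_rate=sample_rate,
        position=position,
        force=np.zeros(n),
        actuator=np.full(n, params.ingress_amp),
        stimulus=stimulus,
        metadata={"seed": seed, "mode": "open_loop"},
    )
    return trace, log


def simulate_trial_table(params: MouseParams, stimulus_ids: list[int],
                         n_trials: int, n_mice: int, seed: int = 0,
                         ingress_median: float = 10.0,
                         non_ingress_median: float = 0.3):
    """Directly sample a per-trial table from the habituation response model.

    Skips trace synthesis: each (mouse, stimulus, trial) row draws the
    Bernoulli response from ``p_n = p0 * exp(-decay * (n - 1))`` and, when
    the animal responds with an ingress, a supra-threshold max displacement
    (lognormal around ``ingress_median``) and latency; non-responses get
    sub-threshold displacements.  Used for replicate-level studies of
    habituation, conditioning contrasts and extinction where full traces
    would add nothing.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_mice):
        for sid in stimulus_ids:
            resp = params.response_for(sid)
            for trial in range(1, n_trials + 1):
                hit = rng.random() < resp.probability(trial)
                if hit and resp.kind == "ingress":
                    disp = float(ingress_median * rng.lognormal(0.0, 0.3))
                    disp = max(disp, 2.5)
                    lat = _draw_latency(rng, params.ingress_latency_mean,
                                        params.ingress_latency_cv)
                else:
                    disp = float(non_ingress_median * rng.lognormal(0.0, 0.5))
                    lat = math.nan
                rows.append({
                    "session_id": f"s{m}", "mouse_id": f"m{m}",
                    "stimulus_id": sid, "trial_index": trial,
                    "max_displacement": disp, "ingress": bool(hit),
                    "latency": lat, "kind": "ingress" if hit else "none",
                    "tremble": False,
                })
    return pd.DataFrame(rows)


def simulate_extinction_table(n_trials: int, n_mice: int,
                              high_latency_p0: float = 0.05,
                              high_latency_p1: float = 0.45,
                              ingress_p: float = 0.9,
                              fast_latency: float = 0.4,
                              slow_latency: float = 2.0,
                              seed: int = 0):
    """Trial table with a linearly increasing high-latency probability.

    Models extinction of a conditioned response: the chance that an ingress
    is initiated later than 1 s rises linearly from ``high_latency_p0`` on
    the first trial to ``high_latency_p1`` on the last, while ingress
    probability stays at ``ingress_p``.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_mice):
        for trial in range(1, n_trials + 1):
            frac = (trial - 1) / max(1, n_trials - 1)
            q = high_latency_p0 + (high_latency_p1 - high_latency_p0) * frac
            hit = rng.random() < ingress_p
            if hit:
                if rng.random() < q:
                    lat = float(slow_latency * rng.lognormal(0.0, 0.25))
                    lat = max(lat, 1.05)
                else:
                    lat = float(min(0.95, fast_latency * rng.lognormal(0.0, 0.3)))
                disp = 10.0
            else:
                lat, disp = math.nan, 0.3
            rows.append({
                "session_id": f"s{m}", "mouse_id": f"m{m}",
                "stimulus_id": 1, "trial_index": trial,
                "max_displacement": disp, "ingress": bool(hit),
                "latency": lat, "kind": "ingress" if hit else "none",
                "tremble": False,
            })
    return pd.DataFrame(rows)


class VirtualMouse:
    """Stateful per-sample mouse model for closed-loop co-simulation.

    The mouse's *desired* position is its rest position plus breathing,
    noise and any active behavioural event; the realised burrow position is
    the desired position clipped by the actuator tether (the tether
    constrains ingress, never pushes).  When the actuator holds the burrow
    short of where the mouse wants to be, the mouse pulls: force rises
    toward ``resist_force_amp`` and decays with time constant
    ``resist_decay`` as the animal gives up, eventually falling below any
    positive quiet threshold.
    """

    def __init__(self, params: MouseParams, sample_rate: float, seed: int,
                 rest_position: float = 0.0, n_samples_hint: int = 0,
                 initially_ingressed: bool = True):
        self.p = params
        self.fs = float(sample_rate)
        self.dt = 1.0 / self.fs
        self.rng = np.random.default_rng(seed)
        self.rest = rest_position
        self.phase = float(self.rng.uniform(0, 2 * np.pi))
        self._n_seen: dict[int, int] = {}
        # active stimulus-evoked event: (kind, t_on, latency) or None
        self._event: tuple[str, float, float] | None = None
        self._spont_until = -1.0   # end time of an active spontaneous ingress
        self._spont_start = -1.0
        self._resist_start: float | None = None  # taut-tether bout start
        self._slack_since: float | None = None
        self._last_taut = False
        if initially_ingressed:
            # naive mice sit fully ingressed and struggle against the first
            # pullback for a bounded time before consenting to egress
            self._spont_start = 0.0
            self._spont_until = params.initial_ingress_duration
        self.log = GroundTruthLog(seed=seed)
        self._noise = (self.rng.normal(0.0, params.noise_sd, n_samples_hint)
                       if n_samples_hint and params.noise_sd > 0 else None)

    # -- stimulus handling -------------------------------------------------

    def on_stimulus(self, stimulus_id: int, t: float) -> None:
        """Notify the mouse of a stimulus onset; draws its response."""
        self._n_seen[stimulus_id] = self._n_seen.get(stimulus_id, 0) + 1
        presentation = self._n_seen[stimulus_id]
        resp = self.p.response_for(stimulus_id)
        if self.rng.random() < resp.probability(presentation):
            if resp.kind == "ingress":
                lat = _draw_latency(self.rng, self.p.ingress_latency_mean,
                                    self.p.ingress_latency_cv)
                peak = self.p.ingress_amp
            elif resp.kind == "flinch":
                lat, peak = self.p.flinch_latency, self.p.flinch_amp
            elif resp.kind == "tremble":
                lat, peak = self.p.tremble_latency, self.p.tremble_amp
            else:
                lat, peak = self.p.egress_bout_latency, -self.p.egress_bout_depth
            self._event = (resp.kind, t, lat)
            self.log.events.append(GroundTruthEvent(
                presentation, stimulus_id, t, resp.kind, lat, peak))
        else:
            self._event = None
            self.log.events.append(GroundTruthEvent(
                presentation, stimulus_id, t, "none", math.nan, 0.0))

    def clear_event(self) -> None:
        self._event = None

    # -- dynamics ----------------------------------------------------------

    def _event_component(self, t: float) -> float:
        ev = self._event
        if ev is None:
            return 0.0
        kind, t_on, lat = ev
        p = self.p
        if kind == "ingress":
            if t < t_on:
                return 0.0
            tau = p.ingress_rise_time / _LOGISTIC_5_95
            t_mid = t_on + lat + tau * math.log(19.0)
            x = (t - t_mid) / tau
            w = p.ingress_amp / (1.0 + math.exp(-min(max(x, -500), 500)))
            over = t - (t_mid + p.ingress_hold)
            if over > 0:
                w *= math.exp(-over / p.ingress_release_tau)
                if w < 1e-3:
                    self._event = None
            return w
        if kind == "flinch":
            tt = t - (t_on + p.flinch_latency)
            if tt < 0:
                return 0.0
            if tt >= p.flinch_duration:
                self._event = None
                return 0.0
            return p.flinch_amp * math.sin(2 * math.pi * tt / p.flinch_duration)
        if kind == "tremble":
            tt = t - (t_on + p.tremble_latency)
            if tt < 0:
                return 0.0
            if tt >= p.tremble_duration:
                self._event = None
                return 0.0
            env = 0.5 * (1 - math.cos(2 * math.pi * tt / p.tremble_duration))
            return p.tremble_amp * env * math.sin(2 * math.pi * p.tremble_freq * tt)
        # egress_bout
        tt = t - (t_on + p.egress_bout_latency)
        if tt < 0:
            return 0.0
        if tt >= p.egress_bout_duration:
            self._event = None
            return 0.0
        edge = min(0.1, 0.25 * p.egress_bout_duration)
        s = min(tt / edge, (p.egress_bout_duration - tt) / edge, 1.0)
        return -p.egress_bout_depth * (3 * s * s - 2 * s ** 3)

    def _spontaneous(self, t: float, tether_slack: bool) -> float:
        p = self.p
        if t < self._spont_until:
            tt = t - self._spont_start
            d = self._spont_until - self._spont_start
            edge = min(0.1, 0.25 * d)
            s = min(tt / edge, (d - tt) / edge, 1.0)
            s = max(s, 0.0)
            return p.ingress_amp * (3 * s * s - 2 * s ** 3)
        if (tether_slack and self._event is None
                and p.spont_ingress_rate > 0
                and self.rng.random() < p.spont_ingress_rate * self.dt):
            self._spont_start = t
            self._spont_until = t + p.spont_ingress_duration
            return 0.0
        return 0.0

    def mouse_reaction(self, taut: bool, t: float) -> float:
        """Tether force (mN): decaying resistance bout while taut, else 0.

        A bout outlives slack gaps shorter than 0.2 s (the animal keeps its
        grip through flickers), so intermittent tautness does not restart
        the bout at full amplitude.
        """
        if not taut:
            if self._slack_since is None:
                self._slack_since = t
            elif t - self._slack_since > 0.2:
                self._resist_start = None
            return 0.0
        self._slack_since = None
        if self._resist_start is None:
            self._resist_start = t
        el = t - self._resist_start
        p = self.p
        rise = 1.0 - math.exp(-el / p.resist_rise) if p.resist_rise > 0 else 1.0
        return p.resist_force_amp * rise * math.exp(-el / p.resist_decay)

    def step(self, i: int, actuator_pos: float) -> tuple[float, float]:
        """Advance one sample; returns (position mm, force mN).

        The mouse's ingress aspirations all have finite durations
        (stimulus-evoked ingress holds for ``ingress_hold``, spontaneous
        attempts for ``spont_ingress_duration``), so a pullback bout of
        resistance always ends with the animal relenting: the desired
        position returns to rest and the tether slackens.
        """
        t = i * self.dt
        p = self.p
        breath = -p.breathing_amp * max(
            0.0, math.sin(2 * math.pi * p.breathing_rate * t + self.phase))
        if self._noise is not None and i < len(self._noise):
            noise = self._noise[i]
        elif p.noise_sd > 0:
            noise = float(self.rng.normal(0.0, p.noise_sd))
        else:
            noise = 0.0
        ev_kind = self._event[0] if self._event is not None else None
        ev = self._event_component(t)
        sp = self._spontaneous(t, not self._last_taut)
        ing = sp + (ev if ev_kind == "ingress" else 0.0)
        # breathing fades out while the animal executes an ingress
        suppress = min(max(1.0 - ing / (0.05 * p.ingress_amp), 0.0), 1.0)
        desired = self.rest + breath * suppress + noise + ev + sp
        position = min(desired, actuator_pos)
        taut = desired > actuator_pos + 1e-6
        force = self.mouse_reaction(taut, t)
        self._last_taut = taut
        return position, force
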