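"""Closed-loop trial controller for the virtual burrow assay.

Before each trial the controller pulls the burrow back to the egress
position, waits until the tether force drops below a quiet threshold
(the animal has ceased resisting), advances the actuator to the
ingress-permitting position (slackening the tether), and arms the trial:
the stimulus is delivered only once the animal has held the egress position
below the spontaneous-ingress threshold for the hold duration while keeping
the rolling position SD below threshold.  A spontaneous ingress during the
armed period aborts the trial, triggers another pullback, and the sequence
repeats.  During the stimulus and a set post-stimulus period the loop is
open: the actuator never restricts ingress.

The hold gate and the SD gate run concurrently — both must hold at the
moment of stimulus delivery.

:func:`replay_gate_check` re-derives every gate offline from the recorded
channels, independently of the state machine, and reports violations; it is
the safety auditor for recorded or simulated sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .core import SessionTrace
from .mouse import GroundTruthLog, MouseParams, VirtualMouse

__all__ = [
    "Phase",
    "ControllerConfig",
    "ControllerState",
    "ControllerEvent",
    "step",
    "run_closed_loop",
    "replay_gate_check",
]


class Phase(Enum):
    RETRACTING = "retracting"
    WAIT_FORCE_QUIET = "wait_force_quiet"
    ADVANCING = "advancing"
    ARMED = "armed"
    STIMULUS_OPEN_LOOP = "stimulus_open_loop"
    POST_OPEN_LOOP = "post_open_loop"
    ABORTED = "aborted"


@dataclass(frozen=True)
class ControllerConfig:
    """Gating thresholds and geometry of the trial machine.

    The paper-level quantities (force-quiet threshold, spontaneous-ingress
    position threshold theta_p, SD gate) are user-specified in the real
    instrument; the defaults here are consistent with the behavioural
    scales involved (mm-range quiescence, tens-of-mN resistance tails).
    """

    force_quiet_threshold: float = 50.0   # mN
    abort_position_threshold: float = 2.0  # mm above egress position (theta_p)
    sd_threshold: float = 0.5             # mm
    sd_window: float = 2.0                # s
    hold_duration: float = 5.0            # s
    ingress_position: float = 15.0        # mm, actuator ingress-permitting cmd
    egress_retract_distance: float = 15.0  # mm posterior to ingress position
    stim_duration: float = 8.0            # s
    post_open_loop_duration: float = 4.0  # s
    actuator_speed: float = 100.0         # mm/s
    armed_timeout: float = 60.0           # s; armed periods are bounded

    def __post_init__(self) -> None:
        for name in ("force_quiet_threshold", "abort_position_threshold",
                     "sd_threshold", "sd_window", "hold_duration",
                     "egress_retract_distance", "stim_duration",
                     "post_open_loop_duration", "actuator_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sd_window > self.hold_duration:
            raise ValueError("sd_window must not exceed hold_duration")

    @property
    def egress_position(self) -> float:
        return self.ingress_position - self.egress_retract_distance


@dataclass(frozen=True)
class ControllerEvent:
    name: str       # pullback | force_quiet | armed | abort | stimulus_on |
    #                 stimulus_off | trial_complete
    time: float     # session seconds
    info: dict = field(default_factory=dict)


class ControllerState:
    """Mutable state of the trial machine (one instance per session)."""

    def __init__(self, config: ControllerConfig, sample_rate: float):
        self.cfg = config
        self.fs = float(sample_rate)
        self.dt = 1.0 / self.fs
        self.phase = Phase.RETRACTING
        self.actuator = config.ingress_position
        self.phase_entered = 0.0
        self.pullback_count = 1   # the initial retraction counts as a pullback
        self.abort_count = 0
        self.stimulus_count = 0
        self.armed_clean_since: float | None = None
        # rolling-SD ring buffer over the position channel (population SD)
        self._w = max(1, int(round(config.sd_window * sample_rate)))
        self._buf = np.zeros(self._w)
        self._idx = 0
        self._count = 0
        self._sum = 0.0
        self._sumsq = 0.0

    def _push(self, x: float) -> None:
        if self._count == self._w:
            old = self._buf[self._idx]
            self._sum -= old
            self._sumsq -= old * old
        else:
            self._count += 1
        self._buf[self._idx] = x
        self._idx = (self._idx + 1) % self._w
        self._sum += x
        self._sumsq += x * x

    def rolling_sd(self) -> float:
        """Causal population SD over the last sd_window of position samples."""
        c = self._count
        if c == 0:
            return math.inf
        m = self._sum / c
        v = self._sumsq / c - m * m
        return math.sqrt(max(v, 0.0))

    def window_full(self) -> bool:
        return self._count == self._w

    def _enter(self, phase: Phase, t: float) -> None:
        self.phase = phase
        self.phase_entered = t


def step(state: ControllerState, position: float, force: float,
         t: float) -> tuple[float, list[ControllerEvent]]:
    """Advance the trial machine by one sample.

    Returns the actuator command (mm) for the next sample and any events
    emitted at this sample.  Call exactly once per sample at the session
    rate.
    """
    if not (math.isfinite(position) and math.isfinite(force)):
        raise ValueError("non-finite sensor sample")
    cfg = state.cfg
    events: list[ControllerEvent] = []
    state._push(position)
    dmax = cfg.actuator_speed * state.dt
    ph = state.phase

    if ph is Phase.RETRACTING:
        target = cfg.egress_position
        if state.actuator > target:
            state.actuator = max(target, state.actuator - dmax)
        if state.actuator <= target + 1e-9:
            state._enter(Phase.WAIT_FORCE_QUIET, t)
    elif ph is Phase.WAIT_FORCE_QUIET:
        if force < cfg.force_quiet_threshold:
            events.append(ControllerEvent("force_quiet", t))
            state._enter(Phase.ADVANCING, t)
    elif ph is Phase.ADVANCING:
        target = cfg.ingress_position
        if state.actuator < target:
            state.actuator = min(target, state.actuator + dmax)
        if state.actuator >= target - 1e-9:
            state._enter(Phase.ARMED, t)
            state.armed_clean_since = t
            events.append(ControllerEvent("armed", t))
    elif ph is Phase.ARMED:
        rel = position - cfg.egress_position
        if rel > cfg.abort_position_threshold:
            state.abort_count += 1
            events.append(ControllerEvent(
                "abort", t, {"reason": "spontaneous_ingress", "position": rel}))
            state._enter(Phase.ABORTED, t)
        elif t - state.phase_entered > cfg.armed_timeout:
            state.abort_count += 1
            events.append(ControllerEvent("abort", t, {"reason": "timeout"}))
            state._enter(Phase.ABORTED, t)
        else:
            held = t - state.armed_clean_since
            if (held >= cfg.hold_duration and state.window_full()
                    and state.rolling_sd() < cfg.sd_threshold):
                state.stimulus_count += 1
                events.append(ControllerEvent(
                    "stimulus_on", t, {"index": state.stimulus_count}))
                state._enter(Phase.STIMULUS_OPEN_LOOP, t)
    elif ph is Phase.STIMULUS_OPEN_LOOP:
        # open loop: the actuator never restricts ingress
        state.actuator = cfg.ingress_position
        if t - state.phase_entered >= cfg.stim_duration:
            events.append(ControllerEvent("stimulus_off", t))
            state._enter(Phase.POST_OPEN_LOOP, t)
    elif ph is Phase.POST_OPEN_LOOP:
        state.actuator = cfg.ingress_position
        if t - state.phase_entered >= cfg.post_open_loop_duration:
            events.append(ControllerEvent("trial_complete", t))
            state.pullback_count += 1
            events.append(ControllerEvent("pullback", t))
            state._enter(Phase.RETRACTING, t)
    elif ph is Phase.ABORTED:
        state.pullback_count += 1
        events.append(ControllerEvent("pullback", t))
        state._enter(Phase.RETRACTING, t)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"malformed controller state: {ph!r}")

    return state.actuator, events


def run_closed_loop(params: MouseParams, config: ControllerConfig,
                    stimulus_ids: list[int], sample_rate: float = 1000.0,
                    seed: int = 0, max_duration: float = 600.0,
                    ) -> tuple[SessionTrace, GroundTruthLog, list[ControllerEvent]]:
    """Co-simulate a virtual mouse against the closed-loop controller.

    ``stimulus_ids`` is the ordered list of stimuli to deliver; the
    controller decides *when* each is delivered (after its gates pass).
    The session ends when the last trial completes or at ``max_duration``.
    """
    fs = float(sample_rate)
    n_max = int(round(max_duration * fs))
    mouse = VirtualMouse(params, fs, seed,
                         rest_position=config.egress_position,
                         n_samples_hint=n_max)
    state = ControllerState(config, fs)

    pos = np.empty(n_max)
    frc = np.empty(n_max)
    act = np.empty(n_max)
    stim = np.zeros(n_max, dtype=np.int64)
    events: list[ControllerEvent] = []

    queue = list(stimulus_ids)
    current_stim = 0
    actuator_cmd = state.actuator
    n = n_max
    for i in range(n_max):
        t = i / fs
        cmd_in_force = actuator_cmd
        position, force = mouse.step(i, cmd_in_force)
        actuator_cmd, ev = step(state, position, force, t)
        pos[i] = position
        frc[i] = force
        act[i] = cmd_in_force
        for e in ev:
            if e.name == "stimulus_on":
                current_stim = queue.pop(0) if queue else 0
                e.info["stimulus_id"] = current_stim
                mouse.on_stimulus(current_stim, t)
            elif e.name == "stimulus_off":
                current_stim = 0
        stim[i] = current_stim
        events.extend(ev)
        if not queue and state.phase is Phase.RETRACTING and \
                state.stimulus_count == len(stimulus_ids) and \
                any(e.name == "trial_complete" for e in ev):
            n = i + 1
            break

    trace = SessionTrace(
        sample_rate=fs,
        position=pos[:n], force=frc[:n], actuator=act[:n], stimulus=stim[:n],
        metadata={"seed": seed, "mode": "closed_loop"},
    )
    return trace, mouse.log, events


@dataclass(frozen=True)
class GateViolation:
    stimulus_time: float
    gate: str
    detail: str


def replay_gate_check(trace: SessionTrace, config: ControllerConfig,
                      events: list[ControllerEvent],
                      tol: float = 1e-6) -> list[GateViolation]:
    """Offline audit of every stimulus delivery against the gates.

    Recomputes each gate directly from the recorded channels — position
    below the abort threshold throughout the preceding hold duration,
    rolling population SD below threshold over the preceding SD window, and
    a force-quiet crossing between the previous pullback and the stimulus —
    without consulting the state machine.  Returns one record per violated
    gate (empty list = clean session).
    """
    fs = trace.sample_rate
    pos = trace.position
    frc = trace.force
    hold_n = int(round(config.hold_duration * fs))
    sd_n = int(round(config.sd_window * fs))
    stim_times = [e.time for e in events if e.name == "stimulus_on"]
    pull_times = sorted(e.time for e in events if e.name == "pullback")

    violations: list[GateViolation] = []
    for ts in stim_times:
        i = int(round(ts * fs))
        # hold gate: position stayed below theta_p over the full hold window
        seg = pos[max(0, i - hold_n + 1): i + 1] - config.egress_position
        if len(seg) < hold_n:
            violations.append(GateViolation(ts, "hold", "window truncated"))
        elif np.max(seg) > config.abort_position_threshold + tol:
            violations.append(GateViolation(
                ts, "hold",
                f"position {np.max(seg):.3f} mm above threshold in hold window"))
        # SD gate: population SD over the trailing sd_window below threshold
        win = pos[max(0, i - sd_n + 1): i + 1]
        if len(win) < sd_n:
            violations.append(GateViolation(ts, "sd", "window truncated"))
        else:
            sd = float(np.std(win))
            if sd >= config.sd_threshold + tol:
                violations.append(GateViolation(
                    ts, "sd", f"rolling SD {sd:.4f} mm at stimulus"))
        # force gate: force dropped below threshold after the last pullback
        prior = [tp for tp in pull_times if tp < ts]
        j0 = int(round(prior[-1] * fs)) if prior else 0
        if not np.any(frc[j0:i + 1] < config.force_quiet_threshold - tol):
            violations.append(GateViolation(
                ts, "force_quiet", "no sub-threshold force before stimulus"))
    return violations
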