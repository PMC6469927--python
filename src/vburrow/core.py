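"""Shared domain types and epoch arithmetic for the virtual burrow assay.

Conventions used throughout the package:

* Position is in millimetres, ingress-positive: positive displacement means
  the burrow is moving toward the animal's head.  Zero is the instrument
  origin, not the behavioural baseline; trial analysis re-baselines each
  trial to its own pre-stimulus mean.
* Force is in millinewtons, time in seconds.
* Epochs are half-open ``[start, end)`` and convert to sample indices with
  ``floor(t * fs)`` so trial slicing is deterministic and gap-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SessionTrace",
    "Epoch",
    "TrialRecord",
    "DetectionConfig",
    "SpikeData",
    "rebaseline",
    "epoch_to_indices",
    "extract_trial",
]


@dataclass(frozen=True)
class Epoch:
    """Half-open time interval [start, end) in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.start) and math.isfinite(self.end)):
            raise ValueError("epoch bounds must be finite")
        if self.end <= self.start:
            raise ValueError(f"epoch end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass
class SessionTrace:
    """Uniformly sampled multichannel recording of one assay session.

    Channels
    --------
    position : mm, ingress-positive burrow position (laser displacement sensor).
    force : mN, tether force (load cell); zero when the tether is slack.
    actuator : mm, linear-actuator command position in the same coordinates
        as ``position`` (the burrow cannot ingress past it).
    stimulus : integer stimulus-id channel; 0 means no stimulus is on.
    """

    sample_rate: float
    position: np.ndarray
    force: np.ndarray
    actuator: np.ndarray
    stimulus: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.position = np.asarray(self.position, dtype=np.float64)
        self.force = np.asarray(self.force, dtype=np.float64)
        self.actuator = np.asarray(self.actuator, dtype=np.float64)
        self.stimulus = np.asarray(self.stimulus, dtype=np.int64)
        n = len(self.position)
        if n < 1:
            raise ValueError("session trace must contain at least one sample")
        for name in ("force", "actuator", "stimulus"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length differs from position")

    @property
    def n_samples(self) -> int:
        return len(self.position)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds (implicit from index)."""
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation cut out of a session.

    ``rel_position`` covers ``[baseline.start, post.end)`` and is the raw
    position minus its mean over the baseline epoch, so a value of +2 mm
    means 2 mm of ingress relative to the pre-stimulus resting position.
    Epoch fields are in session time; ``rel_position[0]`` corresponds to
    ``baseline.start``.
    """

    trial_index: int
    stimulus_id: int
    baseline: Epoch
    stim: Epoch
    post: Epoch
    rel_position: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based")
        if not (self.baseline.end <= self.stim.start < self.stim.end <= self.post.end):
            raise ValueError("epochs must be ordered baseline < stim < post")

    def epoch_slice(self, epoch: Epoch) -> np.ndarray:
        """rel_position samples falling in ``epoch`` (session time)."""
        i0, i1 = epoch_to_indices(
            Epoch(epoch.start - self.baseline.start, epoch.end - self.baseline.start),
            self.sample_rate,
        )
        if i0 < 0 or i1 > len(self.rel_position):
            raise ValueError("epoch outside trial extent")
        return self.rel_position[i0:i1]


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for behaviour calls on re-baselined trial traces.

    ``ingress_threshold`` (mm) is the maximum-displacement criterion for an
    ingress call; ``onset_threshold`` (mm) the first-crossing criterion for
    onset latency; ``high_latency_threshold`` (s) splits fast from slow
    conditioned responses.  Flinch thresholds and the spectral bands for
    trembling/breathing are operational definitions, exposed for tuning.
    """

    ingress_threshold: float = 2.0
    onset_threshold: float = 0.75
    high_latency_threshold: float = 1.0
    flinch_peak_min: float = 0.3
    flinch_net_max: float = 0.2
    flinch_window: float = 0.5
    tremble_band: tuple[float, float] = (15.0, 30.0)
    breathing_band: tuple[float, float] = (1.0, 4.0)
    tremble_ratio_threshold: float = 3.0
    egress_bout_threshold: float = 2.0
    egress_merge_gap: float = 0.1
    force_quiet_threshold: float = 50.0
    force_quiet_duration: float = 0.5

    def __post_init__(self) -> None:
        if not (self.ingress_threshold > self.onset_threshold > 0):
            raise ValueError("require ingress_threshold > onset_threshold > 0")
        lo1, hi1 = self.breathing_band
        lo2, hi2 = self.tremble_band
        if not (0 < lo1 < hi1 and 0 < lo2 < hi2):
            raise ValueError("bands must be positive increasing intervals")
        if max(lo1, lo2) < min(hi1, hi2):
            raise ValueError("tremble_band and breathing_band must be disjoint")


@dataclass
class SpikeData:
    """Spike times per unit, seconds, nondecreasing within each unit."""

    units: list[np.ndarray]

    def __post_init__(self) -> None:
        self.units = [np.asarray(u, dtype=np.float64) for u in self.units]
        for i, u in enumerate(self.units):
            if u.size and np.any(np.diff(u) < 0):
                raise ValueError(f"unit {i} spike times are not nondecreasing")

    @property
    def n_units(self) -> int:
        return len(self.units)


def rebaseline(segment: np.ndarray, baseline: Epoch, sample_rate: float,
               segment_start: float = 0.0) -> np.ndarray:
    """Subtract the mean over ``baseline`` from a position segment.

    ``baseline`` is given in the same time base as ``segment_start`` (the
    time of ``segment[0]``).  The returned series has zero mean over the
    baseline samples; applying the operation twice is a no-op.
    """
    segment = np.asarray(segment, dtype=np.float64)
    i0, i1 = epoch_to_indices(
        Epoch(baseline.start - segment_start, baseline.end - segment_start),
        sample_rate,
    )
    if i0 < 0 or i1 > len(segment):
        raise ValueError("baseline epoch lies outside the segment")
    if i1 <= i0:
        raise ValueError("baseline epoch is degenerate (spans no samples)")
    return segment - segment[i0:i1].mean()


def epoch_to_indices(e: Epoch, sample_rate: float) -> tuple[int, int]:
    """Convert an epoch to a half-open sample-index range [i0, i1).

    Both bounds map through ``floor(t * fs)``.  Equivalently, sample ``i``
    (covering the period ``[i/fs, (i+1)/fs)``) belongs to the epoch iff the
    period's right edge ``(i+1)/fs`` falls in ``(start, end]``.  Epochs
    spanning at least one sample period always yield a nonempty range;
    shorter epochs may come back empty, which callers treat as degenerate.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    # +1e-9 guards against 0.3 * 1000 -> 299.999... style float dust
    i0 = int(math.floor(e.start * sample_rate + 1e-9))
    i1 = int(math.floor(e.end * sample_rate + 1e-9))
    return i0, i1


def extract_trial(trace: SessionTrace, stim: Epoch, trial_index: int,
                  stimulus_id: int, baseline_duration: float = 1.0,
                  post_duration: float = 4.0) -> TrialRecord:
    """Cut one trial out of a session and re-baseline it.

    The baseline window is the ``baseline_duration`` seconds immediately
    preceding stimulus onset (configurable; the resting position right
    before the stimulus defines zero displacement).
    """
    baseline = Epoch(stim.start - baseline_duration, stim.start)
    post = Epoch(stim.end, stim.end + post_duration)
    i0, i1 = epoch_to_indices(Epoch(baseline.start, post.end), trace.sample_rate)
    if i0 < 0 or i1 > trace.n_samples:
        raise ValueError("trial epochs extend outside the session trace")
    rel = rebaseline(trace.position[i0:i1], baseline, trace.sample_rate,
                     segment_start=baseline.start)
    return TrialRecord(
        trial_index=trial_index,
        stimulus_id=stimulus_id,
        baseline=baseline,
        stim=stim,
        post=post,
        rel_position=rel,
        sample_rate=trace.sample_rate,
    )
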