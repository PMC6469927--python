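"""Behaviour calls on re-baselined trial traces.

Operational definitions:

* **ingress** — maximum displacement during the stimulus epoch strictly
  exceeds the ingress threshold (2 mm by default).
* **onset latency** — time from stimulus onset to the first raw sample
  whose re-baselined displacement exceeds the onset threshold (0.75 mm by
  default); no smoothing is applied before thresholding.
* **flinch** — a short transient whose peak magnitude exceeds the flinch
  peak threshold but whose net displacement at the end of the post-onset
  window is near zero; ingress takes precedence.
* **trembling** — excess band power in the tremble band relative to the
  breathing band; an independent flag, since trembling can precede ingress
  on the same trial.
* **egress bout** — a maximal run of displacement below the negative bout
  threshold, measured on traces re-baselined to the ingressed rest position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import DetectionConfig, Epoch, TrialRecord, epoch_to_indices

__all__ = [
    "EventCall",
    "max_displacement",
    "classify_ingress",
    "onset_latency",
    "classify_flinch",
    "tremble_score",
    "classify_tremble",
    "detect_egress_bouts",
    "integrate_force",
    "classify_trial",
    "detect_session",
    "build_trial_table",
    "TRIAL_TABLE_COLUMNS",
]


@dataclass(frozen=True)
class EventCall:
    """Detected behaviour for one trial.

    ``kind`` is the primary class (precedence: ingress > flinch > none);
    ``tremble`` is an independent flag.  ``onset_latency`` is present
    (non-nan) iff the trial is an ingress and the onset threshold was
    crossed.
    """

    kind: str                      # ingress | flinch | none
    max_displacement: float        # mm, signed max of rel_position
    net_displacement: float        # mm at end of flinch window
    onset_latency: float           # s, nan if absent
    tremble: bool
    tremble_power_ratio: float     # nan if epoch too short


def max_displacement(trial: TrialRecord, epoch: Epoch) -> float:
    """Signed maximum of rel_position over ``epoch`` (ingress-positive)."""
    seg = trial.epoch_slice(epoch)
    if len(seg) == 0:
        raise ValueError("epoch spans no samples")
    return float(np.max(seg))


def classify_ingress(trial: TrialRecord, cfg: DetectionConfig,
                     epoch: Epoch | None = None) -> bool:
    """True iff max displacement strictly exceeds the ingress threshold."""
    if epoch is None:
        epoch = trial.stim
    return max_displacement(trial, epoch) > cfg.ingress_threshold


def onset_latency(trial: TrialRecord, cfg: DetectionConfig) -> float:
    """Latency from stimulus onset to the first supra-threshold sample.

    Searches the raw re-baselined samples from stimulus onset to the end of
    the post epoch; returns nan if the threshold is never crossed.
    """
    seg = trial.epoch_slice(Epoch(trial.stim.start, trial.post.end))
    above = np.nonzero(seg > cfg.onset_threshold)[0]
    if len(above) == 0:
        return math.nan
    return float(above[0] / trial.sample_rate)


def classify_flinch(trial: TrialRecord, cfg: DetectionConfig) -> bool:
    """Transient with large peak but near-zero net displacement.

    Evaluated over the ``flinch_window`` seconds following stimulus onset;
    an ingress trial is never a flinch (exclusivity rule).
    """
    if classify_ingress(trial, cfg):
        return False
    end = min(trial.stim.start + cfg.flinch_window, trial.post.end)
    seg = trial.epoch_slice(Epoch(trial.stim.start, end))
    if len(seg) == 0:
        return False
    peak = float(np.max(np.abs(seg)))
    net = float(seg[-1])
    return peak > cfg.flinch_peak_min and abs(net) < cfg.flinch_net_max


def tremble_score(trial: TrialRecord, cfg: DetectionConfig,
                  epoch: Epoch | None = None) -> float:
    """Band-power ratio tremble_band / breathing_band on the detrended epoch.

    Uses a Hann-windowed periodogram.  Raises if the epoch is too short to
    resolve the tremble band (needs at least ~3 cycles of its lower edge).
    """
    if epoch is None:
        epoch = trial.stim
    seg = trial.epoch_slice(epoch)
    lo_t, hi_t = cfg.tremble_band
    lo_b, hi_b = cfg.breathing_band
    if len(seg) / trial.sample_rate < 3.0 / lo_t:
        raise ValueError("epoch too short for a spectral estimate")
    seg = sps.detrend(seg)
    f, pxx = sps.periodogram(seg, fs=trial.sample_rate, window="hann")
    p_t = float(pxx[(f >= lo_t) & (f <= hi_t)].sum())
    p_b = float(pxx[(f >= lo_b) & (f <= hi_b)].sum())
    if p_b <= 0:
        return math.inf if p_t > 0 else 0.0
    return p_t / p_b


def classify_tremble(trial: TrialRecord, cfg: DetectionConfig,
                     epoch: Epoch | None = None) -> bool:
    return tremble_score(trial, cfg, epoch) > cfg.tremble_ratio_threshold


def detect_egress_bouts(trace: np.ndarray, sample_rate: float,
                        bout_threshold: float = 2.0,
                        merge_gap: float = 0.1,
                        ) -> list[tuple[float, float, float]]:
    """Egress bouts on a trace re-baselined to the ingressed rest position.

    Returns ``(onset s, duration s, depth mm)`` for each maximal run of
    displacement below ``-bout_threshold``; runs separated by less than
    ``merge_gap`` seconds are merged.  Depth is the magnitude of the
    deepest excursion within the (merged) run.
    """
    trace = np.asarray(trace, dtype=np.float64)
    below = trace < -bout_threshold
    if not below.any():
        return []
    d = np.diff(below.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(len(trace))
    gap_n = merge_gap * sample_rate
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        depth = float(-np.min(trace[s:e]))
        out.append((s / sample_rate, (e - s) / sample_rate, depth))
    return out


def integrate_force(force: np.ndarray, sample_rate: float,
                    pullback_onset: float, cfg: DetectionConfig,
                    ) -> tuple[float, float, bool]:
    """Total force impulse (mN*s) from a pullback until resistance ends.

    Integration (left Riemann sum at the sample period) runs from
    ``pullback_onset`` until the force first stays below
    ``force_quiet_threshold`` for ``force_quiet_duration`` consecutive
    seconds.  Returns ``(integral, stop_time, criterion_met)``; if the stop
    criterion is never met the integral extends to the end of the trace and
    the flag is False.
    """
    force = np.asarray(force, dtype=np.float64)
    i0 = int(math.floor(pullback_onset * sample_rate + 1e-9))
    if not 0 <= i0 < len(force):
        raise ValueError("pullback onset outside the trace")
    quiet = force[i0:] < cfg.force_quiet_threshold
    need = max(1, int(round(cfg.force_quiet_duration * sample_rate)))
    # first index (relative to i0) where a quiet run of length `need` begins
    if len(quiet) >= need:
        runs = np.convolve(quiet.astype(np.int32),
                           np.ones(need, dtype=np.int32), "valid")
        hits = np.nonzero(runs == need)[0]
    else:
        hits = np.array([], dtype=np.int64)
    if hits.size:
        stop_rel, met = int(hits[0]), True
    else:
        stop_rel, met = len(quiet), False
    integral = float(force[i0:i0 + stop_rel].sum() / sample_rate)
    return integral, (i0 + stop_rel) / sample_rate, met


def classify_trial(trial: TrialRecord, cfg: DetectionConfig) -> EventCall:
    """Full behaviour call for one trial (primary class + tremble flag)."""
    md = max_displacement(trial, trial.stim)
    is_ingress = md > cfg.ingress_threshold
    lat = onset_latency(trial, cfg) if is_ingress else math.nan
    end = min(trial.stim.start + cfg.flinch_window, trial.post.end)
    fl_seg = trial.epoch_slice(Epoch(trial.stim.start, end))
    net = float(fl_seg[-1]) if len(fl_seg) else math.nan
    if is_ingress:
        kind = "ingress"
    elif classify_flinch(trial, cfg):
        kind = "flinch"
    else:
        kind = "none"
    # trembling is scored on the pre-ingress portion of the stimulus epoch:
    # the ingress step itself would swamp the spectrum (trembling can
    # precede ingress by seconds on the same trial)
    t_end = trial.stim.end
    if is_ingress and math.isfinite(lat):
        t_end = min(trial.stim.start + lat, trial.stim.end)
    try:
        ratio = tremble_score(trial, cfg, Epoch(trial.stim.start, t_end))
        trembling = ratio > cfg.tremble_ratio_threshold
    except ValueError:
        ratio, trembling = math.nan, False
    return EventCall(kind=kind, max_displacement=md, net_displacement=net,
                     onset_latency=lat, tremble=trembling,
                     tremble_power_ratio=ratio)


def detect_session(trace, cfg: DetectionConfig,
                   baseline_duration: float = 1.0,
                   post_duration: float = 4.0,
                   mouse_id: str = "m0", session_id: str = "s0",
                   ) -> pd.DataFrame:
    """Run the full detection pipeline on one session.

    Stimulus presentations are taken from the rising edges of the stimulus
    channel; each is cut into a re-baselined trial and classified.  Trials
    whose analysis window would extend outside the recording are dropped.
    Returns the flat trial table.
    """
    from .core import extract_trial

    stim = trace.stimulus
    edges = np.nonzero((stim[1:] != 0) & (stim[:-1] == 0))[0] + 1
    if len(stim) and stim[0] != 0:
        edges = np.concatenate([[0], edges])
    trials, calls = [], []
    counts: dict[int, int] = {}
    fs = trace.sample_rate
    for i0 in edges:
        sid = int(stim[i0])
        offs = np.nonzero(stim[i0:] != sid)[0]
        i1 = i0 + (int(offs[0]) if len(offs) else len(stim) - i0)
        counts[sid] = counts.get(sid, 0) + 1
        onset, offset = i0 / fs, i1 / fs
        if onset - baseline_duration < 0 or \
                (offset + post_duration) * fs > trace.n_samples + 0.5:
            continue
        trial = extract_trial(trace, Epoch(onset, offset), counts[sid], sid,
                              baseline_duration, post_duration)
        trials.append(trial)
        calls.append(classify_trial(trial, cfg))
    return build_trial_table(trials, calls, mouse_id, session_id)


TRIAL_TABLE_COLUMNS = [
    "session_id", "mouse_id", "stimulus_id", "trial_index",
    "max_displacement", "ingress", "latency", "kind", "tremble",
]


def build_trial_table(trials: list[TrialRecord], calls: list[EventCall],
                      mouse_id: str = "m0", session_id: str = "s0",
                      ) -> pd.DataFrame:
    """Flat per-trial results table (one row per stimulus presentation)."""
    if len(trials) != len(calls):
        raise ValueError("trials and calls must align")
    rows = [{
        "session_id": session_id,
        "mouse_id": mouse_id,
        "stimulus_id": tr.stimulus_id,
        "trial_index": tr.trial_index,
        "max_displacement": c.max_displacement,
        "ingress": c.kind == "ingress",
        "latency": c.onset_latency,
        "kind": c.kind,
        "tremble": c.tremble,
    } for tr, c in zip(trials, calls)]
    return pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)
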