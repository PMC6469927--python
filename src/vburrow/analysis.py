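"""Trial-table and neural-alignment analyses.

Operates on the flat per-trial table produced by the detection pipeline
(one row per stimulus presentation, pooled across mice): habituation
curves, pooled ingress rates for conditioning contrasts, high-latency
fractions over extinction, the Spearman trend test, and the firing-rate
versus behavioural-covariate regressions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist

from .core import SessionTrace, SpikeData

__all__ = [
    "habituation_curve",
    "ingress_rate",
    "high_latency_fraction",
    "spearman",
    "extinction_trend",
    "bin_firing",
    "velocity_from_position",
    "RateBehaviorTable",
    "make_rate_behavior_table",
    "rate_behavior_regression",
]


def habituation_curve(table: pd.DataFrame, block_col: str = "trial_index",
                      ) -> pd.DataFrame:
    """Across-mouse median of max displacement per (stimulus, block).

    Each mouse contributes one presentation of each stimulus per block, so
    the median is taken across mice.  Blocks with no trials are absent.
    """
    if table.empty:
        raise ValueError("trial table is empty")
    g = (table.groupby(["stimulus_id", block_col])["max_displacement"]
         .median().rename("median_max_displacement"))
    return g.reset_index()


def ingress_rate(table: pd.DataFrame, trial_range: tuple[int, int],
                 stimulus_id: int) -> tuple[int, int, float]:
    """Pooled ingress rate over an inclusive trial-index range.

    Returns ``(k, n, k/n)`` with trials pooled across mice.
    """
    lo, hi = trial_range
    sel = table[(table["stimulus_id"] == stimulus_id)
                & (table["trial_index"] >= lo)
                & (table["trial_index"] <= hi)]
    n = len(sel)
    if n == 0:
        raise ValueError("no trials in range")
    k = int(sel["ingress"].sum())
    return k, n, k / n


def high_latency_fraction(table: pd.DataFrame, threshold: float = 1.0,
                          ) -> pd.Series:
    """Per-trial-index fraction of ingresses with latency above threshold.

    Indices with zero ingress trials are absent from the result.
    """
    ing = table[table["ingress"].astype(bool)]
    if ing.empty:
        return pd.Series(dtype=float, name="high_latency_fraction")
    frac = (ing.groupby("trial_index")["latency"]
            .apply(lambda s: float((s > threshold).mean())))
    frac.name = "high_latency_fraction"
    return frac


def spearman(x, y, exact_max_n: int = 10, seed: int | None = None,
             ) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use the average method for ties.  For n above ``exact_max_n``
    the p-value is the standard large-sample approximation (t-distribution
    on the transformed coefficient); for small n it is an exact permutation
    p over all n! orderings of one rank vector.

    Raises on constant input, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rx = rankdata(x)
    ry = rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _spearman_exact_p(rx, ry, rs)
    else:
        tt = rs * math.sqrt((n - 2) / max(1e-300, 1.0 - rs * rs))
        p = float(2.0 * t_dist.sf(abs(tt), n - 2))
    return rs, min(p, 1.0)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rs_obs: float) -> float:
    """Exact two-sided permutation p over all orderings of ry."""
    n = len(rx)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt(float((sx ** 2).sum() * (sy ** 2).sum()))
    count = 0
    total = 0
    thresh = abs(rs_obs) * denom - 1e-9
    for perm in permutations(sy):
        s = float(np.dot(sx, perm))
        if abs(s) >= thresh:
            count += 1
        total += 1
    return count / total


def extinction_trend(fractions: pd.Series) -> tuple[float, float]:
    """Spearman trend of high-latency fraction against trial index.

    ``fractions`` is indexed by trial index (as produced by
    :func:`high_latency_fraction`).  Returns ``(r_s, p)``.
    """
    if len(fractions) < 3:
        raise ValueError("need at least 3 trial indices")
    return spearman(np.asarray(fractions.index, dtype=float),
                    fractions.to_numpy())


# -- neural alignment ------------------------------------------------------


def bin_firing(spikes: SpikeData, bin_width: float, session_length: float,
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit firing rates in half-open bins, plus the across-unit mean.

    Returns ``(unit_rates, mean_rate)`` with ``unit_rates`` of shape
    (n_units, n_bins) in spk/s.  Spikes in ``[0, session_length)`` are
    conserved: counts sum to the number of in-range spike times.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(math.ceil(session_length / bin_width - 1e-9))
    rates = np.zeros((spikes.n_units, n_bins))
    for u, times in enumerate(spikes.units):
        times = times[(times >= 0) & (times < session_length)]
        idx = np.floor(times / bin_width).astype(np.int64)
        idx = np.clip(idx, 0, n_bins - 1)
        rates[u] = np.bincount(idx, minlength=n_bins) / bin_width
    mean_rate = rates.mean(axis=0) if spikes.n_units else np.zeros(n_bins)
    return rates, mean_rate


def velocity_from_position(position: np.ndarray, sample_rate: float,
                           smoothing_window: float = 0.05) -> np.ndarray:
    """|velocity| in mm/s from a position trace.

    The position is smoothed with a moving average (edges replicated) of
    ``smoothing_window`` seconds, then differentiated with central
    differences; output length matches the input.
    """
    position = np.asarray(position, dtype=np.float64)
    if len(position) < 2:
        raise ValueError("need at least 2 samples")
    w = max(1, int(round(smoothing_window * sample_rate)))
    if w > 1:
        pad = np.concatenate([np.repeat(position[0], w // 2), position,
                              np.repeat(position[-1], (w - 1) // 2)])
        kernel = np.ones(w) / w
        smooth = np.convolve(pad, kernel, mode="valid")
    else:
        smooth = position
    return np.abs(np.gradient(smooth) * sample_rate)


@dataclass
class RateBehaviorTable:
    """Firing rates aligned to behavioural covariates in fixed-width bins."""

    bin_width: float
    mean_rate: np.ndarray      # (n_bins,)
    unit_rates: np.ndarray     # (n_units, n_bins)
    position: np.ndarray       # mm, per-bin mean
    abs_velocity: np.ndarray   # mm/s, per-bin mean
    force: np.ndarray          # mN, per-bin mean

    def __post_init__(self) -> None:
        n = len(self.mean_rate)
        for name in ("position", "abs_velocity", "force"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} misaligned")
        if self.unit_rates.shape[1] != n:
            raise ValueError("unit_rates misaligned")

    @property
    def covariates(self) -> dict[str, np.ndarray]:
        return {"position": self.position, "abs_velocity": self.abs_velocity,
                "force": self.force}


def make_rate_behavior_table(spikes: SpikeData, trace: SessionTrace,
                             bin_width: float = 0.1,
                             smoothing_window: float = 0.05,
                             ) -> RateBehaviorTable:
    """Bin spikes and behaviour channels on a common time base."""
    length = trace.duration
    unit_rates, mean_rate = bin_firing(spikes, bin_width, length)
    n_bins = len(mean_rate)
    vel = velocity_from_position(trace.position, trace.sample_rate,
                                 smoothing_window)
    idx = np.floor(np.arange(trace.n_samples) / trace.sample_rate
                   / bin_width).astype(np.int64)
    idx = np.clip(idx, 0, n_bins - 1)

    def binmean(x: np.ndarray) -> np.ndarray:
        return np.bincount(idx, weights=x, minlength=n_bins) / \
            np.bincount(idx, minlength=n_bins)

    return RateBehaviorTable(
        bin_width=bin_width,
        mean_rate=mean_rate,
        unit_rates=unit_rates,
        position=binmean(trace.position),
        abs_velocity=binmean(vel),
        force=binmean(trace.force),
    )


def _r_squared(y: np.ndarray, x: np.ndarray) -> float:
    """R^2 of ordinary least squares of y on x with intercept."""
    vx = x.var()
    if vx <= 0:
        raise ValueError("zero-variance covariate")
    vy = y.var()
    if vy <= 0:
        return 0.0
    c = np.cov(x, y, ddof=0)[0, 1]
    return float(c * c / (vx * vy))


def rate_behavior_regression(table: RateBehaviorTable) -> pd.DataFrame:
    """Single-covariate OLS R^2 for the mean rate and each unit.

    One row per covariate; the ``mean_rate`` column is the R^2 of the mean
    firing rate on that covariate, ``median_unit`` the median across
    single-unit R^2 values.
    """
    rows = []
    for name, x in table.covariates.items():
        r2_mean = _r_squared(table.mean_rate, x)
        r2_units = np.array([_r_squared(u, x) for u in table.unit_rates])
        rows.append({"covariate": name, "mean_rate": r2_mean,
                     "median_unit": float(np.median(r2_units)) if len(r2_units)
                     else math.nan,
                     "unit_r2": r2_units})
    return pd.DataFrame(rows)
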