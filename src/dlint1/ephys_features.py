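"""Stimulus-locked spike-train features and group comparison.

The interneuron's stereotyped response to a sustained vibration stimulus is
resolved into four activity periods relative to stimulus onset/offset:

* spontaneous: the 3 s preceding onset,
* on-phasic:   the first 75 ms after onset,
* inhibitory:  from the end of the on-phasic period to stimulus offset,
* rebound:     a 75 ms window starting 25 ms after offset.

Per neuron the pipeline computes trial-averaged firing rates per period, the
Relative Inhibition ``1 - rate_inhibitory / rate_spontaneous``, the on-phasic
spike-timing features (first-spike latency T0 and the first three interspike
intervals T1-T3), and a time-resolved rate profile via adaptive kernel density
estimation (global Gaussian bandwidth by cost minimization, then Abramson
local adaptation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .stats_engine import mann_whitney, ols_fit, welch_t

__all__ = [
    "VoltageTrace",
    "SpikeTrainTrial",
    "PeriodWindows",
    "RateProfile",
    "PERIODS",
    "detect_spikes",
    "make_windows",
    "period_rates",
    "relative_inhibition",
    "spike_timing_features",
    "rate_profile",
    "features_per_neuron",
    "compare_groups_ephys",
]

PERIODS = ("spontaneous", "on_phasic", "inhibitory", "rebound")

STUDY_SAMPLING_RATE = 20833.0  # Hz
STUDY_STIM_FREQ = 265.0  # Hz
ON_PHASIC_DURATION = 0.075  # s
REBOUND_DELAY = 0.025  # s
REBOUND_DURATION = 0.075  # s
SPONTANEOUS_DURATION = 3.0  # s


@dataclass
class VoltageTrace:
    """Sampled membrane potential, mV, with t0 relative to stimulus onset."""

    samples: np.ndarray
    sampling_rate: float = STUDY_SAMPLING_RATE
    t0: float = -SPONTANEOUS_DURATION

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("voltage samples must be finite")

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class SpikeTrainTrial:
    """Stimulus-aligned spike times for one trial (onset at 0 by convention)."""

    spike_times: np.ndarray
    stim_offset: float = 1.0
    stim_onset: float = 0.0
    stim_freq: float = STUDY_STIM_FREQ
    neuron_id: str = ""
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.stim_offset <= self.stim_onset:
            raise ValueError("stim_offset must exceed stim_onset")


@dataclass(frozen=True)
class PeriodWindows:
    """Half-open analysis windows [start, stop) per activity period, s."""

    spontaneous: tuple[float, float]
    on_phasic: tuple[float, float]
    inhibitory: tuple[float, float]
    rebound: tuple[float, float]

    def __getitem__(self, period: str) -> tuple[float, float]:
        return getattr(self, period)

    def items(self):
        for p in PERIODS:
            yield p, getattr(self, p)


@dataclass
class RateProfile:
    """Time-resolved trial-averaged firing rate with bootstrap band, Hz."""

    times: np.ndarray
    rate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def integral(self) -> float:
        """Expected spikes per trial over the profile span."""
        return float(np.trapezoid(self.rate, self.times))


def make_windows(onset: float, offset: float) -> PeriodWindows:
    """The four activity windows for a stimulus spanning [onset, offset]."""
    if offset <= onset + ON_PHASIC_DURATION:
        raise ValueError(
            "stimulus too short: offset must exceed onset + 75 ms "
            "(inhibitory window would be empty)"
        )
    return PeriodWindows(
        spontaneous=(onset - SPONTANEOUS_DURATION, onset),
        on_phasic=(onset, onset + ON_PHASIC_DURATION),
        inhibitory=(onset + ON_PHASIC_DURATION, offset),
        rebound=(offset + REBOUND_DELAY, offset + REBOUND_DELAY + REBOUND_DURATION),
    )


def detect_spikes(
    trace: VoltageTrace,
    threshold_sd: float = 5.0,
    refractory: float = 0.002,
    highpass_hz: float = 100.0,
) -> SpikeTrainTrial:
    """Threshold-crossing spike detection on an intracellular trace.

    The trace is high-pass filtered (3rd-order Butterworth), spikes are upward
    crossings of ``threshold_sd`` standard deviations above the filtered
    baseline, separated by at least ``refractory`` seconds, and localized at
    the local maximum of the raw trace within the refractory span.
    """
    n = trace.samples.size
    if n / trace.sampling_rate < 0.5:
        raise ValueError("trace must be at least 0.5 s long")
    if np.ptp(trace.samples) == 0:
        warnings.warn("flat trace: no spikes detected", stacklevel=2)
        return SpikeTrainTrial(np.empty(0), stim_offset=1.0)
    sos = signal.butter(3, highpass_hz, "highpass", fs=trace.sampling_rate, output="sos")
    filt = signal.sosfiltfilt(sos, trace.samples)
    sd = float(filt.std())
    if sd == 0:
        warnings.warn("flat trace: no spikes detected", stacklevel=2)
        return SpikeTrainTrial(np.empty(0), stim_offset=1.0)
    thr = float(np.median(filt)) + threshold_sd * sd
    above = filt >= thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    ref_n = max(int(round(refractory * trace.sampling_rate)), 1)
    times = []
    last = -np.inf
    for idx in crossings:
        if idx - last < ref_n:
            continue
        stop = min(idx + ref_n, n)
        peak = idx + int(np.argmax(trace.samples[idx:stop]))
        times.append(trace.t0 + peak / trace.sampling_rate)
        last = idx
    times = np.asarray(times)
    times = times[np.insert(np.diff(times) > 0, 0, True)] if times.size else times
    return SpikeTrainTrial(times, stim_offset=1.0)


def _count_in(spikes: np.ndarray, window: tuple[float, float]) -> int:
    lo, hi = window
    return int(np.count_nonzero((spikes >= lo) & (spikes < hi)))


def period_rates(
    trials: list[SpikeTrainTrial], windows: PeriodWindows
) -> dict[str, float]:
    """Trial-averaged firing rate per activity period, Hz."""
    if not trials:
        raise ValueError("period_rates requires at least one trial")
    out = {}
    for period, (lo, hi) in windows.items():
        counts = [_count_in(t.spike_times, (lo, hi)) for t in trials]
        out[period] = float(np.mean(counts)) / (hi - lo)
    return out


def relative_inhibition(rate_spont: float, rate_inhib: float) -> float:
    """1 - rate_inhibitory / rate_spontaneous (strength of suppression)."""
    if rate_spont <= 0:
        raise ZeroDivisionError(
            "relative_inhibition undefined for zero spontaneous rate"
        )
    return 1.0 - rate_inhib / rate_spont


def spike_timing_features(
    trial: SpikeTrainTrial,
) -> tuple[float, float, float, float]:
    """(T0, T1, T2, T3): first-spike latency within the on-phasic window and
    the following three interspike intervals, in seconds (NaN when missing)."""
    onset = trial.stim_onset
    post = trial.spike_times[trial.spike_times >= onset]
    nan4 = (math.nan,) * 4
    if post.size == 0:
        return nan4
    t0 = float(post[0] - onset)
    if t0 >= ON_PHASIC_DURATION:
        return nan4  # latency only defined by an on-phasic spike
    isis = np.diff(post[:4])
    feats = [t0] + [float(v) for v in isis]
    while len(feats) < 4:
        feats.append(math.nan)
    return tuple(feats)


# -- adaptive kernel rate estimation ------------------------------------------


def _gauss_sum(
    eval_t: np.ndarray, centers: np.ndarray, bw, block: int = 4000
) -> np.ndarray:
    """Sum of Gaussian kernels (possibly per-center bandwidths) at eval_t,
    accumulated in blocks to bound memory."""
    bw = np.broadcast_to(np.asarray(bw, dtype=float), centers.shape)
    out = np.zeros_like(eval_t, dtype=float)
    for i in range(0, centers.size, block):
        c = centers[i : i + block]
        b = bw[i : i + block]
        z = (eval_t[:, None] - c[None, :]) / b[None, :]
        out += (np.exp(-0.5 * z**2) / (math.sqrt(2 * math.pi) * b[None, :])).sum(axis=1)
    return out


_BANDWIDTH_SUBSAMPLE = 1200  # pairwise cost is O(n^2); the optimum is stable


def _optimal_fixed_bandwidth(spikes: np.ndarray, span: float) -> float:
    """Global Gaussian bandwidth minimizing the kernel cost function
    C(w) = sum_ij k_{sqrt(2)w}(di-dj) - 2 sum_{i!=j} k_w(di-dj)
    (an unbiased cross-validation estimate of the integrated squared error)."""
    if spikes.size > _BANDWIDTH_SUBSAMPLE:
        idx = np.linspace(0, spikes.size - 1, _BANDWIDTH_SUBSAMPLE).astype(int)
        spikes = np.sort(spikes)[idx]
    n = spikes.size
    diff = spikes[:, None] - spikes[None, :]
    d2 = diff**2
    grid = np.geomspace(span / 500.0, span / 2.0, 25)
    best_w, best_c = grid[0], np.inf
    for w in grid:
        k2 = np.exp(-d2 / (4 * w**2)).sum() / (2 * math.sqrt(math.pi) * w)
        kw = np.exp(-d2 / (2 * w**2)) / (math.sqrt(2 * math.pi) * w)
        cost = k2 - 2 * (kw.sum() - np.trace(kw))
        if cost < best_c:
            best_c, best_w = cost, w
    return float(best_w)


def _adaptive_bandwidths(spikes: np.ndarray, w_global: float) -> np.ndarray:
    """Abramson local bandwidths: w_i = w * sqrt(G / pilot(t_i)), where pilot
    is the fixed-bandwidth density and G its geometric mean at the spikes.
    The pilot is evaluated on a grid and interpolated (it is w-smooth)."""
    lo, hi = float(spikes.min()), float(spikes.max())
    grid = np.linspace(lo, hi, min(800, max(200, spikes.size)))
    pilot_grid = _gauss_sum(grid, spikes, w_global)
    pilot = np.maximum(np.interp(spikes, grid, pilot_grid), 1e-12)
    g = math.exp(float(np.mean(np.log(pilot))))
    return w_global * np.sqrt(g / pilot)


def rate_profile(
    trials: list[SpikeTrainTrial],
    resolution: float = 0.001,
    span: tuple[float, float] | None = None,
    n_boot: int = 100,
    adaptive: bool = True,
    min_spikes_adaptive: int = 20,
    rng: np.random.Generator | None = None,
) -> RateProfile:
    """Trial-averaged firing-rate profile by (adaptive) kernel estimation.

    Spike times pooled across trials are smoothed with Gaussian kernels; the
    global bandwidth minimizes a cross-validation cost, then local bandwidths
    adapt inversely to the square root of the pilot density.  With fewer than
    ``min_spikes_adaptive`` pooled spikes a fixed Scott's-rule bandwidth is
    used instead.  Edge mass is conserved by reflecting spikes at the span
    boundaries, so the profile integral estimates the mean spike count per
    trial.  The confidence band is a percentile bootstrap over trials.
    """
    if span is None:
        lo = min((t.spike_times[0] for t in trials if t.spike_times.size), default=0.0)
        hi = max((t.spike_times[-1] for t in trials if t.spike_times.size), default=1.0)
        span = (float(lo), float(hi))
    times = np.arange(span[0], span[1] + resolution / 2, resolution)
    n_trials = max(len(trials), 1)
    pooled = np.concatenate([t.spike_times for t in trials]) if trials else np.empty(0)
    pooled = pooled[(pooled >= span[0]) & (pooled <= span[1])]
    if pooled.size == 0:
        z = np.zeros_like(times)
        return RateProfile(times, z, z, z)

    width = span[1] - span[0]
    if adaptive and pooled.size >= min_spikes_adaptive:
        w = _optimal_fixed_bandwidth(pooled, width)
        bws = _adaptive_bandwidths(pooled, w)
    else:
        w = 1.06 * float(pooled.std()) * pooled.size ** (-1 / 5) or resolution
        bws = np.full(pooled.size, max(w, resolution))
    bw_of = dict(zip(pooled.tolist(), bws.tolist()))
    bw_med = float(np.median(bws))

    def estimate(spike_sets: list[np.ndarray]) -> np.ndarray:
        s = np.concatenate(spike_sets) if spike_sets else np.empty(0)
        s = s[(s >= span[0]) & (s <= span[1])]
        if s.size == 0:
            return np.zeros_like(times)
        b = np.array([bw_of.get(v, bw_med) for v in s.tolist()])
        # reflect only spikes close to a boundary; farther kernels carry no
        # mass outside the span
        cut = 6.0 * float(bws.max())
        near_lo = s <= span[0] + cut
        near_hi = s >= span[1] - cut
        centers = np.concatenate(
            [s, 2 * span[0] - s[near_lo], 2 * span[1] - s[near_hi]]
        )
        b3 = np.concatenate([b, b[near_lo], b[near_hi]])
        return _gauss_sum(times, centers, b3) / len(spike_sets)

    rate = estimate([t.spike_times for t in trials])
    if n_boot > 0 and len(trials) > 1:
        rng = rng or np.random.default_rng(0)
        boots = np.empty((n_boot, times.size))
        for i in range(n_boot):
            pick = rng.integers(0, len(trials), len(trials))
            boots[i] = estimate([trials[j].spike_times for j in pick])
        lo_b, hi_b = np.percentile(boots, [2.5, 97.5], axis=0)
    else:
        lo_b = hi_b = rate
    return RateProfile(times, rate, lo_b, hi_b)


# -- per-neuron aggregation and group comparison -------------------------------

TIMING_FEATURES = ("T0", "T1", "T2", "T3")


def features_per_neuron(
    trials_by_neuron: dict[str, list[SpikeTrainTrial]],
    windows: PeriodWindows | None = None,
) -> pd.DataFrame:
    """One row of trial-averaged features per neuron.

    Columns: neuron_id, group, rate_<period> (Hz), relative_inhibition,
    T0..T3 (s, trial-averaged over trials where defined).
    """
    rows = []
    for neuron_id, trials in trials_by_neuron.items():
        if not trials:
            continue
        win = windows or make_windows(trials[0].stim_onset, trials[0].stim_offset)
        rates = period_rates(trials, win)
        timing = np.array([spike_timing_features(t) for t in trials], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            timing_mean = np.nanmean(timing, axis=0)
        rec = dict(neuron_id=neuron_id, group=trials[0].group)
        rec.update({f"rate_{p}": rates[p] for p in PERIODS})
        rec["relative_inhibition"] = (
            relative_inhibition(rates["spontaneous"], rates["inhibitory"])
            if rates["spontaneous"] > 0
            else math.nan
        )
        rec.update(dict(zip(TIMING_FEATURES, timing_mean)))
        rows.append(rec)
    return pd.DataFrame(rows)


def compare_groups_ephys(rows: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Group comparison of per-neuron response features.

    Per feature: group means, percent change of the mean from NE to F, and a
    two-sided Mann-Whitney p.  Relative Inhibition additionally gets a Welch
    unequal-variance t test, and the inhibitory-vs-spontaneous rate relation
    gets per-group OLS slopes (reported as extra rows with feature names
    ``ols_slope_<group>``).
    """
    for g in ("NE", "F"):
        if not (rows.group == g).any():
            raise ValueError(f"compare_groups_ephys: group {g!r} is empty")
    features = [f"rate_{p}" for p in PERIODS] + ["relative_inhibition"] + list(
        TIMING_FEATURES
    )
    out = []
    for feat in features:
        ne = rows.loc[rows.group == "NE", feat].dropna().to_numpy()
        f = rows.loc[rows.group == "F", feat].dropna().to_numpy()
        if ne.size == 0 or f.size == 0:
            continue
        mean_ne, mean_f = float(ne.mean()), float(f.mean())
        rec = dict(
            feature=feat,
            ne_mean=mean_ne,
            ne_sd=float(ne.std(ddof=1)) if ne.size > 1 else math.nan,
            f_mean=mean_f,
            f_sd=float(f.std(ddof=1)) if f.size > 1 else math.nan,
            change_pct=(
                100.0 * (mean_f - mean_ne) / mean_ne if mean_ne != 0 else math.nan
            ),
            p_mannwhitney=mann_whitney(ne, f).p_two_sided,
        )
        if feat == "relative_inhibition" and ne.size > 1 and f.size > 1:
            _, p_w = welch_t(ne, f)
            rec["p_welch"] = p_w
        rec["significant"] = rec["p_mannwhitney"] < alpha
        out.append(rec)
    for g in ("NE", "F"):
        sub = rows[rows.group == g]
        x = sub["rate_spontaneous"].to_numpy()
        y = sub["rate_inhibitory"].to_numpy()
        if np.unique(x).size >= 2:
            slope, intercept = ols_fit(x, y)
            out.append(
                dict(
                    feature=f"ols_slope_{g}",
                    ne_mean=math.nan, ne_sd=math.nan,
                    f_mean=math.nan, f_sd=math.nan,
                    change_pct=math.nan, p_mannwhitney=math.nan,
                    slope=slope, intercept=intercept, significant=False,
                )
            )
    return pd.DataFrame(out)
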