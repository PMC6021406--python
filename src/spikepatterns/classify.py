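"""Regularity quantification and firing-pattern classification.

Every spontaneously active unit is assigned one label from the taxonomy
IS / IFB / ISB / IMB (irregular simple, fast-, slow-, mixed-burst) and
RS / RFB / RSB / RMB (their regular counterparts):

1. fewer than ``min_spikes_for_classification`` spikes -> INSUFFICIENT;
2. bursts are detected; a unit with >= 25% of spikes grouped is bursting,
   otherwise simple;
3. bursting subtype: mixed when intra-burst frequency decays from above to
   below the 70 Hz limit (or by a factor >= 4) within most long bursts,
   else fast when the mean intra-burst instantaneous frequency is >= 70 Hz,
   else slow;
4. regularity: simple units use the CV of all ISIs, bursting units the CV
   of burst onset-to-onset intervals; CV < 0.5 is regular.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bursts import BurstSet, auto_burst_threshold, burst_statistics, detect_bursts
from .types import (
    INSUFFICIENT,
    ClassifierConfig,
    Epoch,
    InsufficientDataError,
    SpikeTrain,
)

__all__ = [
    "ClassificationResult",
    "compute_cv",
    "mean_frequency",
    "classify_pattern",
    "autocorrelogram",
    "autocorrelogram_frame",
]


@dataclass(frozen=True)
class ClassificationResult:
    """A pattern label together with the metrics that justify it.

    NaN marks quantities that are undefined for the label (e.g. intra-burst
    frequency of a simple pattern).  ``insufficient_regularity`` flags
    bursting trains with too few bursts for an onset-interval CV, which
    default to the irregular prefix because regularity could not be
    demonstrated.
    """

    unit_id: str
    label: str
    n_spikes: int
    mean_frequency: float            # Hz over the analysed window
    cv_classification: float         # all-ISI CV (simple) or onset-interval CV
    cv_intraburst: float             # CV of pooled within-burst ISIs
    burst_spike_fraction: float
    intra_burst_freq: float          # Hz
    inter_burst_freq: float          # Hz
    burst_threshold: float           # s; NaN when no grouping was possible
    insufficient_regularity: bool = False


def compute_cv(intervals) -> float:
    """Coefficient of variation: sample standard deviation / mean.

    ``intervals`` must contain at least two strictly positive values.
    """
    arr = np.asarray(intervals, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("CV needs at least 2 intervals")
    if np.any(arr <= 0):
        raise ValueError("intervals must all be positive")
    return float(np.std(arr, ddof=1) / np.mean(arr))


def mean_frequency(train: SpikeTrain, window: Epoch) -> float:
    """Spike count inside ``window`` divided by the window length (Hz)."""
    if window.start < train.t_start - 1e-9 or window.end > train.t_stop + 1e-9:
        raise ValueError(
            f"window [{window.start}, {window.end}] outside the observation "
            f"window [{train.t_start}, {train.t_stop}]"
        )
    i0 = np.searchsorted(train.spike_times, window.start, side="left")
    i1 = np.searchsorted(train.spike_times, window.end, side="right")
    return float(i1 - i0) / window.duration


def _resolve_burst_threshold(train: SpikeTrain, cfg: ClassifierConfig) -> float | None:
    if cfg.max_intra_burst_isi == "auto":
        try:
            return auto_burst_threshold(train)
        except InsufficientDataError:
            return None
    return float(cfg.max_intra_burst_isi)


def _is_mixed(bs: BurstSet, cfg: ClassifierConfig) -> bool:
    """Mixed-burst criterion, per burst with >= 6 spikes: the mean
    instantaneous frequency of the first third of its ISIs is at or above
    the fast/slow limit while the last third is below it, or the
    first/last-third ratio is at least ``mixed_ratio_threshold``.  The train
    is mixed when a strict majority of such bursts qualifies."""
    qualifying = [b for b in bs.bursts if b.n_spikes >= 6]
    if not qualifying:
        return False
    hits = 0
    for b in qualifying:
        isis = b.intra_isis
        third = max(1, isis.size // 3)
        f_first = float(np.mean(1.0 / isis[:third]))
        f_last = float(np.mean(1.0 / isis[-third:]))
        decays = f_first >= cfg.fast_slow_limit and f_last < cfg.fast_slow_limit
        if decays or f_first / f_last >= cfg.mixed_ratio_threshold:
            hits += 1
    return hits > len(qualifying) / 2


def classify_pattern(
    train: SpikeTrain, cfg: ClassifierConfig | None = None
) -> ClassificationResult:
    """Assign a firing-pattern label to a train (see module docstring).

    The train should already be restricted to the analysis window; the mean
    frequency is computed over ``[t_start, t_stop]``.  The result is fully
    deterministic given the train and config.
    """
    cfg = cfg or ClassifierConfig()
    n = len(train)
    freq = n / train.duration
    if n < cfg.min_spikes_for_classification:
        return ClassificationResult(
            unit_id=train.unit_id,
            label=INSUFFICIENT,
            n_spikes=n,
            mean_frequency=freq,
            cv_classification=math.nan,
            cv_intraburst=math.nan,
            burst_spike_fraction=math.nan,
            intra_burst_freq=math.nan,
            inter_burst_freq=math.nan,
            burst_threshold=math.nan,
        )

    threshold = _resolve_burst_threshold(train, cfg)
    if threshold is None:
        bs = detect_bursts(train, max_intra_burst_isi=np.finfo(float).tiny,
                           min_spikes_per_burst=cfg.min_spikes_per_burst)
    else:
        bs = detect_bursts(train, threshold, cfg.min_spikes_per_burst)
    fraction = bs.burst_spike_fraction
    bursting = fraction >= cfg.burst_fraction_threshold

    cv_intra = math.nan
    intra_freq = math.nan
    inter_freq = math.nan
    flag = False
    if not bursting:
        cv = compute_cv(train.isi())
        label = ("RS" if cv < cfg.cv_threshold else "IS")
    else:
        stats = burst_statistics(bs)
        intra_freq = stats.intra_burst_freq
        inter_freq = stats.inter_burst_freq
        if _is_mixed(bs, cfg):
            subtype = "MB"
        elif stats.intra_burst_freq >= cfg.fast_slow_limit:
            subtype = "FB"          # 70 Hz exactly counts as fast
        else:
            subtype = "SB"
        onset_intervals = bs.onset_intervals
        if onset_intervals.size >= cfg.min_burst_onset_intervals:
            cv = compute_cv(onset_intervals)
            prefix = "R" if cv < cfg.cv_threshold else "I"
        else:
            # regularity cannot be demonstrated from so few bursts
            cv = (
                compute_cv(onset_intervals)
                if onset_intervals.size >= 2
                else math.nan
            )
            prefix = "I"
            flag = True
        label = prefix + subtype
        pooled = bs.pooled_intra_isis()
        if pooled.size >= 2:
            cv_intra = compute_cv(pooled)

    return ClassificationResult(
        unit_id=train.unit_id,
        label=label,
        n_spikes=n,
        mean_frequency=freq,
        cv_classification=cv,
        cv_intraburst=cv_intra,
        burst_spike_fraction=fraction,
        intra_burst_freq=intra_freq,
        inter_burst_freq=inter_freq,
        burst_threshold=math.nan if threshold is None else float(threshold),
        insufficient_regularity=flag,
    )


def autocorrelogram(
    train: SpikeTrain, bin_width: float = 0.01, max_lag: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of ordered spike-pair lags in ``(0, max_lag]``.

    Returns ``(counts, bin_edges)`` with edges ``0, bin_width, 2*bin_width,
    ...`` covering ``max_lag``.  Zero-lag self-pairs are excluded.  A train
    with fewer than two spikes yields an all-zero histogram.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    if not max_lag > bin_width:
        raise ValueError("max_lag must exceed bin_width")
    n_bins = int(math.ceil(max_lag / bin_width - 1e-12))
    edges = np.arange(n_bins + 1) * bin_width
    times = train.spike_times
    counts = np.zeros(n_bins, dtype=np.int64)
    if times.size < 2:
        return counts, edges
    lags = []
    for i, t in enumerate(times[:-1]):
        j = np.searchsorted(times, t + max_lag, side="right")
        lags.append(times[i + 1 : j] - t)
    all_lags = np.concatenate(lags) if lags else np.empty(0)
    all_lags = all_lags[all_lags <= max_lag]
    counts, _ = np.histogram(all_lags, bins=edges)
    return counts, edges


def autocorrelogram_frame(train: SpikeTrain, bin_width: float = 0.01,
                          max_lag: float = 10.0):
    """Autocorrelogram as a two-column DataFrame (lag_s = bin centre, count)."""
    import pandas as pd

    counts, edges = autocorrelogram(train, bin_width, max_lag)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"lag_s": centres, "count": counts})
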