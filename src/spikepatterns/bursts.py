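"""Burst detection and burst descriptive statistics.

A burst is a maximal run of consecutive spikes whose successive inter-spike
intervals are all below (or equal to) a grouping threshold, with at least
``min_spikes_per_burst`` spikes.  The threshold can be given explicitly or
derived from the train itself (:func:`auto_burst_threshold`) as the valley
between the intra-burst and inter-burst modes of the log10-ISI histogram.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import InsufficientDataError, SpikeTrain


@dataclass(frozen=True)
class Burst:
    """One detected burst: a contiguous group of spikes."""

    first_spike_index: int
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "spike_times", np.asarray(self.spike_times, dtype=float)
        )
        if self.n_spikes < 2:
            raise ValueError("a burst needs at least 2 spikes")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def onset(self) -> float:
        return float(self.spike_times[0])

    @property
    def offset(self) -> float:
        return float(self.spike_times[-1])

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def intra_isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class BurstSet:
    """Partition of a train's spikes into bursts and lone spikes."""

    bursts: tuple[Burst, ...]
    lone_spike_indices: np.ndarray
    n_total_spikes: int
    max_intra_burst_isi: float

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def n_burst_spikes(self) -> int:
        return sum(b.n_spikes for b in self.bursts)

    @property
    def burst_spike_fraction(self) -> float:
        """Fraction of all spikes that sit inside a burst (0 for empty train)."""
        if self.n_total_spikes == 0:
            return 0.0
        return self.n_burst_spikes / self.n_total_spikes

    @property
    def onsets(self) -> np.ndarray:
        return np.array([b.onset for b in self.bursts])

    @property
    def onset_intervals(self) -> np.ndarray:
        """Onset-to-onset intervals between consecutive bursts (the IBI used
        for the regularity CV of bursting patterns)."""
        return np.diff(self.onsets)

    @property
    def inter_burst_gaps(self) -> np.ndarray:
        """Offset-to-onset gaps (last spike of burst i to first of burst i+1),
        the interval whose reciprocal is the inter-burst instantaneous
        frequency."""
        if self.n_bursts < 2:
            return np.empty(0)
        offsets = np.array([b.offset for b in self.bursts[:-1]])
        return self.onsets[1:] - offsets

    def pooled_intra_isis(self) -> np.ndarray:
        """All within-burst ISIs, pooled across bursts."""
        if not self.bursts:
            return np.empty(0)
        return np.concatenate([b.intra_isis for b in self.bursts])

    def to_dict(self) -> dict:
        """JSON-serialisable summary for downstream inspection."""
        return {
            "max_intra_burst_isi_s": self.max_intra_burst_isi,
            "n_total_spikes": self.n_total_spikes,
            "burst_spike_fraction": self.burst_spike_fraction,
            "bursts": [
                {
                    "onset_s": b.onset,
                    "offset_s": b.offset,
                    "n_spikes": b.n_spikes,
                }
                for b in self.bursts
            ],
        }


def detect_bursts(
    train: SpikeTrain,
    max_intra_burst_isi: float,
    min_spikes_per_burst: int = 2,
) -> BurstSet:
    """Group spikes into maximal runs with all ISIs <= ``max_intra_burst_isi``.

    An ISI exactly equal to the threshold joins the burst.  Runs shorter than
    ``min_spikes_per_burst`` spikes are left as lone spikes.  An empty train
    yields an empty :class:`BurstSet`.
    """
    if not max_intra_burst_isi > 0:
        raise ValueError("max_intra_burst_isi must be positive")
    times = train.spike_times
    n = times.size
    if n == 0:
        return BurstSet((), np.empty(0, dtype=int), 0, float(max_intra_burst_isi))
    grouped = np.diff(times) <= max_intra_burst_isi
    padded = np.concatenate(([False], grouped, [False]))
    step = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(step == 1)        # index of first ISI in run
    run_ends = np.flatnonzero(step == -1)         # one past last ISI in run
    bursts = []
    in_burst = np.zeros(n, dtype=bool)
    for s, e in zip(run_starts, run_ends):
        n_spk = e - s + 1                         # spikes s .. e inclusive
        if n_spk >= min_spikes_per_burst:
            bursts.append(Burst(int(s), times[s : e + 1]))
            in_burst[s : e + 1] = True
    return BurstSet(
        tuple(bursts),
        np.flatnonzero(~in_burst),
        int(n),
        float(max_intra_burst_isi),
    )


def auto_burst_threshold(train: SpikeTrain, bins: int = 25) -> float | None:
    """Grouping threshold from the valley of the log10-ISI histogram.

    Builds a ``bins``-bin histogram of log10(ISI), smooths it with a 3-bin
    moving average, and scans every interior bin as a candidate split: a bin
    qualifies when a smoothed peak of at least 2 counts exists on each side
    and its own smoothed count is at most half the smaller of those side
    maxima.  The deepest qualifying valley wins (ties: the median tied bin)
    and its bin centre, back-transformed to seconds, is returned.

    Returns ``None`` when the histogram is effectively unimodal, meaning no
    bursts are detectable.  Requires at least 10 ISIs.
    """
    isis = train.isi()
    if isis.size < 10:
        raise InsufficientDataError(
            f"auto threshold needs >= 10 ISIs, got {isis.size}"
        )
    log_isi = np.log10(isis)
    # a near-periodic train (all ISIs within ~12% of each other) has no
    # burst/gap structure; without this guard float rounding of identical
    # intervals can masquerade as bimodality
    if np.ptp(log_isi) < 0.05:
        return None
    counts, edges = np.histogram(log_isi, bins=bins)
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    candidates = []
    for v in range(1, bins - 1):
        left = smooth[:v].max()
        right = smooth[v + 1 :].max()
        if left >= 2 and right >= 2 and smooth[v] <= 0.5 * min(left, right):
            candidates.append(v)
    if not candidates:
        return None
    depths = smooth[candidates]
    tied = [v for v, d in zip(candidates, depths) if d == depths.min()]
    v = tied[len(tied) // 2]
    centre = 0.5 * (edges[v] + edges[v + 1])
    return float(10.0 ** centre)


@dataclass(frozen=True)
class BurstStatistics:
    """Descriptive burst statistics; NaN marks undefined quantities."""

    n_bursts: int
    mean_duration: float             # s
    mean_spikes_per_burst: float
    intra_burst_freq: float          # Hz, mean of 1/ISI over all intra ISIs
    inter_burst_freq: float          # Hz, mean of 1/gap over inter-burst gaps


def burst_statistics(bs: BurstSet) -> BurstStatistics:
    """Summarise a :class:`BurstSet`.

    Instantaneous frequencies are means of reciprocals of intervals (not the
    reciprocal of the mean interval): intra-burst over all within-burst ISIs
    pooled across bursts, inter-burst over the offset-to-onset gaps.  With no
    bursts every statistic is NaN (an explicit undefined marker, never zero);
    the inter-burst frequency additionally needs at least two bursts.
    """
    if bs.n_bursts == 0:
        return BurstStatistics(0, math.nan, math.nan, math.nan, math.nan)
    intra = bs.pooled_intra_isis()
    intra_freq = float(np.mean(1.0 / intra)) if intra.size else math.nan
    gaps = bs.inter_burst_gaps
    inter_freq = float(np.mean(1.0 / gaps)) if gaps.size else math.nan
    return BurstStatistics(
        n_bursts=bs.n_bursts,
        mean_duration=float(np.mean([b.duration for b in bs.bursts])),
        mean_spikes_per_burst=float(np.mean([b.n_spikes for b in bs.bursts])),
        intra_burst_freq=intra_freq,
        inter_burst_freq=inter_freq,
    )
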