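"""Domain types shared by every stage of the pipeline.

The central container is :class:`SpikeTrain`: one unit's sorted spike times
with an explicit observation window.  Classification thresholds live in
:class:`ClassifierConfig`; pharmacological epochs in :class:`Epoch`; 2x2
inhibition counts in :class:`ContingencyTable2x2`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("spikepatterns")

#: Firing-pattern labels.  Prefix R/I encodes regularity (classification CV
#: below / at-or-above the CV threshold), suffix encodes the burst subtype:
#: S = simple (single spikes), FB/SB/MB = fast / slow / mixed bursts.
IRREGULAR_LABELS = frozenset({"IS", "IFB", "ISB", "IMB"})
REGULAR_LABELS = frozenset({"RS", "RFB", "RSB", "RMB"})
PATTERN_LABELS = IRREGULAR_LABELS | REGULAR_LABELS
BURSTING_LABELS = frozenset({lab for lab in PATTERN_LABELS if lab.endswith("B")})
SIMPLE_LABELS = PATTERN_LABELS - BURSTING_LABELS
#: Sentinel label for trains with too few spikes to classify.
INSUFFICIENT = "INSUFFICIENT"


def is_regular(label: str) -> bool:
    """True for the regular firing-pattern labels (RS, RFB, RSB, RMB)."""
    return label in REGULAR_LABELS


def is_irregular(label: str) -> bool:
    return label in IRREGULAR_LABELS


def is_bursting(label: str) -> bool:
    return label in BURSTING_LABELS


class InsufficientDataError(ValueError):
    """Raised when an estimator has too little data to be meaningful."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of a single unit within an observation window.

    Parameters
    ----------
    unit_id:
        Text label of the unit (e.g. a sorting channel id).
    spike_times:
        Spike times in seconds, strictly ascending, all inside
        ``[t_start, t_stop]``.
    t_start, t_stop:
        Observation window in seconds, ``t_stop > t_start``.  ``t_stop``
        defaults to the last spike time when omitted.
    """

    unit_id: str
    spike_times: np.ndarray
    t_start: float = 0.0
    t_stop: float | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        if times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        object.__setattr__(self, "spike_times", times)
        t_stop = self.t_stop
        if t_stop is None:
            if times.size == 0:
                raise ValueError("t_stop is required for an empty train")
            t_stop = float(times[-1])
            object.__setattr__(self, "t_stop", t_stop)
        if not t_stop > self.t_start:
            raise ValueError(
                f"t_stop ({t_stop}) must exceed t_start ({self.t_start})"
            )
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError(
                    f"spike times of unit {self.unit_id!r} are not strictly "
                    "ascending; use SpikeTrain.from_times to sort/deduplicate"
                )
            if times[0] < self.t_start or times[-1] > t_stop:
                raise ValueError(
                    f"spike times of unit {self.unit_id!r} fall outside "
                    f"[{self.t_start}, {t_stop}]"
                )

    @classmethod
    def from_times(
        cls,
        unit_id: str,
        times: Iterable[float],
        t_start: float = 0.0,
        t_stop: float | None = None,
    ) -> "SpikeTrain":
        """Build a train from possibly unsorted times, collapsing duplicates.

        Duplicate times (spike-extraction artifacts) are removed with a
        logged warning rather than an error.
        """
        arr = np.sort(np.asarray(list(times), dtype=float))
        uniq = np.unique(arr)
        if uniq.size < arr.size:
            logger.warning(
                "unit %s: collapsed %d duplicate spike time(s)",
                unit_id,
                arr.size - uniq.size,
            )
        return cls(unit_id, uniq, t_start=t_start, t_stop=t_stop)

    def __len__(self) -> int:
        return int(self.spike_times.size)

    @property
    def n_spikes(self) -> int:
        return len(self)

    @property
    def duration(self) -> float:
        return float(self.t_stop - self.t_start)

    def isi(self) -> np.ndarray:
        """Inter-spike intervals (seconds), length ``n_spikes - 1``."""
        return np.diff(self.spike_times)

    def slice(self, start: float, stop: float) -> "SpikeTrain":
        """Restrict the train to the window ``[start, stop]``."""
        if not stop > start:
            raise ValueError("slice window must have stop > start")
        i0, i1 = np.searchsorted(self.spike_times, [start, stop], side="left")
        # include a spike exactly at `stop`
        if i1 < len(self) and self.spike_times[i1] == stop:
            i1 += 1
        return SpikeTrain(
            self.unit_id, self.spike_times[i0:i1], t_start=start, t_stop=stop
        )

    def rescale(self, factor: float) -> "SpikeTrain":
        """Multiply all times by ``factor`` (> 0); CVs are invariant to this."""
        if factor <= 0:
            raise ValueError("rescale factor must be positive")
        return SpikeTrain(
            self.unit_id,
            self.spike_times * factor,
            t_start=self.t_start * factor,
            t_stop=self.t_stop * factor,
        )


@dataclass(frozen=True)
class Epoch:
    """A named recording period, optionally with the drugs present in it."""

    name: str
    start: float
    end: float
    drugs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"epoch {self.name!r}: end must exceed start")
        object.__setattr__(self, "drugs", tuple(self.drugs))

    @property
    def duration(self) -> float:
        return float(self.end - self.start)


def check_non_overlapping(epochs: Sequence[Epoch]) -> None:
    """Raise if any two epochs on the same recording overlap."""
    ordered = sorted(epochs, key=lambda e: e.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(f"epochs {a.name!r} and {b.name!r} overlap")


@dataclass(frozen=True)
class ClassifierConfig:
    """All thresholds of the classification pipeline.

    Defaults encode the published criteria: regularity is CV < 0.5, a neuron
    is bursting when at least 25% of its spikes are grouped, 70 Hz separates
    fast from slow bursts, and a unit counts as inhibited when its firing
    rate drops to <= 20% of control measured over a 5-minute window.
    """

    cv_threshold: float = 0.5
    burst_fraction_threshold: float = 0.25
    fast_slow_limit: float = 70.0          # Hz
    inhibition_ratio: float = 0.20
    analysis_window: float = 300.0         # seconds
    min_spikes_for_classification: int = 10
    min_burst_onset_intervals: int = 3
    max_intra_burst_isi: float | str = "auto"   # seconds, or "auto"
    min_spikes_per_burst: int = 2
    mixed_ratio_threshold: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.cv_threshold <= 1:
            raise ValueError("cv_threshold must be in (0, 1]")
        if not 0 < self.burst_fraction_threshold <= 1:
            raise ValueError("burst_fraction_threshold must be in (0, 1]")
        for name in (
            "fast_slow_limit",
            "inhibition_ratio",
            "analysis_window",
            "mixed_ratio_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "min_spikes_for_classification",
            "min_burst_onset_intervals",
            "min_spikes_per_burst",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.max_intra_burst_isi != "auto":
            if not float(self.max_intra_burst_isi) > 0:
                raise ValueError("max_intra_burst_isi must be positive or 'auto'")

    def with_(self, **kwargs) -> "ClassifierConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts; rows = neuron groups, columns = inhibited / not inhibited."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if int(getattr(self, name)) < 0:
                raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return int(self.a + self.b + self.c + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)
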