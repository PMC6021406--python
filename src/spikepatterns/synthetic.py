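"""Synthetic spike trains and voltage-clamp traces for every pipeline stage.

Single-spike patterns are gamma-renewal processes: the two parameters map
directly onto a (rate, CV) description, with shape k = 1/CV^2.  Burst
patterns place bursts at renewal onsets (gap CV 0.3 for regular classes,
1.2 for irregular, so the realised onset-interval CV lands clearly on the
right side of the 0.5 criterion) and fill each burst with spikes at the
intra-burst frequency jittered by 10%; mixed bursts decay geometrically
from a high starting to a low ending frequency.  Default parameter regimes
follow the published class descriptions (e.g. fast bursts of 2-4 spikes
near 124 Hz, slow bursts of ~28 spikes near 15 Hz, regular simple units
near 5.6 Hz with CV 0.28).

All generators are deterministic under (spec, seed); a master seed spawns
per-train substreams so suites are reproducible item by item.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .membrane import (
    JUNCTION_POTENTIAL_MV,
    E_NA_MV,
    VoltageClampTrace,
    boltzmann,
    correct_junction_potential,
)
from .types import SpikeTrain

__all__ = [
    "SyntheticSpec",
    "PRESETS",
    "SUITE_CLASSES",
    "generate_renewal_train",
    "generate_burst_train",
    "generate_labelled_suite",
    "DrugModulation",
    "apply_drug_modulation",
    "IhStepParams",
    "InapRampParams",
    "generate_vc_traces",
    "synthetic_activation_points",
]

#: classes emitted by :func:`generate_labelled_suite`
SUITE_CLASSES = ("IS", "RS", "IFB", "ISB", "IMB", "RFB", "RSB")

#: multiplicative jitter applied to every intra-burst ISI
_INTRA_JITTER = 0.10
#: bursts must be separated from gaps by at least this factor of the
#: longest nominal intra-burst ISI
_SEPARABILITY = 5.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Target statistics for one generated train.

    For simple patterns set ``rate``/``cv_target``; for burst patterns set
    ``burst_rate`` (onsets per second), ``spikes_per_burst`` (inclusive
    integer range), ``intra_burst_freq`` (Hz; a (start, end) pair yields a
    mixed burst decaying geometrically) and optionally ``gap_cv`` (defaults
    by the label's regularity prefix).
    """

    label: str
    duration: float = 300.0
    seed: int | np.random.SeedSequence | np.random.Generator | None = None
    rate: float | None = None
    cv_target: float | None = None
    burst_rate: float | None = None
    spikes_per_burst: tuple[int, int] | None = None
    intra_burst_freq: float | tuple[float, float] | None = None
    gap_cv: float | None = None


PRESETS: dict[str, SyntheticSpec] = {
    "IS": SyntheticSpec(label="IS", rate=1.16, cv_target=1.0),
    "RS": SyntheticSpec(label="RS", rate=5.62, cv_target=0.28),
    "IFB": SyntheticSpec(
        label="IFB", burst_rate=0.33, spikes_per_burst=(2, 4),
        intra_burst_freq=124.0,
    ),
    "ISB": SyntheticSpec(
        label="ISB", burst_rate=0.14, spikes_per_burst=(20, 36),
        intra_burst_freq=15.0,
    ),
    "IMB": SyntheticSpec(
        label="IMB", burst_rate=0.19, spikes_per_burst=(30, 50),
        intra_burst_freq=(120.0, 10.0),
    ),
    "RFB": SyntheticSpec(
        label="RFB", burst_rate=3.9, spikes_per_burst=(2, 3),
        intra_burst_freq=138.0,
    ),
    "RSB": SyntheticSpec(
        label="RSB", burst_rate=0.177, spikes_per_burst=(24, 42),
        intra_burst_freq=13.0,
    ),
}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _gamma_intervals(
    rng: np.random.Generator, mean: float, cv: float, size: int
) -> np.ndarray:
    shape = 1.0 / cv**2
    return rng.gamma(shape, scale=mean / shape, size=size)


def generate_renewal_train(
    rate: float,
    cv_target: float,
    duration: float,
    seed=None,
    unit_id: str = "unit0",
) -> SpikeTrain:
    """Gamma-renewal spike train with the given rate (Hz) and target ISI CV.

    Shape k = 1/cv_target^2, mean interval 1/rate; the empirical CV
    converges to ``cv_target`` as the train grows.  ``cv_target`` must lie
    in (0, 1.5].
    """
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    if not 0 < cv_target <= 1.5:
        raise ValueError("cv_target must be in (0, 1.5]")
    rng = _rng(seed)
    mean_isi = 1.0 / rate
    times: list[np.ndarray] = []
    t = 0.0
    # draw in chunks until the window is covered
    chunk = max(64, int(rate * duration * 1.2) + 16)
    while t <= duration:
        isis = _gamma_intervals(rng, mean_isi, cv_target, chunk)
        cumulative = t + np.cumsum(isis)
        times.append(cumulative)
        t = float(cumulative[-1])
    spikes = np.concatenate(times)
    spikes = spikes[spikes <= duration]
    return SpikeTrain(unit_id, spikes, t_start=0.0, t_stop=duration)


def _nominal_isis(spec: SyntheticSpec, n_spikes: int) -> np.ndarray:
    freq = spec.intra_burst_freq
    n_isi = n_spikes - 1
    if isinstance(freq, tuple):
        f_start, f_end = freq
        if n_isi == 1:
            freqs = np.array([math.sqrt(f_start * f_end)])
        else:
            freqs = f_start * (f_end / f_start) ** (
                np.arange(n_isi) / (n_isi - 1)
            )
        return 1.0 / freqs
    return np.full(n_isi, 1.0 / float(freq))


def _max_nominal_isi(spec: SyntheticSpec) -> float:
    freq = spec.intra_burst_freq
    f_min = min(freq) if isinstance(freq, tuple) else float(freq)
    return (1.0 / f_min) * (1.0 + _INTRA_JITTER)


def _estimated_burst_duration(spec: SyntheticSpec) -> float:
    lo, hi = spec.spikes_per_burst
    mean_n = 0.5 * (lo + hi)
    return float(np.sum(_nominal_isis(spec, max(2, int(round(mean_n))))))


def generate_burst_train(spec: SyntheticSpec) -> SpikeTrain:
    """Generate a bursting train from a :class:`SyntheticSpec`.

    Burst onsets follow a renewal process built as burst offset + a gamma
    gap (CV 0.3 for R-prefixed labels, 1.2 for I-prefixed); any gap shorter
    than 5x the longest intra-burst ISI is redrawn (up to 100 attempts) so
    bursts stay separable from gaps.
    """
    if spec.burst_rate is None or spec.spikes_per_burst is None:
        raise ValueError("burst spec needs burst_rate and spikes_per_burst")
    if spec.intra_burst_freq is None:
        raise ValueError("burst spec needs intra_burst_freq")
    if not spec.burst_rate > 0 or not spec.duration > 0:
        raise ValueError("burst_rate and duration must be positive")
    rng = _rng(spec.seed)
    gap_cv = spec.gap_cv
    if gap_cv is None:
        gap_cv = 0.3 if spec.label.startswith("R") else 1.2
    mean_onset_interval = 1.0 / spec.burst_rate
    mean_gap = mean_onset_interval - _estimated_burst_duration(spec)
    if mean_gap <= 0:
        raise ValueError(
            "burst_rate too high: bursts would overlap on average"
        )
    floor = _SEPARABILITY * _max_nominal_isi(spec)
    lo, hi = spec.spikes_per_burst

    def draw_gap() -> float:
        for _ in range(100):
            g = float(_gamma_intervals(rng, mean_gap, gap_cv, 1)[0])
            if g >= floor:
                return g
        raise RuntimeError(
            "could not draw a non-overlapping burst onset in 100 attempts"
        )

    spikes: list[float] = []
    t = draw_gap()
    while t <= spec.duration:
        n = int(rng.integers(lo, hi + 1))
        isis = _nominal_isis(spec, n) * rng.uniform(
            1.0 - _INTRA_JITTER, 1.0 + _INTRA_JITTER, size=n - 1
        )
        burst_times = t + np.concatenate(([0.0], np.cumsum(isis)))
        spikes.extend(burst_times[burst_times <= spec.duration])
        t = float(burst_times[-1]) + draw_gap()
    return SpikeTrain(
        f"{spec.label}_synth", np.asarray(spikes),
        t_start=0.0, t_stop=spec.duration,
    )


def generate_train(spec: SyntheticSpec) -> SpikeTrain:
    """Dispatch on the spec: renewal train for simple labels, bursts else."""
    if spec.rate is not None:
        train = generate_renewal_train(
            spec.rate, spec.cv_target, spec.duration, spec.seed,
            unit_id=f"{spec.label}_synth",
        )
        return train
    return generate_burst_train(spec)


def _jittered_spec(
    label: str, rng: np.random.Generator, duration: float, seed
) -> SyntheticSpec:
    """Preset with per-train parameter variation near the class regime."""
    base = PRESETS[label]
    u = rng.uniform
    if label == "IS":
        return replace(base, rate=base.rate * u(0.7, 1.3),
                       cv_target=u(0.8, 1.3), duration=duration, seed=seed)
    if label == "RS":
        return replace(base, rate=base.rate * u(0.8, 1.2),
                       cv_target=u(0.22, 0.36), duration=duration, seed=seed)
    scale = u(0.85, 1.15)
    intra = base.intra_burst_freq
    factor = u(0.9, 1.1)
    intra = (
        (intra[0] * factor, intra[1] * factor)
        if isinstance(intra, tuple)
        else intra * factor
    )
    return replace(base, burst_rate=base.burst_rate * scale,
                   intra_burst_freq=intra, duration=duration, seed=seed)


def generate_labelled_suite(
    seed: int, n_per_class: int = 100, duration: float = 300.0,
    classes: Sequence[str] = SUITE_CLASSES,
) -> list[tuple[SpikeTrain, str]]:
    """Deterministic labelled suite: ``n_per_class`` trains per class.

    Per-train parameters are drawn near the class regimes; one master seed
    spawns independent substreams per train, so the suite is reproducible
    item by item.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(classes) * n_per_class)
    out: list[tuple[SpikeTrain, str]] = []
    idx = 0
    for label in classes:
        for i in range(n_per_class):
            rng = np.random.default_rng(children[idx])
            idx += 1
            spec = _jittered_spec(label, rng, duration, seed=rng)
            train = generate_train(spec)
            train = SpikeTrain(
                f"{label}_{i:03d}", train.spike_times,
                t_start=train.t_start, t_stop=train.t_stop,
            )
            out.append((train, label))
    return out


@dataclass(frozen=True)
class DrugModulation:
    """Emulated drug effect applied to a train from ``onset`` onwards.

    ``inhibit`` thins post-onset spikes to ``keep_fraction`` (default 12%,
    safely at or below the 20% inhibition criterion); ``regularise``
    replaces the post-onset segment with a low-CV renewal train at the
    pre-onset rate; ``none`` is the identity.
    """

    kind: str                     # "inhibit" | "regularise" | "none"
    onset: float
    seed: int = 0
    keep_fraction: float = 0.12
    target_cv: float = 0.25


def apply_drug_modulation(train: SpikeTrain, effect: DrugModulation) -> SpikeTrain:
    if effect.kind == "none":
        return train
    if not train.t_start < effect.onset < train.t_stop:
        raise ValueError("modulation onset must lie inside the observation window")
    rng = np.random.default_rng(effect.seed)
    times = train.spike_times
    pre = times[times < effect.onset]
    post = times[times >= effect.onset]
    if effect.kind == "inhibit":
        keep = rng.random(post.size) < effect.keep_fraction
        new_post = post[keep]
    elif effect.kind == "regularise":
        pre_rate = pre.size / (effect.onset - train.t_start)
        if pre_rate <= 0:
            raise ValueError("cannot regularise a train silent before onset")
        segment = generate_renewal_train(
            pre_rate, effect.target_cv, train.t_stop - effect.onset, rng
        )
        new_post = effect.onset + segment.spike_times
    else:
        raise ValueError(f"unknown modulation kind {effect.kind!r}")
    return SpikeTrain(
        train.unit_id, np.concatenate([pre, new_post]),
        t_start=train.t_start, t_stop=train.t_stop,
    )


# ---------------------------------------------------------------------------
# voltage-clamp trace generators

@dataclass(frozen=True)
class IhStepParams:
    """Hyperpolarising step protocol: 1.5 s steps from -62 mV holding."""

    step_voltage: float = -132.0   # mV
    holding_voltage: float = -62.0  # mV
    duration: float = 1.5          # s
    sample_rate: float = 10_000.0  # Hz
    leak_pa: float = -50.0
    amplitude_pa: float = -100.0   # asymptotic slow current, inward negative
    tau: float = 0.3               # s, activation time constant
    noise_pa: float = 0.0


@dataclass(frozen=True)
class InapRampParams:
    """Slow depolarising ramp protocol: hold -113 mV, ramp to -31 mV.

    The default 26 mV/s rate matches the published protocol (lowered to
    8 mV/s in some cells); the persistent inward current injected into the
    control trace is Boltzmann-shaped in the junction-corrected voltage.
    """

    v_start: float = -113.0        # mV (command)
    v_end: float = -31.0           # mV (command)
    rate_mv_per_s: float = 26.0
    sample_rate: float = 2_000.0   # Hz
    leak_g_ns: float = 2.0
    leak_e_mv: float = -60.0
    gmax_ns: float = 2.0
    v50_mv: float = -51.7          # mV, junction-corrected
    slope_mv: float = 6.0
    noise_pa: float = 0.0


def generate_vc_traces(kind: str, params=None, seed: int | None = 0):
    """Synthetic voltage-clamp sweeps.

    ``kind='ih_step'`` returns one :class:`VoltageClampTrace` whose current
    relaxes exponentially (leak + amplitude*(1 - exp(-t/tau)) + noise).
    ``kind='inap_ramp'`` returns a ``(control, blocked)`` pair whose
    pointwise difference is a Boltzmann-shaped persistent inward current.
    """
    rng = _rng(seed)
    if kind == "ih_step":
        p = params or IhStepParams()
        n = int(round(p.duration * p.sample_rate))
        t = np.arange(n) / p.sample_rate
        current = p.leak_pa + p.amplitude_pa * (1.0 - np.exp(-t / p.tau))
        if p.noise_pa > 0:
            current = current + rng.normal(0.0, p.noise_pa, size=n)
        return VoltageClampTrace(
            time=t, current=current,
            command_voltage=p.step_voltage,
            holding_voltage=p.holding_voltage,
        )
    if kind == "inap_ramp":
        p = params or InapRampParams()
        span = p.v_end - p.v_start
        duration = span / p.rate_mv_per_s
        n = int(round(duration * p.sample_rate))
        t = np.arange(n) / p.sample_rate
        command = p.v_start + p.rate_mv_per_s * t
        v_corr = correct_junction_potential(command)
        leak = p.leak_g_ns * (command - p.leak_e_mv)
        inap = (
            p.gmax_ns
            * boltzmann(v_corr, p.v50_mv, p.slope_mv)
            * (v_corr - E_NA_MV)
        )
        noise = (
            rng.normal(0.0, p.noise_pa, size=(2, n))
            if p.noise_pa > 0
            else np.zeros((2, n))
        )
        control = VoltageClampTrace(
            time=t, current=leak + inap + noise[0],
            command_voltage=command, holding_voltage=p.v_start,
        )
        blocked = VoltageClampTrace(
            time=t, current=leak + noise[1],
            command_voltage=command, holding_voltage=p.v_start,
        )
        return control, blocked
    raise ValueError(f"unknown trace kind {kind!r}")


def synthetic_activation_points(
    v50: float = -51.7,
    slope: float = 6.0,
    voltages=None,
    noise_sd: float = 0.02,
    seed: int | None = 0,
    top: float = 1.0,
    bottom: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised-conductance activation points with additive Gaussian noise.

    Default voltages span the junction-corrected ramp range (-124.5 to
    -42.5 mV, i.e. the -113 to -31 mV command ramp) at 0.25 mV spacing — a
    conservative decimation of a digitized 26 mV/s ramp, which yields one
    test potential every few microvolts.
    """
    if voltages is None:
        voltages = np.arange(-124.5, -42.5 + 1e-9, 0.25)
    v = np.asarray(voltages, dtype=float)
    rng = _rng(seed)
    g = boltzmann(v, v50, slope, top, bottom)
    if noise_sd > 0:
        g = g + rng.normal(0.0, noise_sd, size=v.shape)
    return v, g
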