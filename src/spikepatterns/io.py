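"""Readers and writers for spike tables, epochs, configs and reports.

The interchange format for spike times is a plain CSV with the header
``unit_id,spike_time_s`` (seconds as decimal floats), optionally preceded by
comment lines ``# t_start=<s>`` / ``# t_stop=<s>`` fixing the observation
window; without them the window is 0 to the last spike.  A JSON alternative
mirrors it: ``{"t_start": ..., "t_stop": ..., "units": {id: [times]}}``.
"""
from __future__ import annotations

import dataclasses
import json
import math
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import ClassifierConfig, Epoch, SpikeTrain, logger


# ---------------------------------------------------------------------------
# formatting / small statistics helpers

def sem(values) -> float:
    """Standard error of the mean: sample standard deviation / sqrt(n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return math.nan
    return float(np.std(arr, ddof=1) / math.sqrt(arr.size))


def format_percent(
    numerator: float, denominator: float, decimals: int = 1,
    mode: str = "half_up",
) -> str:
    """Render ``numerator/denominator`` as a percent string.

    ``mode='half_up'`` rounds half away from zero (the style of the
    distribution table); ``mode='floor'`` truncates (the style of the
    published inhibition tables, where 8/45 prints as 17.7%).
    """
    if denominator == 0:
        raise ZeroDivisionError("cannot format a percentage of zero total")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    rounding = ROUND_HALF_UP if mode == "half_up" else ROUND_DOWN
    return f"{pct.quantize(quantum, rounding=rounding)}%"


# ---------------------------------------------------------------------------
# spike tables

_SPIKE_COLUMNS = ("unit_id", "spike_time_s")


def read_spike_table(path) -> list[SpikeTrain]:
    """Read spike trains from a CSV (or ``.json``) spike table.

    Returns one :class:`SpikeTrain` per unit, times sorted, exact duplicates
    collapsed with a logged warning.  The observation window comes from
    ``# t_start=`` / ``# t_stop=`` header comments when present, otherwise
    from 0 / the latest spike in the file.  An empty file yields an empty
    list with a warning; a malformed row raises naming its line.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_spike_json(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line.lstrip("#").strip()
            if "=" in text:
                key, _, value = text.partition("=")
                try:
                    header[key.strip()] = float(value)
                except ValueError:
                    pass
    try:
        df = pd.read_csv(path, comment="#", dtype={"unit_id": str})
    except pd.errors.EmptyDataError:
        logger.warning("spike table %s is empty", path)
        return []
    missing = [c for c in _SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df.empty:
        logger.warning("spike table %s has no spikes", path)
        return []
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = times.isna() | df["unit_id"].isna()
    if bad.any():
        # +2: header line plus 1-based numbering (comments shift this for
        # files with a comment preamble, so report the data row too)
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: malformed value in data row {row + 1} "
            f"(line ~{row + 2} of the file)"
        )
    df = df.assign(spike_time_s=times)
    t_start = header.get("t_start", 0.0)
    t_stop = header.get("t_stop", float(times.max()))
    trains = []
    for unit_id, group in df.groupby("unit_id", sort=True):
        trains.append(
            SpikeTrain.from_times(
                str(unit_id), group["spike_time_s"].to_numpy(),
                t_start=t_start, t_stop=t_stop,
            )
        )
    return trains


def _read_spike_json(path: Path) -> list[SpikeTrain]:
    payload = json.loads(Path(path).read_text())
    units = payload.get("units", {})
    if not units:
        logger.warning("spike table %s has no units", path)
        return []
    t_start = float(payload.get("t_start", 0.0))
    t_stop = payload.get("t_stop")
    if t_stop is None:
        t_stop = max(max(v) for v in units.values() if v)
    return [
        SpikeTrain.from_times(str(uid), times, t_start=t_start,
                              t_stop=float(t_stop))
        for uid, times in sorted(units.items())
    ]


def write_spike_table(trains: Sequence[SpikeTrain], path) -> None:
    """Write trains to the CSV spike-table format (lossless round-trip)."""
    path = Path(path)
    t_start = min(t.t_start for t in trains)
    t_stop = max(t.t_stop for t in trains)
    with open(path, "w") as fh:
        fh.write(f"# t_start={float(t_start)!r}\n# t_stop={float(t_stop)!r}\n")
        fh.write("unit_id,spike_time_s\n")
        for train in trains:
            for t in train.spike_times:
                fh.write(f"{train.unit_id},{float(t)!r}\n")


# ---------------------------------------------------------------------------
# epochs and config

def read_epochs(path) -> list[Epoch]:
    """Read ``[{name, start_s, end_s, drugs[]}]`` from JSON."""
    payload = json.loads(Path(path).read_text())
    return [
        Epoch(
            name=item["name"],
            start=float(item["start_s"]),
            end=float(item["end_s"]),
            drugs=tuple(item.get("drugs", ())),
        )
        for item in payload
    ]


def write_epochs(epochs: Sequence[Epoch], path) -> None:
    payload = [
        {"name": e.name, "start_s": e.start, "end_s": e.end,
         "drugs": list(e.drugs)}
        for e in epochs
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_config(path) -> ClassifierConfig:
    payload = json.loads(Path(path).read_text())
    return ClassifierConfig(**payload)


def write_config(cfg: ClassifierConfig, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(cfg), indent=2))


# ---------------------------------------------------------------------------
# classification reports

_METRIC_FIELDS = (
    "mean_frequency",
    "cv_classification",
    "cv_intraburst",
    "burst_spike_fraction",
    "intra_burst_freq",
    "inter_burst_freq",
)

#: canonical row order of the distribution table
LABEL_ORDER = ("IS", "IFB", "ISB", "IMB", "RS", "RFB", "RSB", "RMB",
               "INSUFFICIENT")


def label_count_summary(
    counts: Mapping[str, int], total: int | None = None
) -> pd.DataFrame:
    """Per-class counts and percent-of-total strings (half-up, 1 decimal)."""
    total = sum(counts.values()) if total is None else total
    rows = [
        {
            "label": lab,
            "n": int(counts[lab]),
            "percent": format_percent(counts[lab], total, 1, "half_up"),
        }
        for lab in LABEL_ORDER
        if lab in counts
    ]
    return pd.DataFrame(rows)


def results_frame(results: Iterable) -> pd.DataFrame:
    """Per-unit classification table (report CSV columns)."""
    rows = []
    for r in results:
        rows.append(
            {
                "unit_id": r.unit_id,
                "label": r.label,
                "mean_frequency_hz": r.mean_frequency,
                "cv_classification": r.cv_classification,
                "cv_intraburst": r.cv_intraburst,
                "burst_spike_fraction": r.burst_spike_fraction,
                "intra_burst_freq_hz": r.intra_burst_freq,
                "inter_burst_freq_hz": r.inter_burst_freq,
            }
        )
    return pd.DataFrame(rows)


def summarize_results(results: Sequence) -> dict:
    """Per-class counts, percent of total, and mean +/- SEM of each metric."""
    results = list(results)
    if not results:
        raise ValueError("no classification results to summarise")
    counts: dict[str, int] = {}
    for r in results:
        counts[r.label] = counts.get(r.label, 0) + 1
    total = len(results)
    summary: dict = {"total": total, "classes": {}}
    for lab in LABEL_ORDER:
        if lab not in counts:
            continue
        members = [r for r in results if r.label == lab]
        metrics = {}
        for fieldname in _METRIC_FIELDS:
            vals = np.array(
                [getattr(r, fieldname) for r in members], dtype=float
            )
            vals = vals[~np.isnan(vals)]
            metrics[fieldname] = {
                "mean": float(np.mean(vals)) if vals.size else None,
                "sem": (s if not math.isnan(s := sem(vals)) else None)
                if vals.size >= 2
                else None,
                "n": int(vals.size),
            }
        summary["classes"][lab] = {
            "n": counts[lab],
            "percent": format_percent(counts[lab], total, 1, "half_up"),
            "metrics": metrics,
        }
    return summary


def write_classification_report(results: Sequence, path) -> dict:
    """Write the per-unit CSV plus a JSON class summary next to it.

    Returns the summary dict (also written to ``<path>.summary.json``).
    Raises on empty results.
    """
    results = list(results)
    if not results:
        raise ValueError("refusing to write an empty classification report")
    path = Path(path)
    results_frame(results).to_csv(path, index=False)
    summary = summarize_results(results)
    summary_path = path.with_suffix(path.suffix + ".summary.json")
    summary_path.write_text(json.dumps(summary, indent=2))
    return summary


def human_summary(summary: dict) -> str:
    """Short human-readable rendering of a classification summary."""
    lines = [f"total units: {summary['total']}"]
    for lab, info in summary["classes"].items():
        freq = info["metrics"]["mean_frequency"]["mean"]
        freq_txt = f", mean rate {freq:.2f} Hz" if freq is not None else ""
        lines.append(f"  {lab:>12s}: n={info['n']:4d} ({info['percent']}){freq_txt}")
    return "\n".join(lines)
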