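"""Pre/post drug-epoch comparison: inhibition verdicts, regularisation,
and contingency analysis across neuron groups.

A unit counts as *inhibited* when its firing frequency in the last analysis
window of the drug epoch drops to at most ``inhibition_ratio`` (default 20%)
of the control frequency; *regularised* when an irregular pre-drug pattern
re-classifies as regular under the drug.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import classify_pattern, mean_frequency
from .io import format_percent
from .types import (
    ClassifierConfig,
    ContingencyTable2x2,
    Epoch,
    SpikeTrain,
    is_irregular,
    is_regular,
    logger,
)

__all__ = [
    "DrugEffect",
    "assess_drug_effect",
    "tabulate_inhibition",
    "InhibitionTabulation",
    "chi_square_2x2",
    "Chi2Result",
]


@dataclass(frozen=True)
class DrugEffect:
    """Outcome of one unit's pre/post epoch comparison.

    ``assessable`` is False when the unit was silent in the control window;
    such units have ``ratio`` NaN and ``inhibited`` None (a silent control
    never counts as inhibited by zero division).
    """

    unit_id: str
    pre_frequency: float
    post_frequency: float
    ratio: float
    inhibited: bool | None
    pre_label: str
    post_label: str
    regularised: bool
    assessable: bool = True


def assess_drug_effect(
    train: SpikeTrain,
    pre: Epoch,
    post: Epoch,
    cfg: ClassifierConfig | None = None,
) -> DrugEffect:
    """Compare the control epoch with a drug epoch for one unit.

    Frequencies and classifications use the last ``cfg.analysis_window``
    seconds of each epoch (the published protocol measures the 5 minutes
    before drug onset and the last 5 minutes of perfusion).  Both epochs
    must be at least one analysis window long, non-overlapping, with ``pre``
    before ``post``.
    """
    cfg = cfg or ClassifierConfig()
    for epoch in (pre, post):
        if epoch.duration < cfg.analysis_window:
            raise ValueError(
                f"epoch {epoch.name!r} is shorter than the analysis window"
            )
    if pre.end > post.start:
        raise ValueError("pre epoch must end before the post epoch starts")

    windows = [
        Epoch(e.name, e.end - cfg.analysis_window, e.end, e.drugs)
        for e in (pre, post)
    ]
    pre_f, post_f = (mean_frequency(train, w) for w in windows)
    pre_res, post_res = (
        classify_pattern(train.slice(w.start, w.end), cfg) for w in windows
    )

    if pre_f == 0:
        return DrugEffect(
            unit_id=train.unit_id,
            pre_frequency=0.0,
            post_frequency=post_f,
            ratio=math.nan,
            inhibited=None,
            pre_label=pre_res.label,
            post_label=post_res.label,
            regularised=False,
            assessable=False,
        )
    ratio = post_f / pre_f
    return DrugEffect(
        unit_id=train.unit_id,
        pre_frequency=pre_f,
        post_frequency=post_f,
        ratio=ratio,
        inhibited=ratio <= cfg.inhibition_ratio,
        pre_label=pre_res.label,
        post_label=post_res.label,
        regularised=is_irregular(pre_res.label) and is_regular(post_res.label),
    )


def _default_grouping(effect: DrugEffect) -> str | None:
    if is_irregular(effect.pre_label):
        return "irregular"
    if is_regular(effect.pre_label):
        return "regular"
    return None


@dataclass(frozen=True)
class InhibitionTabulation:
    """Counts of inhibited vs. not-inhibited units, by group and by class."""

    table: ContingencyTable2x2
    by_group: pd.DataFrame      # group, inhibited, total, percent
    by_class: pd.DataFrame      # pre_label, inhibited, total, percent


def tabulate_inhibition(
    effects: Iterable[DrugEffect],
    grouping: Callable[[DrugEffect], str | None] | None = None,
) -> InhibitionTabulation:
    """Tabulate inhibition verdicts into a 2x2 contingency table.

    ``grouping`` maps each effect to one of exactly two group names (or None
    to exclude it); the default partitions by pre-drug regularity.  Units
    that were not assessable (silent control) are excluded with a logged
    warning.  Percentages are truncated to one decimal, the style of the
    published inhibition tables.
    """
    grouping = grouping or _default_grouping
    effects = list(effects)
    if not effects:
        raise ValueError("no drug effects to tabulate")
    usable = [e for e in effects if e.assessable]
    if len(usable) < len(effects):
        logger.warning(
            "excluded %d non-assessable unit(s) from the contingency table",
            len(effects) - len(usable),
        )
    groups: dict[str, list[DrugEffect]] = {}
    for e in usable:
        g = grouping(e)
        if g is not None:
            groups.setdefault(g, []).append(e)
    if len(groups) != 2:
        raise ValueError(
            f"contingency analysis needs exactly 2 groups, got {sorted(groups)}"
        )
    # deterministic row order; 'irregular' first when present
    names = sorted(groups, key=lambda g: (g != "irregular", g))

    def _rows(partition: dict[str, list[DrugEffect]]) -> pd.DataFrame:
        rows = []
        for key in partition:
            members = partition[key]
            inhibited = sum(bool(e.inhibited) for e in members)
            rows.append(
                {
                    "group": key,
                    "inhibited": inhibited,
                    "total": len(members),
                    "percent": format_percent(inhibited, len(members), 1, "floor"),
                }
            )
        return pd.DataFrame(rows)

    by_group = _rows({name: groups[name] for name in names})
    by_class_map: dict[str, list[DrugEffect]] = {}
    for e in usable:
        by_class_map.setdefault(e.pre_label, []).append(e)
    by_class = _rows(dict(sorted(by_class_map.items()))).rename(
        columns={"group": "pre_label"}
    )
    a, b = (
        int(by_group.loc[0, "inhibited"]),
        int(by_group.loc[0, "total"] - by_group.loc[0, "inhibited"]),
    )
    c, d = (
        int(by_group.loc[1, "inhibited"]),
        int(by_group.loc[1, "total"] - by_group.loc[1, "inhibited"]),
    )
    return InhibitionTabulation(ContingencyTable2x2(a, b, c, d), by_group, by_class)


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    dof: int = 1


def chi_square_2x2(table: ContingencyTable2x2) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 df.

    Raises when a row or column margin is zero (the test is undefined).
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero row or column margin")
    res = stats.chi2_contingency(arr, correction=False)
    return Chi2Result(float(res.statistic), float(res.pvalue), int(res.dof))


def drug_effect_frame(effects: Sequence[DrugEffect]) -> pd.DataFrame:
    """Drug-effect report table (one row per unit)."""
    return pd.DataFrame(
        [
            {
                "unit_id": e.unit_id,
                "pre_hz": e.pre_frequency,
                "post_hz": e.post_frequency,
                "ratio": e.ratio,
                "inhibited": e.inhibited,
                "pre_label": e.pre_label,
                "post_label": e.post_label,
                "regularised": e.regularised,
            }
            for e in effects
        ]
    )
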