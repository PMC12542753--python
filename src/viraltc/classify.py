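"""Temporal classification of viral genes by the half-maximum rule.

A gene's class is determined by the first timepoint t_half at which its
percent-of-max expression reaches the half-maximum threshold (default 50%):

* early        — t_half ≤ 20 min
* middle       — 20 < t_half ≤ 60 min, never dropping below threshold later
* middle_down  — 20 < t_half ≤ 60 min, later falling below the threshold
* late         — t_half > 60 min

Unexpressed genes are reported as unclassified rather than classified from
noise.  Deadlines and threshold are configurable; the defaults mirror a
6-sample time course at 5/20/60/120/180/300 min post-infection.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import TemporalProfile

__all__ = ["TemporalClass", "ClassifierConfig", "classify", "classify_detail", "classify_all"]


class TemporalClass(enum.Enum):
    EARLY = "early"
    MIDDLE = "middle"
    MIDDLE_DOWN = "middle_down"
    LATE = "late"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifierConfig:
    half_max_threshold: float = 50.0  # percent of maximum
    early_deadline: float = 20.0  # minutes post-infection
    middle_deadline: float = 60.0

    def __post_init__(self) -> None:
        if not (0 < self.half_max_threshold < 100):
            raise ValueError("half_max_threshold must lie in (0, 100)")
        if not (self.early_deadline < self.middle_deadline):
            raise ValueError("early_deadline must precede middle_deadline")


def classify(profile: TemporalProfile, cfg: ClassifierConfig = ClassifierConfig()) -> TemporalClass:
    """Apply the half-maximum rule to one percent-of-max profile."""
    return classify_detail(profile, cfg)[0]


def classify_detail(
    profile: TemporalProfile, cfg: ClassifierConfig = ClassifierConfig()
) -> tuple[TemporalClass, float | None, bool]:
    """Classify and also report (label, t_half, drops_after_early).

    ``drops_after_early`` flags early genes whose expression later falls
    below the threshold; they remain early (the "-down" variant exists only
    for the middle group) but the drop is advisory output.
    """
    if not profile.expressed:
        return TemporalClass.UNCLASSIFIED, None, False
    pct = np.asarray(profile.pct_of_max, dtype=float)
    tps = np.asarray(profile.timepoints, dtype=float)
    reached = np.flatnonzero(pct >= cfg.half_max_threshold)  # ties count as reached
    if reached.size == 0:  # unreachable: max pct is 100
        return TemporalClass.UNCLASSIFIED, None, False
    i_half = int(reached[0])
    t_half = float(tps[i_half])
    drops_later = bool(np.any(pct[i_half + 1 :] < cfg.half_max_threshold))
    if t_half <= cfg.early_deadline:
        return TemporalClass.EARLY, t_half, drops_later
    if t_half <= cfg.middle_deadline:
        label = TemporalClass.MIDDLE_DOWN if drops_later else TemporalClass.MIDDLE
        return label, t_half, False
    return TemporalClass.LATE, t_half, False


def classify_all(
    profiles: list[TemporalProfile], cfg: ClassifierConfig = ClassifierConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every feature; return (per-feature table, group summary).

    The per-feature table has one row per feature (feature_id, label,
    t_half, drops_after_early, plus the pct-of-max vector as columns).  The
    summary counts each label over *all* features, unclassified included,
    with percentages of the total.
    """
    ids = [p.feature_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate feature_id in profiles: {dupes}")
    rows = []
    for p in profiles:
        label, t_half, drops = classify_detail(p, cfg)
        row = {
            "feature_id": p.feature_id,
            "label": label.value,
            "t_half": t_half,
            "drops_after_early": drops,
        }
        for i, t in enumerate(p.timepoints):
            row[f"pct_t{t}"] = p.pct_of_max[i]
        rows.append(row)
    table = pd.DataFrame(rows)
    total = len(table)
    counts = table["label"].value_counts()
    summary = pd.DataFrame(
        {
            "label": [c.value for c in TemporalClass],
            "count": [int(counts.get(c.value, 0)) for c in TemporalClass],
        }
    )
    summary["percent"] = (100.0 * summary["count"] / total).round(1) if total else 0.0
    return table, summary
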