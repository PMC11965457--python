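"""Extreme-deviation summaries.

Converts deviation Z-scores into the study's individual-level maps: per
region, the percentage of each group with extreme positive (Z > 2) or
negative (Z < -2) deviations, with frequency tiers at 5/7.5/10%; per
subject, the burden count of extreme deviations aggregated across
modalities.  Thresholding is strict: Z exactly at +/-threshold is not
extreme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normative import DeviationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ExtremeMask",
    "threshold_extremes",
    "roi_extreme_frequency",
    "subject_extreme_burden",
    "group_mean_extreme_rate",
    "top_regions",
    "frequency_tier",
]

TIER_LEVELS = (5.0, 7.5, 10.0)


@dataclass
class ExtremeMask:
    """Boolean subjects-by-ROIs masks of extreme deviations per sign."""

    positive: pd.DataFrame = field(repr=False)
    negative: pd.DataFrame = field(repr=False)
    threshold: float = 2.0
    modality: str = ""

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if (self.positive.to_numpy() & self.negative.to_numpy()).any():
            raise ValueError("a cell cannot be both an extreme positive and negative")


def threshold_extremes(dev: DeviationMatrix, threshold: float = 2.0) -> ExtremeMask:
    """Flag extreme deviations with strict inequalities Z > t and Z < -t."""
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    Z = dev.zscores
    return ExtremeMask(
        positive=Z.gt(threshold), negative=Z.lt(-threshold),
        threshold=threshold, modality=dev.modality,
    )


def frequency_tier(pct: float) -> float:
    """Highest minimum-frequency tier (5/7.5/10%) a percentage reaches;
    NaN below the lowest tier."""
    tier = np.nan
    for level in TIER_LEVELS:
        if pct >= level:
            tier = level
    return tier


def roi_extreme_frequency(mask: ExtremeMask, groups: pd.Series) -> pd.DataFrame:
    """Per (group, region, sign): count and percentage of group members
    flagged, with the frequency tier reached.

    Percentages are 100 * flagged / group size, reported to full
    precision (display rounding to 1 decimal is left to writers).
    """
    groups = groups.loc[mask.positive.index]
    rows = []
    for group, idx in groups.groupby(groups).groups.items():
        n = len(idx)
        if n == 0:
            raise ValueError(f"group {group!r} is empty")
        for sign, m in (("positive", mask.positive), ("negative", mask.negative)):
            counts = m.loc[idx].sum(axis=0)
            for roi, count in counts.items():
                pct = 100.0 * count / n
                rows.append((group, roi, sign, int(count), n, pct, frequency_tier(pct)))
    return pd.DataFrame(
        rows, columns=["group", "roi", "sign", "count", "group_n", "pct", "tier"]
    )


def subject_extreme_burden(masks: list[ExtremeMask]) -> pd.DataFrame:
    """Per-subject counts of extreme deviations aggregated across the
    given modality masks, plus a has_any flag."""
    if not masks:
        raise ValueError("need at least one mask")
    index = masks[0].positive.index
    for m in masks[1:]:
        if not m.positive.index.equals(index):
            raise ValueError("masks do not share the same subject index")
    n_pos = sum(m.positive.sum(axis=1) for m in masks)
    n_neg = sum(m.negative.sum(axis=1) for m in masks)
    out = pd.DataFrame({"n_pos": n_pos.astype(int), "n_neg": n_neg.astype(int)})
    out["has_any"] = (out["n_pos"] + out["n_neg"]) > 0
    out.index.name = "subject_id"
    return out


def group_mean_extreme_rate(
    mask: ExtremeMask, groups: pd.Series, pooled: bool = False
) -> pd.DataFrame:
    """Per (group, sign): mean percentage of regions flagged.

    Default averages each subject's percentage of flagged regions over
    the group; ``pooled=True`` instead pools all flags in the group
    (flagged cells / (subjects x regions)).  The two differ only under
    unequal per-subject region counts, but both conventions exist in the
    literature.
    """
    groups = groups.loc[mask.positive.index]
    n_roi = mask.positive.shape[1]
    rows = []
    for group, idx in groups.groupby(groups).groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {group!r} is empty")
        for sign, m in (("positive", mask.positive), ("negative", mask.negative)):
            sub = m.loc[idx]
            if pooled:
                rate = 100.0 * sub.to_numpy().sum() / (len(idx) * n_roi)
            else:
                rate = float((100.0 * sub.sum(axis=1) / n_roi).mean())
            rows.append((group, mask.modality, sign, rate))
    return pd.DataFrame(rows, columns=["group", "modality", "sign", "mean_pct"])


def top_regions(
    freq: pd.DataFrame, group: str, sign: str = "negative", k: int = 15
) -> pd.DataFrame:
    """Top-k regions by deviation frequency for one group and sign.

    Ties broken by (percentage desc, count desc, region name asc) for a
    deterministic listing.
    """
    sub = freq[(freq["group"] == group) & (freq["sign"] == sign)].copy()
    sub = sub.sort_values(
        by=["pct", "count", "roi"], ascending=[False, False, True], kind="mergesort"
    )
    return sub.head(k).reset_index(drop=True)
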