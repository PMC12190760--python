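"""Phase segmentation of tumor radiance time series.

A mouse's whole-body (or per-region) average radiance trajectory passes
through up to three qualitative phases -- growth, decay and relapse --
detected by stepwise ratio thresholds on consecutive timepoints:

* growth ends at the timepoint immediately prior to a drop below 75% of
  the previous timepoint's radiance;
* decay ends at the timepoint immediately prior to a three-fold increase;
* relapse is all remaining timepoints.

Every trajectory receives exactly one of five class labels: G (growth
only), GD (growth then decay), GDR (growth, decay, relapse), D (decay
only), DR (decay then relapse).  A "growth phase" that would consist of a
single point (the drop threshold fires at the very first step) is treated
as no growth phase at all: the series starts in decay.  Ties on the
three-fold rule break toward relapse (an exact 3-fold jump starts
relapse); the 75% rule is strict.

Because both rules are ratios, segmentation is invariant under uniform
rescaling of the radiance values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "RadianceSeries",
    "PhaseSegmentation",
    "segment_phases",
    "classify_trajectory",
    "cohort_class_counts",
]

#: The five trajectory classes, in canonical order.
CLASS_LABELS: tuple[str, ...] = ("G", "GD", "GDR", "D", "DR")


@dataclass
class RadianceSeries:
    """One mouse's average radiance per pixel versus acquisition day.

    ``days`` must be strictly increasing with at least two entries and
    ``values`` strictly positive (callers clamp instrument zeros to a
    detection floor before constructing a series).  ``scope`` is
    ``"whole-body"`` or an anatomical region label.
    """

    mouse_id: str
    days: np.ndarray
    values: np.ndarray
    scope: str = "whole-body"

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.ndim != 1 or self.days.shape != self.values.shape:
            raise ValueError("days and values must be 1-D and equal length")
        if len(self.days) < 2:
            raise ValueError("a radiance series needs at least two timepoints")
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("acquisition days must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("radiance values must be finite and positive")

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class PhaseSegmentation:
    """Phase boundaries and class label for one series.

    ``D_index`` is the index of the last growth timepoint (absent when the
    series starts in decay or never leaves growth); ``R_index`` is the
    index of the first relapse timepoint (the first point at/above the
    three-fold jump).  ``initial_phase`` records whether the series opened
    in growth or decay, which disambiguates G from D when no boundary
    index is present.
    """

    D_index: int | None
    R_index: int | None
    initial_phase: str
    label: str

    def __post_init__(self) -> None:
        if self.initial_phase not in ("growth", "decay"):
            raise ValueError("initial_phase must be 'growth' or 'decay'")
        if self.D_index is not None and self.R_index is not None:
            if not 0 <= self.D_index < self.R_index:
                raise ValueError("indices must satisfy 0 <= D_index < R_index")
        if self.label != classify_trajectory(self):
            raise ValueError(
                f"label {self.label!r} inconsistent with boundary indices"
            )


def classify_trajectory(seg: PhaseSegmentation) -> str:
    """Pure relabeling of a segmentation into one of the five classes.

    Idempotent: derived only from which boundary indices are present and
    which phase the series opened in.
    """
    if seg.initial_phase == "growth":
        if seg.D_index is None:
            return "G"
        return "GDR" if seg.R_index is not None else "GD"
    return "DR" if seg.R_index is not None else "D"


def segment_phases(
    series: RadianceSeries,
    growth_end_ratio: float = 0.75,
    relapse_ratio: float = 3.0,
    *,
    floor: float | None = None,
) -> PhaseSegmentation:
    """Segment a radiance series by the stepwise ratio thresholds.

    Scans consecutive pairs once, in order: growth ends at index ``i-1``
    when ``values[i] < growth_end_ratio * values[i-1]`` (strict); decay
    then ends at index ``j-1`` when ``values[j] >= relapse_ratio *
    values[j-1]``; remaining points are relapse.  Only the first firing of
    each rule is used.  ``floor`` optionally clamps values from below
    before the ratio tests (useful for region series that touch the
    detection limit).
    """
    if growth_end_ratio <= 0 or relapse_ratio <= 0:
        raise ValueError("thresholds must be positive")
    v = series.values if floor is None else np.maximum(series.values, floor)
    n = len(v)
    drop = np.flatnonzero(v[1:] < growth_end_ratio * v[:-1]) + 1
    if drop.size == 0:
        return PhaseSegmentation(None, None, "growth", "G")
    fire = int(drop[0])
    if fire == 1:
        D_index, initial, d_start = None, "decay", 0
    else:
        D_index, initial, d_start = fire - 1, "growth", fire - 1
    R_index = None
    for j in range(d_start + 1, n):
        if v[j] >= relapse_ratio * v[j - 1]:
            R_index = j
            break
    if initial == "growth":
        label = "GDR" if R_index is not None else "GD"
    else:
        label = "DR" if R_index is not None else "D"
    return PhaseSegmentation(D_index, R_index, initial, label)


def cohort_class_counts(
    labels: Iterable[str],
    strata: Sequence[object] | None = None,
    *,
    stratum_order: Sequence[object] | None = None,
    class_order: Sequence[str] = CLASS_LABELS,
) -> pd.DataFrame:
    """Tabulate class counts and within-stratum percentages for a cohort.

    ``labels`` are trajectory class labels, optionally paired with an
    aligned ``strata`` sequence (e.g. CAR construct or dose group).
    Returns a long-format frame with columns ``stratum``, ``label``,
    ``count``, ``percent``; percentages sum to 100 within each non-empty
    stratum, and strata listed in ``stratum_order`` but absent from the
    data appear as zero rows.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty cohort")
    strata_list = list(strata) if strata is not None else ["all"] * len(labels)
    if len(strata_list) != len(labels):
        raise ValueError("strata must align with labels")
    df = pd.DataFrame({"stratum": strata_list, "label": labels})
    counts = pd.crosstab(df["stratum"], df["label"])
    counts = counts.reindex(columns=list(class_order), fill_value=0)
    if stratum_order is not None:
        counts = counts.reindex(list(stratum_order), fill_value=0)
    totals = counts.sum(axis=1)
    rows = []
    for stratum, row in counts.iterrows():
        tot = totals.loc[stratum]
        for label in class_order:
            c = int(row[label])
            pct = 100.0 * c / tot if tot else 0.0
            rows.append(
                {"stratum": stratum, "label": label, "count": c, "percent": pct}
            )
    return pd.DataFrame(rows)
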