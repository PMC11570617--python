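"""MDS-UPDRS tremor/PIGD ratio classification of PD patients.

The mean tremor score is the sum of 11 tremor-related MDS-UPDRS items
(2.10, 3.15a/b, 3.16a/b, 3.17a-e, 3.18) divided by 11; the mean PIGD score is
the sum of 5 postural/gait items (2.12, 2.13, 3.10, 3.11, 3.12) divided by 5.
Patients with tremor/PIGD ratio >= 1.15 are tremor-dominant (TD), ratio
<= 0.9 postural-instability-and-gait-difficulty-dominant (PIGD); inside the
open indeterminate band (0.9, 1.15) a patient is Mix when both mean scores
exceed the mix floor of 0.8, otherwise Indeterminate.  The Mix rule departs
from the classical TD/PIGD/indeterminate scheme by carving the
high-tremor-and-high-gait-score patients out of the indeterminate band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import math

import pandas as pd

from .errors import ValidationError

TREMOR_ITEMS = (
    "2.10",
    "3.15a",
    "3.15b",
    "3.16a",
    "3.16b",
    "3.17a",
    "3.17b",
    "3.17c",
    "3.17d",
    "3.17e",
    "3.18",
)
PIGD_ITEMS = ("2.12", "2.13", "3.10", "3.11", "3.12")

LABEL_TD = "TD"
LABEL_PIGD = "PIGD"
LABEL_MIX = "Mix"
LABEL_INDETERMINATE = "Indeterminate"
LABEL_UNSCORABLE = "Unscorable"


@dataclass(frozen=True)
class RatioThresholds:
    """Classification thresholds; comparisons are inclusive as written."""

    td_ratio: float = 1.15
    pigd_ratio: float = 0.9
    mix_floor: float = 0.8
    #: if True, the Mix rule is tested before the ratio bands (alternative
    #: precedence: a patient in the TD band with both means > mix_floor
    #: becomes Mix); the default applies the Mix rule only inside the
    #: indeterminate band.
    mix_first: bool = False

    def __post_init__(self):
        if not (0 < self.pigd_ratio < self.td_ratio):
            raise ValidationError("need 0 < pigd_ratio < td_ratio")
        if self.mix_floor < 0:
            raise ValidationError("mix_floor must be non-negative")


def _check_item(item: str, value) -> float:
    v = float(value)
    if not v.is_integer() or not (0 <= v <= 4):
        raise ValidationError(f"item {item!r} must be an integer rating in [0, 4], got {value!r}")
    return v


def score_updrs(record: Mapping[str, object]) -> tuple[float, float]:
    """Mean tremor and mean PIGD score for one patient's item ratings.

    ``record`` maps item names (``"2.10"`` ... ``"3.12"``) to 0-4 integer
    ratings; a missing or out-of-range item raises a validation error naming
    it.
    """
    for item in TREMOR_ITEMS + PIGD_ITEMS:
        if item not in record or pd.isna(record[item]):
            raise ValidationError(f"missing MDS-UPDRS item {item!r}")
    mean_tremor = sum(_check_item(i, record[i]) for i in TREMOR_ITEMS) / len(TREMOR_ITEMS)
    mean_pigd = sum(_check_item(i, record[i]) for i in PIGD_ITEMS) / len(PIGD_ITEMS)
    return mean_tremor, mean_pigd


def classify_patient(
    mean_tremor: float,
    mean_pigd: float,
    thresholds: RatioThresholds = RatioThresholds(),
) -> str:
    """Label one patient from the two mean scores.

    Every non-negative (mean_tremor, mean_pigd) pair receives exactly one of
    TD / PIGD / Mix / Indeterminate / Unscorable.
    """
    if mean_tremor < 0 or mean_pigd < 0:
        raise ValidationError("mean scores must be non-negative")
    if mean_tremor == 0 and mean_pigd == 0:
        return LABEL_UNSCORABLE
    both_high = mean_tremor > thresholds.mix_floor and mean_pigd > thresholds.mix_floor
    if thresholds.mix_first and both_high:
        return LABEL_MIX
    ratio = math.inf if mean_pigd == 0 else mean_tremor / mean_pigd
    if ratio >= thresholds.td_ratio:
        return LABEL_TD
    if ratio <= thresholds.pigd_ratio:
        return LABEL_PIGD
    return LABEL_MIX if both_high else LABEL_INDETERMINATE


def classify_cohort(
    records: pd.DataFrame, thresholds: RatioThresholds = RatioThresholds()
) -> pd.DataFrame:
    """Score and classify a patient table (one column per named item).

    Returns a table with patient_id, mean_tremor, mean_pigd, ratio and label;
    the ratio is ``inf`` when the PIGD mean is zero and ``NaN`` when both
    means are zero.
    """
    if "patient_id" not in records.columns:
        raise ValidationError("patient table missing 'patient_id' column")
    rows = []
    for _, rec in records.iterrows():
        mt, mp = score_updrs(rec)
        if mp > 0:
            ratio = mt / mp
        else:
            ratio = math.inf if mt > 0 else math.nan
        rows.append(
            {
                "patient_id": rec["patient_id"],
                "mean_tremor": mt,
                "mean_pigd": mp,
                "ratio": ratio,
                "label": classify_patient(mt, mp, thresholds),
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "mean_tremor", "mean_pigd", "ratio", "label"]
    )


def updrs_columns() -> Iterable[str]:
    """Header names a patient CSV must carry besides patient_id."""
    return TREMOR_ITEMS + PIGD_ITEMS
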