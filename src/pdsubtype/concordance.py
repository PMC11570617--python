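"""Cross-species direction-of-change concordance for shared features.

For each contrast (e.g. Mix vs control), metabolites detected in both species
are compared by the sign of their log2 fold change.  The concordance
percentage is 100 * n_consistent / (n_consistent + n_inconsistent), rounded
half-up to two decimals.  Features with log2fc exactly 0 are "unchanged" and
drop out of the denominator; an optional stricter mode additionally requires
significance (p <= alpha) in both species for a direction to count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .errors import ValidationError

CHANGE_COLUMNS = ["feature_id", "contrast", "log2fc", "p_value"]

MODE_SIGN_ONLY = "sign_only"
MODE_SIGN_AND_SIG = "sign_and_significance"


@dataclass(frozen=True)
class ConcordanceResult:
    contrast: str
    n_shared: int
    n_consistent: int
    n_inconsistent: int
    pct_consistent: float | None  # None when no feature has a defined direction

    def to_dict(self) -> dict:
        return asdict(self)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (3.145 -> 3.15), matching printed percentages."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _validate_change_table(table: pd.DataFrame, name: str) -> None:
    missing = [c for c in CHANGE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"{name} table missing columns: {missing}")
    dup = table.duplicated(subset=["feature_id", "contrast"])
    if dup.any():
        ids = table.loc[dup, "feature_id"].unique().tolist()[:5]
        raise ValidationError(f"duplicate feature_id within {name} table: {ids}")


def match_shared(rat_table: pd.DataFrame, human_table: pd.DataFrame) -> list[str]:
    """Exact-string intersection of feature identifiers, order-stable.

    Order follows first appearance in the rat table.
    """
    for tab, name in ((rat_table, "rat"), (human_table, "human")):
        _validate_change_table(tab, name)
    human_ids = set(human_table["feature_id"])
    seen: set[str] = set()
    shared = []
    for fid in rat_table["feature_id"]:
        if fid in human_ids and fid not in seen:
            shared.append(fid)
            seen.add(fid)
    return shared


def direction(log2fc: float, p_value: float, mode: str = MODE_SIGN_ONLY, alpha: float = 0.05) -> str:
    """Classify a change as up / down / unchanged under the given mode."""
    if mode == MODE_SIGN_AND_SIG and p_value > alpha:
        return "unchanged"
    if log2fc > 0:
        return "up"
    if log2fc < 0:
        return "down"
    return "unchanged"


def concordance(
    rat_table: pd.DataFrame,
    human_table: pd.DataFrame,
    contrast: str,
    mode: str = MODE_SIGN_ONLY,
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Direction concordance of shared features for one contrast."""
    if mode not in {MODE_SIGN_ONLY, MODE_SIGN_AND_SIG}:
        raise ValidationError(f"unknown concordance mode {mode!r}")
    rat = rat_table[rat_table["contrast"] == contrast]
    human = human_table[human_table["contrast"] == contrast]
    if len(rat) == 0 or len(human) == 0:
        raise ValidationError(f"contrast {contrast!r} absent from input table")
    shared = match_shared(rat, human)
    rat_idx = rat.set_index("feature_id")
    hum_idx = human.set_index("feature_id")
    n_consistent = n_inconsistent = 0
    for fid in shared:
        d_rat = direction(rat_idx.at[fid, "log2fc"], rat_idx.at[fid, "p_value"], mode, alpha)
        d_hum = direction(hum_idx.at[fid, "log2fc"], hum_idx.at[fid, "p_value"], mode, alpha)
        if d_rat == "unchanged" or d_hum == "unchanged":
            continue
        if d_rat == d_hum:
            n_consistent += 1
        else:
            n_inconsistent += 1
    denom = n_consistent + n_inconsistent
    pct = round_half_up(100.0 * n_consistent / denom) if denom else None
    return ConcordanceResult(
        contrast=contrast,
        n_shared=len(shared),
        n_consistent=n_consistent,
        n_inconsistent=n_inconsistent,
        pct_consistent=pct,
    )


def concordance_all(
    rat_table: pd.DataFrame,
    human_table: pd.DataFrame,
    mode: str = MODE_SIGN_ONLY,
    alpha: float = 0.05,
) -> list[ConcordanceResult]:
    """Concordance for every contrast present in both tables (sorted order)."""
    contrasts = sorted(
        set(rat_table["contrast"]).intersection(human_table["contrast"])
    )
    return [concordance(rat_table, human_table, c, mode, alpha) for c in contrasts]
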