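"""Travel-survey processing: daily walking outcomes and inclusion rules.

A one-day trip diary yields, per respondent, total minutes and metres
walked plus a discretionary / non-discretionary split: work and study
trips are non-discretionary (fixed destinations), while shopping, leisure
walks, sports/hobby, recreational and home visits — trips with destination
choice — are discretionary.  A respondent with a completed diary and no
walking legs is a true observed zero (the left-censored observation the
Tobit model relies on), never a missing value.

Inclusion rules: working-age adults (18-65), no personal-circumstance
immobility, no travel abroad, and complete cases on the model variables.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DISCRETIONARY = "discretionary"
NON_DISCRETIONARY = "non_discretionary"

#: default purpose vocabulary -> trip class; external surveys can supply
#: their own mapping, unknown labels always fail loudly
DEFAULT_PURPOSE_MAP: dict[str, str] = {
    "work": NON_DISCRETIONARY,
    "study": NON_DISCRETIONARY,
    "grocery_shopping": DISCRETIONARY,
    "shopping": DISCRETIONARY,
    "leisure_walk": DISCRETIONARY,
    "sports_hobby": DISCRETIONARY,
    "recreational_visit": DISCRETIONARY,
    "home_visit": DISCRETIONARY,
    "other": DISCRETIONARY,
}

#: outcome columns derived per respondent
OUTCOME_COLUMNS = (
    "walk_minutes_total", "walk_minutes_discretionary",
    "walk_minutes_non_discretionary",
    "walk_metres_total", "walk_metres_discretionary",
    "walk_metres_non_discretionary",
)


def classify_purpose(purpose: str,
                     mapping: Mapping[str, str] | None = None) -> str:
    """Classify a trip purpose as discretionary or non-discretionary.

    Raises ``KeyError`` for labels outside the vocabulary — surveys with
    other codings must supply an explicit mapping rather than rely on a
    silent default.
    """
    mapping = DEFAULT_PURPOSE_MAP if mapping is None else mapping
    try:
        return mapping[purpose]
    except KeyError:
        raise KeyError(
            f"unknown trip purpose {purpose!r}; extend the purpose mapping "
            f"(known: {sorted(mapping)})"
        ) from None


def derive_daily_outcomes(trips: pd.DataFrame,
                          respondents: pd.DataFrame,
                          mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Sum walking legs per respondent-day into total and per-class outcomes.

    ``trips`` needs ``respondent_id``, ``purpose``, ``walk_minutes``,
    ``walk_metres``.  Every trip's respondent must exist in
    ``respondents``; respondents without trips get explicit zeros.
    """
    out = respondents.copy()
    if len(trips):
        unknown_resp = set(trips["respondent_id"]) - set(out["respondent_id"])
        if unknown_resp:
            raise ValueError(f"trips reference unknown respondents: {sorted(unknown_resp)[:5]}")
        if (trips["walk_minutes"] < 0).any() or (trips["walk_metres"] < 0).any():
            raise ValueError("negative walking minutes or metres in trip table")
        t = trips.copy()
        t["trip_class"] = [classify_purpose(p, mapping) for p in t["purpose"]]
        sums = (t.groupby(["respondent_id", "trip_class"])[["walk_minutes", "walk_metres"]]
                .sum().unstack("trip_class", fill_value=0.0))
    else:
        sums = pd.DataFrame()
    for unit, col in (("walk_minutes", "minutes"), ("walk_metres", "metres")):
        for cls, suffix in ((DISCRETIONARY, "discretionary"),
                            (NON_DISCRETIONARY, "non_discretionary")):
            vals = (sums[(unit, cls)] if (unit, cls) in sums.columns
                    else pd.Series(dtype=float))
            out[f"walk_{col}_{suffix}"] = (
                out["respondent_id"].map(vals).fillna(0.0).to_numpy())
        out[f"walk_{col}_total"] = (out[f"walk_{col}_discretionary"]
                                    + out[f"walk_{col}_non_discretionary"])
    return out


def apply_exclusions(respondents: pd.DataFrame,
                     model_vars: list[str] | None = None,
                     min_age: int = 18, max_age: int = 65):
    """Apply the inclusion rules; returns ``(kept, exclusion_log)``.

    Drops, in this order (the rules commute, so order only affects the
    attribution in the log): age outside [18, 65]; immobility for personal
    circumstances (``no_mobility_personal`` flag); travel abroad
    (``travelled_abroad`` flag); then complete-case deletion on
    ``model_vars`` with per-variable missingness counts in the log.
    """
    df = respondents
    log_rows = []
    mask_age = (df["age"] >= min_age) & (df["age"] <= max_age)
    log_rows.append(("age_outside_18_65", int((~mask_age).sum())))
    kept = df[mask_age]

    for flag, rule in (("no_mobility_personal", "immobile_personal_circumstances"),
                       ("travelled_abroad", "travelled_abroad")):
        if flag in kept.columns:
            drop = kept[flag].astype(bool)
            log_rows.append((rule, int(drop.sum())))
            kept = kept[~drop]
        else:
            log_rows.append((rule, 0))

    if model_vars:
        missing_any = pd.Series(False, index=kept.index)
        for v in model_vars:
            miss = kept[v].isna()
            log_rows.append((f"missing_{v}", int(miss.sum())))
            missing_any |= miss
        log_rows.append(("incomplete_case_total", int(missing_any.sum())))
        kept = kept[~missing_any]

    exclusion_log = pd.DataFrame(log_rows, columns=["rule", "n_excluded"])
    log.info("exclusions: %d of %d respondents kept", len(kept), len(df))
    return kept.copy(), exclusion_log
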