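"""Derivation of the two binary alcohol traits from gated questionnaire items.

``sips`` (alcohol initiation): a child who has heard of alcohol and ever
tried a sip.  Children who have not heard of alcohol cannot have sipped;
they are never-users (the gate skips the sip item).

``intent`` (susceptibility to initiation): defined among never-users
only.  A never-user is *not susceptible* (intent = 0) only when all three
susceptibility items sit at their floor — "Not at all curious" to the
curiosity item and "Definitely not" to both willingness items.  Any
single answer above the floor already falsifies that class, so one
susceptible-level answer suffices for intent = 1 even if the other items
are blank.  Ever-users get a not-applicable value; unresolvable blanks
propagate to missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import CURIOUS_LEVELS, WILLING_LEVELS

OBSERVED = "observed"
MISSING = "missing"
NOT_APPLICABLE = "not_applicable"

#: ordinal codes, 0 = floor ("not susceptible") level
CURIOUS_CODES = {lvl: i for i, lvl in enumerate(CURIOUS_LEVELS)}
WILLING_CODES = {lvl: i for i, lvl in enumerate(WILLING_LEVELS)}


@dataclass(frozen=True)
class TraitValue:
    name: str
    value: int | None  # 0 | 1 | None
    status: str = OBSERVED


def derive_sips(heard_alcohol: str, sipped: str) -> TraitValue:
    """heard=yes & sipped=yes -> 1; heard=yes & sipped=no -> 0;
    heard=no -> 0 (gated skip, never-user); blanks -> missing."""
    heard = heard_alcohol.strip().lower()
    sip = sipped.strip().lower()
    if heard == "no":
        return TraitValue("sips", 0)
    if heard == "yes":
        if sip == "yes":
            return TraitValue("sips", 1)
        if sip == "no":
            return TraitValue("sips", 0)
        return TraitValue("sips", None, MISSING)
    return TraitValue("sips", None, MISSING)


def _code(value: str, codes: dict[str, int], item: str) -> int | None:
    if value.strip() == "":
        return None
    for lvl, c in codes.items():
        if value.strip().lower() == lvl.lower():
            return c
    raise ValueError(f"{item}: {value!r} not on scale {list(codes)}")


def derive_intent(sips: TraitValue, curious: str, try_soon: str,
                  friend_offer: str) -> TraitValue:
    """Intent among never-users: 0 only when all three items are at the
    floor; 1 as soon as any item is above it; otherwise missing."""
    if sips.value == 1:
        return TraitValue("intent", None, NOT_APPLICABLE)
    if sips.value is None:
        return TraitValue("intent", None, MISSING)
    codes = [
        _code(curious, CURIOUS_CODES, "curious"),
        _code(try_soon, WILLING_CODES, "try_soon"),
        _code(friend_offer, WILLING_CODES, "friend_offer"),
    ]
    if any(c is not None and c > 0 for c in codes):
        return TraitValue("intent", 1)
    if any(c is None for c in codes):
        return TraitValue("intent", None, MISSING)
    return TraitValue("intent", 0)


def derive_traits(frame: pd.DataFrame) -> pd.DataFrame:
    """Add ``sips``, ``intent`` and ``intent_status`` columns to a cohort
    table (0/1 with NaN for missing; status distinguishes not-applicable
    ever-users from genuinely missing)."""
    out = frame.copy()
    n = len(frame)
    sips_vals = np.full(n, np.nan)
    intent_vals = np.full(n, np.nan)
    status = np.empty(n, dtype=object)

    def col(name):
        if name not in frame.columns:
            return [""] * n
        return frame[name].fillna("").astype(str).tolist()

    for i, (heard, sip, cur, soon, offer) in enumerate(
        zip(col("heard_alcohol"), col("sipped"), col("curious"),
            col("try_soon"), col("friend_offer"))
    ):
        sv = derive_sips(heard, sip)
        iv = derive_intent(sv, cur, soon, offer)
        if sv.value is not None:
            sips_vals[i] = sv.value
        if iv.value is not None:
            intent_vals[i] = iv.value
        status[i] = iv.status
    out["sips"] = sips_vals
    out["intent"] = intent_vals
    out["intent_status"] = status
    return out
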