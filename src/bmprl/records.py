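"""Trial-level record of the token game, shared by the simulator and all analyses."""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

SIDES = ("L", "R")
OUTCOMES = ("gain", "neutral", "loss")


@dataclass
class TrialRecord:
    """One trial of the biased matching pennies token game.

    ``asset_pre`` is the number of tokens owned at decision time; ``asset_post``
    the count after the outcome was applied (post juice-exchange reset, if any).
    ``time_from_injection`` is in seconds, negative before the injection.
    """

    session_id: str
    animal_id: str
    condition: str  # "saline" | "ketamine"
    route: str  # "IM" | "IN" | "none"
    trial_index: int  # 1-based within session
    time_from_injection: float
    risky_side: str
    animal_choice: str
    computer_choice: str
    outcome_class: str
    token_delta: int
    asset_pre: int
    asset_post: int
    juice_delivered: bool


COLUMNS = [f.name for f in fields(TrialRecord)]


def records_to_frame(records) -> pd.DataFrame:
    """Pack a sequence of TrialRecords into a DataFrame (one row per trial)."""
    return pd.DataFrame([vars(r) for r in records], columns=COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    return [TrialRecord(**{c: row[c] for c in COLUMNS}) for _, row in frame.iterrows()]
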