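"""End-of-session game scores.

Accuracy is the percentage of marked sheep that were actually lame
(precision, in information-retrieval terms); recall is the percentage of
truly lame sheep that were marked.  Accuracy is undefined (None) when no
sheep was marked; recall is undefined in the degenerate case of a flock
with no lame sheep.  Percentages are stored at full precision; display
rounding is one decimal place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = ["SessionScore", "accuracy", "recall", "session_report"]


@dataclass(frozen=True)
class SessionScore:
    accuracy: Optional[float]  # percent, None when nothing marked
    recall: Optional[float]  # percent, None only for a lame-free flock
    time_remaining: float  # seconds left on the game clock
    n_marked: int
    n_lame: int

    def rounded(self, ndigits: int = 1) -> dict:
        """Display form: percentages rounded, analysis keeps full precision."""
        rnd = lambda v: None if v is None else round(v, ndigits)
        return {
            "accuracy": rnd(self.accuracy),
            "recall": rnd(self.recall),
            "time_remaining": self.time_remaining,
            "n_marked": self.n_marked,
            "n_lame": self.n_lame,
        }


def _check_ids(marked_ids: set, known_ids: set) -> None:
    unknown = set(marked_ids) - set(known_ids)
    if unknown:
        raise ValueError(f"marks refer to unknown sheep ids: {sorted(unknown)}")


def accuracy(marked_ids: set, lame_ids: set, all_ids: set) -> Optional[float]:
    """Percent of marked sheep that are truly lame; None when none marked."""
    _check_ids(marked_ids, all_ids)
    if not marked_ids:
        return None
    return 100.0 * len(set(marked_ids) & set(lame_ids)) / len(marked_ids)


def recall(marked_ids: set, lame_ids: set, all_ids: set) -> Optional[float]:
    """Percent of truly lame sheep that were marked; None for a lame-free flock."""
    _check_ids(marked_ids, all_ids)
    if not lame_ids:
        warnings.warn(
            "flock contains no lame sheep; recall is undefined", stacklevel=2
        )
        return None
    return 100.0 * len(set(marked_ids) & set(lame_ids)) / len(lame_ids)


def session_report(log) -> SessionScore:
    """Score a finished session from its event log.

    Time remaining is the session length minus the moment the player
    finished (zero when the timer ran out).
    """
    all_ids = set(log.roster)
    lame_ids = {sid for sid, st in log.roster.items() if st == "lame"}
    marked = log.marked_ids()
    session_length = log.config_echo.session_length
    return SessionScore(
        accuracy=accuracy(marked, lame_ids, all_ids),
        recall=recall(marked, lame_ids, all_ids),
        time_remaining=max(0.0, session_length - log.end_time),
        n_marked=len(marked),
        n_lame=len(lame_ids),
    )
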