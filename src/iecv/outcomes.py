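"""Dichotomization of functional-outcome scales.

Functional outcome after aneurysmal subarachnoid hemorrhage is recorded on
one of three ordinal scales: the Glasgow Outcome Scale (GOS, 1-5, 5 = no
symptoms, 1 = death), the extended GOS (eGOS, 1-8), or the modified Rankin
Scale (mRS, 0-6, 0 = no symptoms, 6 = death).  All three are collapsed to a
binary favorable/unfavorable indicator:

* GOS  4-5 favorable, 1-3 unfavorable
* eGOS 4-8 favorable, 1-3 unfavorable
* mRS  0-3 favorable, 4-6 unfavorable

Note the mRS runs in the opposite direction (low = good).

When a patient has scores on several scales, one is chosen by a fixed
priority: GOS first, then mRS, then eGOS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "SCALE_RANGES",
    "SCALE_PRIORITY",
    "OutcomeScore",
    "dichotomize",
    "select_scale",
    "favorable_from_scores",
]

#: inclusive (low, high) integer range of each supported scale
SCALE_RANGES = {"GOS": (1, 5), "eGOS": (1, 8), "mRS": (0, 6)}

#: deterministic preference order when several scales are recorded
SCALE_PRIORITY = ("GOS", "mRS", "eGOS")


@dataclass(frozen=True)
class OutcomeScore:
    """A raw score on one of the supported outcome scales."""

    scale: str
    value: int

    def __post_init__(self) -> None:
        if self.scale not in SCALE_RANGES:
            raise ValueError(
                f"unknown outcome scale {self.scale!r}; "
                f"expected one of {sorted(SCALE_RANGES)}"
            )
        lo, hi = SCALE_RANGES[self.scale]
        if not (isinstance(self.value, (int,)) and lo <= self.value <= hi):
            raise ValueError(
                f"{self.scale} score {self.value!r} outside valid range "
                f"[{lo}, {hi}]"
            )


def dichotomize(score: OutcomeScore) -> int:
    """Map a raw outcome score to 1 (favorable) or 0 (unfavorable).

    Favorable means GOS >= 4, eGOS >= 4 or mRS <= 3.  The mapping is
    monotone in the "better outcome" direction of each scale.
    """
    if score.scale in ("GOS", "eGOS"):
        return int(score.value >= 4)
    return int(score.value <= 3)  # mRS: low is good


def favorable_from_scores(scales: Iterable, values: Iterable) -> list:
    """Row-wise dichotomization of paired scale-name / raw-score columns.

    Rows with a missing scale or score yield ``None`` (missing outcome);
    out-of-range scores raise, naming the scale and value.
    """
    out = []
    for scale, value in zip(scales, values):
        if scale is None or value is None or scale != scale or value != value:
            out.append(None)  # NaN-safe missing check
            continue
        out.append(dichotomize(OutcomeScore(str(scale), int(value))))
    return out


def select_scale(available: Iterable[OutcomeScore]) -> Optional[OutcomeScore]:
    """Pick the preferred score among those recorded for a patient.

    Priority is GOS > mRS > eGOS.  Returns ``None`` when no score is
    available (a missing outcome, not an error).
    """
    by_scale = {s.scale: s for s in available}
    for scale in SCALE_PRIORITY:
        if scale in by_scale:
            return by_scale[scale]
    return None
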