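"""Yale-Brown obsessive-compulsive severity scoring.

Only the ten-item total severity score is implemented: each item (time
spent, interference, distress, resistance, control — for obsessions and
compulsions separately) is rated 0-4, the total ranges 0-40 and is
categorized as low (8-15), moderate (16-23), severe (24-31) or very
severe (32-40).  Totals below 8 fall outside the published categories and
receive the package-defined label "subthreshold".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "N_ITEMS",
    "CATEGORIES",
    "SeverityResult",
    "total_severity",
    "severity_category",
    "score_severity",
]

N_ITEMS = 10
MAX_ITEM = 4

#: Category labels in increasing severity order with their inclusive
#: total-score bounds.  "subthreshold" (0-7) is artifact-defined; the
#: other four are the published bands.
CATEGORIES = (
    ("subthreshold", 0, 7),
    ("low", 8, 15),
    ("moderate", 16, 23),
    ("severe", 24, 31),
    ("very severe", 32, 40),
)


@dataclass(frozen=True)
class SeverityResult:
    total: int
    category: str


def total_severity(items: Sequence[int]) -> int:
    """Sum of the ten severity item scores (0-40)."""
    items = list(items)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected exactly {N_ITEMS} item scores, got {len(items)}")
    for i, v in enumerate(items):
        if not isinstance(v, (int,)) or isinstance(v, bool):
            if not float(v).is_integer():
                raise ValueError(f"item {i + 1} score {v!r} is not an integer")
            v = int(v)
        if not 0 <= v <= MAX_ITEM:
            raise ValueError(f"item {i + 1} score {v} outside 0-{MAX_ITEM}")
    return int(sum(items))


def severity_category(total: int) -> str:
    """Severity band for a total score, boundaries inclusive."""
    if not 0 <= total <= 40:
        raise ValueError(f"total severity {total} outside 0-40")
    for label, lo, hi in CATEGORIES:
        if lo <= total <= hi:
            return label
    raise AssertionError("unreachable: CATEGORIES partition 0-40")


def score_severity(items: Sequence[int]) -> SeverityResult:
    total = total_severity(items)
    return SeverityResult(total=total, category=severity_category(total))
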