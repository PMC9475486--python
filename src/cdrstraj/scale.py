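"""CDRS-R instrument model: item scales, scoring, outcome and stratum labels.

The Children's Depression Rating Scale-Revised (CDRS-R) is a 17-item
clinician-rated depression severity instrument for children and
adolescents.  Fourteen items are rated 1-7 and three observational items
(sleep disturbance, appetite disturbance, listless speech) are rated 1-5,
so the total score ranges from 17 to 113.  A total of >= 40 is the
conventional inclusion threshold for moderate depression in clinical
trials; remission is a total <= 28 at a follow-up visit, and response is a
>= 50% reduction in severity from baseline.

This module holds the fixed scale definitions plus the label algebra used
everywhere else: outcome classification at follow-up visits and the fixed
severity-band stratum assignment (B1/B2/B3 at the intermediate visit,
C1/C2/C3 at the end of the acute phase).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

N_ITEMS = 17
TOTAL_MIN = 17
TOTAL_MAX = 113

#: Remission cut: CDRS-R total <= 28 at a follow-up visit.
REMISSION_CUT = 28
#: Active depression / trial inclusion threshold.
ACTIVE_CUT = 40

VISITS = ("baseline", "mid", "end")

#: Outcome labels in the canonical order used by every probability table.
OUTCOMES = ("remission", "response", "nonresponse")

BASELINE_STRATA = ("A1", "A2")
MID_STRATA = ("B1", "B2", "B3")
END_STRATA = ("C1", "C2", "C3")


@dataclass(frozen=True)
class ItemScale:
    """One CDRS-R item: identifier, label and admissible score range."""

    item_id: int
    label: str
    min_score: int = 1
    max_score: int = 7

    def __post_init__(self) -> None:
        if not 1 <= self.item_id <= N_ITEMS:
            raise ValueError(f"item_id must be 1..{N_ITEMS}, got {self.item_id}")
        if self.max_score not in (5, 7) or self.min_score != 1:
            raise ValueError("CDRS-R items are rated 1-7 or 1-5")

    def validate(self, score: int) -> None:
        if not (self.min_score <= score <= self.max_score):
            raise ValueError(
                f"item {self.item_id} ({self.label}): score {score} outside "
                f"[{self.min_score}, {self.max_score}]"
            )


#: The published CDRS-R item set.  Items 4, 5 and 16 (sleep, appetite,
#: listless speech) are the three 1-5 observational scales.
CDRS_ITEMS: tuple[ItemScale, ...] = (
    ItemScale(1, "impaired schoolwork"),
    ItemScale(2, "difficulty having fun"),
    ItemScale(3, "social withdrawal"),
    ItemScale(4, "sleep disturbance", max_score=5),
    ItemScale(5, "appetite disturbance", max_score=5),
    ItemScale(6, "excessive fatigue"),
    ItemScale(7, "physical complaints"),
    ItemScale(8, "irritability"),
    ItemScale(9, "excessive guilt"),
    ItemScale(10, "low self-esteem"),
    ItemScale(11, "depressed feelings"),
    ItemScale(12, "morbid ideation"),
    ItemScale(13, "suicidal ideation"),
    ItemScale(14, "excessive weeping"),
    ItemScale(15, "depressed facial affect"),
    ItemScale(16, "listless speech", max_score=5),
    ItemScale(17, "hypoactivity"),
)

ITEM_MAXES: tuple[int, ...] = tuple(it.max_score for it in CDRS_ITEMS)


def total_score(items: Sequence[int]) -> int:
    """Sum the 17 item scores after validating each against its scale.

    Raises
    ------
    ValueError
        If the sequence does not have exactly 17 entries or any score is
        outside its item's range (the error names the offending item).
    """
    items = list(items)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item scores, got {len(items)}")
    for scale, score in zip(CDRS_ITEMS, items):
        scale.validate(int(score))
    return int(sum(items))


def classify_outcome(
    baseline_total: int,
    current_total: int,
    response_reference: str = "scale_floor",
) -> str:
    """Classify a follow-up visit as remission, response or nonresponse.

    Remission is a current total <= 28 and takes precedence.  Response is
    a >= 50% reduction in severity from baseline.  Because the CDRS-R
    total is floored at 17 rather than 0, percent reduction is computed on
    the above-floor score by default::

        (baseline - current) / (baseline - 17) >= 0.5

    equivalently ``current <= (baseline + 17) / 2``.  With
    ``response_reference="raw"`` the reduction is taken on the raw total
    (``current <= 0.5 * baseline``); under that reading
    response-without-remission is unattainable for baselines <= 56.
    """
    if baseline_total < ACTIVE_CUT:
        raise ValueError(
            f"baseline total {baseline_total} below inclusion threshold {ACTIVE_CUT}"
        )
    if current_total < 0:
        raise ValueError("negative CDRS-R total")
    if current_total <= REMISSION_CUT:
        return "remission"
    if response_reference == "scale_floor":
        threshold = (baseline_total + TOTAL_MIN) / 2.0
    elif response_reference == "raw":
        threshold = 0.5 * baseline_total
    else:
        raise ValueError(f"unknown response_reference {response_reference!r}")
    return "response" if current_total <= threshold else "nonresponse"


def assign_followup_stratum(total: int, visit: str) -> str:
    """Map a follow-up total to its fixed severity band.

    Bands are 0-28 / 29-39 / >=40, labelled B1/B2/B3 at the intermediate
    visit (weeks 4-6) and C1/C2/C3 at the end of the acute phase (weeks
    10-12).
    """
    if total < 0:
        raise ValueError("negative CDRS-R total")
    if visit == "mid":
        labels = MID_STRATA
    elif visit == "end":
        labels = END_STRATA
    else:
        raise ValueError(f"visit must be 'mid' or 'end', got {visit!r}")
    if total <= REMISSION_CUT:
        return labels[0]
    if total < ACTIVE_CUT:
        return labels[1]
    return labels[2]


def stratum_score_range(stratum: str) -> tuple[int, int | None]:
    """Closed integer score range of a fixed follow-up stratum.

    Returns ``(low, high)`` with ``high=None`` for the open-ended >=40
    band.  Baseline strata depend on the fitted mixture boundary and are
    handled by :mod:`cdrstraj.mixture`.
    """
    if stratum in ("B1", "C1"):
        return (0, REMISSION_CUT)
    if stratum in ("B2", "C2"):
        return (REMISSION_CUT + 1, ACTIVE_CUT - 1)
    if stratum in ("B3", "C3"):
        return (ACTIVE_CUT, None)
    raise ValueError(f"no fixed range for stratum {stratum!r}")


def validate_items(items: Iterable[int]) -> list[str]:
    """Return a list of violation messages for one visit's item scores."""
    problems: list[str] = []
    items = list(items)
    if len(items) != N_ITEMS:
        return [f"expected {N_ITEMS} item scores, got {len(items)}"]
    for scale, score in zip(CDRS_ITEMS, items):
        try:
            scale.validate(int(score))
        except ValueError as exc:
            problems.append(str(exc))
    return problems
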