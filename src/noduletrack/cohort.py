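"""Published reference cohort summary counts for regression checks.

These are the per-lesion outcome counts reported for a 100-patient /
153-follow-up evaluation of a commercial landmark-based nodule-matching
system: 1,141 selected baseline lesions, of which 36 false positives, 964
correct matches, 119 missed matches and 22 incorrect assignments, with
per-localization correct/incorrect splits of 504/45 (parenchymal), 292/54
(peripheral), 136/29 (juxtavascular) and 32/13 (juxtaphrenic).

The reconstruction into per-lesion :class:`OutcomeRecord` rows is synthetic in
two places where the source tabulation does not go to that depth: the split of
each localization's incorrect count into missed vs incorrectly assigned (only
the overall 119/22 totals are published; the allocation below preserves them),
and the localization of false positives (not published; recorded as
parenchymal and excluded from localization analyses anyway). Every quantity
the evaluation module computes from these records depends only on the
published margins.
"""

from __future__ import annotations

from .types import OutcomeRecord

__all__ = ["cohort_outcome_counts", "cohort_outcome_records"]

#: localization -> (correct, missed, incorrect_assignment). Correct counts and
#: the row sums of (missed + incorrect) are published; the missed/incorrect
#: split per row is a synthetic allocation preserving the 119/22 totals.
_LOCALIZATION_COUNTS = {
    "parenchymal": (504, 40, 5),
    "peripheral": (292, 47, 7),
    "juxtavascular": (136, 26, 3),
    "juxtaphrenic": (32, 6, 7),
}
_N_FALSE_POSITIVE = 36


def cohort_outcome_counts() -> dict:
    """The published summary counts as plain integers."""
    correct = sum(v[0] for v in _LOCALIZATION_COUNTS.values())
    missed = sum(v[1] for v in _LOCALIZATION_COUNTS.values())
    incorrect = sum(v[2] for v in _LOCALIZATION_COUNTS.values())
    return {
        "n_lesions": correct + missed + incorrect + _N_FALSE_POSITIVE,
        "false_positive_detection": _N_FALSE_POSITIVE,
        "correct_match": correct,
        "missed_matching": missed,
        "incorrect_assignment": incorrect,
        "by_localization": {
            loc: {"correct": c, "incorrect": m + i}
            for loc, (c, m, i) in _LOCALIZATION_COUNTS.items()
        },
    }


def cohort_outcome_records() -> list[OutcomeRecord]:
    """Expand the summary counts into one OutcomeRecord per lesion."""
    records: list[OutcomeRecord] = []
    i = 0

    def add(outcome: str, localization: str, n: int) -> None:
        nonlocal i
        for _ in range(n):
            records.append(
                OutcomeRecord(
                    case_id="cohort",
                    lesion_id=f"L{i:04d}",
                    outcome=outcome,
                    localization=localization,
                )
            )
            i += 1

    for loc, (correct, missed, incorrect) in _LOCALIZATION_COUNTS.items():
        add("correct_match", loc, correct)
        add("missed_matching", loc, missed)
        add("incorrect_assignment", loc, incorrect)
    add("false_positive_detection", "parenchymal", _N_FALSE_POSITIVE)
    return records
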