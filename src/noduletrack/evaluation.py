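"""Outcome adjudication and stratified statistics for nodule matching.

Every selected baseline lesion receives exactly one outcome:

- ``false_positive_detection`` — the baseline detection is not a true nodule;
- ``correct_match`` — paired with its true counterpart at follow-up;
- ``incorrect_assignment`` — paired with a different nodule;
- ``missed_matching`` — a true nodule left unpaired, whether its counterpart
  was undetected at follow-up or drifted outside the distance threshold.

Lesions whose truth link says the nodule truly disappeared between exams are
excluded before adjudication.

Two matching-rate denominators are reported: the *overall* rate divides
correct matches by all true nodules evaluated, while the *conditional* rate
divides by the nodules whose counterpart was actually detected in both exams —
the difference isolates detection failures from assignment failures.

Association with strata (localization, per-exam nodule-count bin) is screened
by plain Pearson chi-square on contingency tables, with per-cell Pearson
residuals (O - E)/sqrt(E) for association plots; per-case rate differences use
the two-sided Mann-Whitney U-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    COUNT_BINS,
    DISAPPEARED,
    LOCALIZATIONS,
    OUTCOMES,
    DegenerateTableError,
    InconsistentMatchError,
    MatchResult,
    NoduleRecord,
    OutcomeRecord,
    count_bin,
)

__all__ = [
    "classify_outcomes",
    "followup_detected_ids",
    "compute_rates",
    "OutcomeTable",
    "chi2_independence",
    "ContingencyResult",
    "mann_whitney_u",
    "stratify",
    "StratifiedOutcomes",
]


def followup_detected_ids(
    selected_baseline: Sequence[NoduleRecord],
    followup_detections: Sequence[NoduleRecord],
    truth_links: Mapping[str, str],
) -> set[str]:
    """Baseline lesion ids whose true counterpart was detected at follow-up.

    This is the truth-side denominator of the conditional matching rate: a
    nodule registered in *both* exams, regardless of whether the matcher then
    linked it correctly.
    """
    detected_true = {r.true_lesion_id for r in followup_detections if r.true_lesion_id}
    out = set()
    for rec in selected_baseline:
        if rec.true_lesion_id is None:
            continue
        link = truth_links.get(rec.true_lesion_id, rec.true_lesion_id)
        if link != DISAPPEARED and link in detected_true:
            out.add(rec.lesion_id)
    return out


def classify_outcomes(
    selected_baseline: Sequence[NoduleRecord],
    followup_detections: Sequence[NoduleRecord],
    matches: MatchResult,
    truth_links: Mapping[str, str],
    case_nodule_counts: Mapping[str, int] | None = None,
) -> list[OutcomeRecord]:
    """Adjudicate one outcome per selected baseline lesion against truth.

    ``truth_links`` maps each baseline true nodule id to its follow-up true id
    or to ``"disappeared"``; disappeared nodules are excluded. When
    ``case_nodule_counts`` (case_id -> total nodules in the exam) is given,
    each outcome also carries its <20 / 20-50 / >50 count bin.
    """
    fu_by_id = {r.lesion_id: r for r in followup_detections}
    for b, f, _ in matches.pairs:
        if f not in fu_by_id:
            raise InconsistentMatchError(
                f"inconsistent match result: follow-up lesion {f!r} not among detections"
            )
    matched_to = matches.baseline_of

    outcomes: list[OutcomeRecord] = []
    for rec in selected_baseline:
        link = (
            truth_links.get(rec.true_lesion_id, rec.true_lesion_id)
            if rec.true_lesion_id is not None
            else None
        )
        if link == DISAPPEARED:
            continue
        bin_label = (
            count_bin(case_nodule_counts[rec.case_id])
            if case_nodule_counts is not None and rec.case_id in case_nodule_counts
            else ""
        )
        if rec.true_lesion_id is None:
            outcome = "false_positive_detection"
        elif rec.lesion_id in matched_to:
            partner = fu_by_id[matched_to[rec.lesion_id]]
            outcome = (
                "correct_match"
                if partner.true_lesion_id is not None and partner.true_lesion_id == link
                else "incorrect_assignment"
            )
        else:
            outcome = "missed_matching"
        outcomes.append(
            OutcomeRecord(
                case_id=rec.case_id,
                lesion_id=rec.lesion_id,
                outcome=outcome,
                localization=rec.localization,
                case_nodule_count_bin=bin_label,
            )
        )
    return outcomes


@dataclass
class OutcomeTable:
    """Outcome counts and matching rates with explicit denominators.

    Rates are fractions in [0, 1]; a rate whose denominator is zero is None
    and listed in ``undefined_rates`` rather than silently NaN.
    """

    counts: dict[str, int]
    n_total: int
    n_nodules: int  # total minus false positives
    overall_rate: float | None
    conditional_rate: float | None
    conditional_denominator: int
    fp_fraction: float | None
    missed_fraction: float | None
    incorrect_fraction: float | None
    not_matched_fraction: float | None
    by_localization: pd.DataFrame
    by_count_bin: pd.DataFrame
    per_case_rates: dict[str, float]
    per_case_median: float | None
    per_case_iqr: tuple[float, float] | None
    undefined_rates: list[str] = field(default_factory=list)


def _crosstab(df: pd.DataFrame, index: str, categories: Sequence[str]) -> pd.DataFrame:
    tab = pd.crosstab(df[index], df["outcome"])
    tab = tab.reindex(index=[c for c in categories if c in tab.index], fill_value=0)
    return tab.reindex(columns=list(OUTCOMES), fill_value=0)


def compute_rates(
    outcomes: Sequence[OutcomeRecord],
    followup_detected: Iterable[str] | None = None,
) -> OutcomeTable:
    """Aggregate outcome records into counts and the standard rates.

    ``followup_detected`` is the set of baseline lesion ids whose counterpart
    was detected at follow-up (see :func:`followup_detected_ids`); it is the
    conditional-rate denominator. Without it, the denominator falls back to
    correct + incorrect assignments — the flowchart arithmetic that holds when
    every missed match is a detection failure.
    """
    if not outcomes:
        raise ValueError("compute_rates needs at least one outcome record")
    df = pd.DataFrame(
        {
            "case_id": [o.case_id for o in outcomes],
            "lesion_id": [o.lesion_id for o in outcomes],
            "outcome": pd.Categorical([o.outcome for o in outcomes], categories=OUTCOMES),
            "localization": [o.localization for o in outcomes],
            "count_bin": [o.case_nodule_count_bin for o in outcomes],
        }
    )
    counts = df["outcome"].value_counts().to_dict()
    counts = {k: int(counts.get(k, 0)) for k in OUTCOMES}
    n_total = len(df)
    n_fp = counts["false_positive_detection"]
    n_nodules = n_total - n_fp
    n_correct = counts["correct_match"]

    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    if followup_detected is not None:
        cond_den = len(set(followup_detected))
    else:
        cond_den = n_correct + counts["incorrect_assignment"]

    per_case: dict[str, float] = {}
    for case_id, grp in df.groupby("case_id", sort=True):
        den = int((grp["outcome"] != "false_positive_detection").sum())
        if den == 0:
            undefined.append(f"per_case_rate[{case_id}]")
            continue
        per_case[str(case_id)] = float((grp["outcome"] == "correct_match").sum() / den)
    if per_case:
        vals = np.array(list(per_case.values()))
        med = float(np.median(vals))
        iqr = tuple(float(q) for q in np.percentile(vals, [25, 75]))
    else:
        med, iqr = None, None

    return OutcomeTable(
        counts=counts,
        n_total=n_total,
        n_nodules=n_nodules,
        overall_rate=ratio(n_correct, n_nodules, "overall_rate"),
        conditional_rate=ratio(n_correct, cond_den, "conditional_rate"),
        conditional_denominator=cond_den,
        fp_fraction=ratio(n_fp, n_total, "fp_fraction"),
        missed_fraction=ratio(counts["missed_matching"], n_nodules, "missed_fraction"),
        incorrect_fraction=ratio(
            counts["incorrect_assignment"], n_nodules, "incorrect_fraction"
        ),
        not_matched_fraction=ratio(n_nodules - n_correct, n_nodules, "not_matched_fraction"),
        by_localization=_crosstab(df, "localization", LOCALIZATIONS),
        by_count_bin=_crosstab(df[df["count_bin"] != ""], "count_bin", COUNT_BINS),
        per_case_rates=per_case,
        per_case_median=med,
        per_case_iqr=iqr,
        undefined_rates=undefined,
    )


@dataclass
class ContingencyResult:
    """Pearson chi-square independence screen with per-cell residuals."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    dof: int
    p_value: float
    pearson_residuals: pd.DataFrame

    def tidy(self) -> pd.DataFrame:
        """Long-format cells (row, col, observed, expected, residual) for
        association plotting."""
        rows = []
        for r in self.observed.index:
            for c in self.observed.columns:
                rows.append(
                    {
                        "row": r,
                        "col": c,
                        "observed": self.observed.loc[r, c],
                        "expected": self.expected.loc[r, c],
                        "residual": self.pearson_residuals.loc[r, c],
                    }
                )
        return pd.DataFrame(rows)


def chi2_independence(observed) -> ContingencyResult:
    """Plain Pearson chi-square test of independence on an r x c count table.

    No continuity correction is applied; df = (r-1)(c-1); residuals are
    (O - E)/sqrt(E), so their squares sum to the chi-square statistic. A
    warning (not an error) is emitted when any expected cell is below 5.
    """
    obs = observed if isinstance(observed, pd.DataFrame) else pd.DataFrame(np.asarray(observed))
    arr = obs.to_numpy(dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("counts must be finite and non-negative")
    if np.any(arr.sum(axis=1) == 0) or np.any(arr.sum(axis=0) == 0):
        raise DegenerateTableError("degenerate table: zero row or column margin")
    chi2, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    if np.any(expected < 5):
        warnings.warn(
            "chi-square approximation dubious: some expected cell counts are < 5",
            stacklevel=2,
        )
    exp_df = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    resid = (obs - exp_df) / np.sqrt(exp_df)
    return ContingencyResult(
        observed=obs,
        expected=exp_df,
        chi2=float(chi2),
        dof=int(dof),
        p_value=float(p),
        pearson_residuals=resid,
    )


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U-test between two samples of per-case rates.

    ``mode``: "exact" enumerates the null distribution, "asymptotic" uses the
    tie- and continuity-corrected normal approximation, "auto" picks exact for
    min(n) <= 8 without ties. Returns (U of group_a, two-sided p).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if mode == "exact" or (mode == "auto" and min(len(a), len(b)) <= 8 and not has_ties):
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class StratifiedOutcomes:
    """Outcome contingency views of one stratification.

    ``binary`` crosses strata with {correct, incorrect} over true nodules
    (false positives excluded, incorrect = missed + incorrectly assigned);
    ``root_cause`` crosses strata with all four outcome categories. Both carry
    full chi-square results with Pearson residuals when the table is
    non-degenerate.
    """

    by: str
    binary: pd.DataFrame
    root_cause: pd.DataFrame
    rates: pd.Series
    binary_result: ContingencyResult | None
    root_cause_result: ContingencyResult | None

    def tidy(self) -> pd.DataFrame:
        frames = []
        for name, res in (("binary", self.binary_result), ("root_cause", self.root_cause_result)):
            if res is None:
                continue
            t = res.tidy()
            t.insert(0, "table", name)
            frames.append(t)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def stratify(outcomes: Sequence[OutcomeRecord], by: str) -> StratifiedOutcomes:
    """Cross-tabulate outcomes by localization or per-exam count bin."""
    if by == "localization":
        strata = LOCALIZATIONS
        key = lambda o: o.localization
    elif by == "count_bin":
        strata = COUNT_BINS
        key = lambda o: o.case_nodule_count_bin
    else:
        raise ValueError(f"invalid stratum: {by!r} (use 'localization' or 'count_bin')")
    labels = [key(o) for o in outcomes]
    if by == "count_bin" and any(l == "" for l in labels):
        raise ValueError("invalid stratum: outcomes lack count-bin labels")

    df = pd.DataFrame({"stratum": labels, "outcome": [o.outcome for o in outcomes]})
    root = pd.crosstab(df["stratum"], df["outcome"])
    root = root.reindex(
        index=[s for s in strata if s in root.index], columns=list(OUTCOMES), fill_value=0
    )
    nodules = df[df["outcome"] != "false_positive_detection"]
    binary = pd.DataFrame(
        {
            "correct": nodules[nodules["outcome"] == "correct_match"]
            .groupby("stratum")
            .size(),
            "incorrect": nodules[nodules["outcome"] != "correct_match"]
            .groupby("stratum")
            .size(),
        }
    ).fillna(0).astype(int)
    binary = binary.reindex(index=[s for s in strata if s in binary.index], fill_value=0)
    totals = binary.sum(axis=1)
    rates = binary["correct"] / totals.where(totals > 0)

    def _safe(tab: pd.DataFrame) -> ContingencyResult | None:
        tab = tab.loc[:, tab.sum(axis=0) > 0]
        tab = tab.loc[tab.sum(axis=1) > 0, :]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            return None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return chi2_independence(tab)

    return StratifiedOutcomes(
        by=by,
        binary=binary,
        root_cause=root,
        rates=rates,
        binary_result=_safe(binary),
        root_cause_result=_safe(root),
    )
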