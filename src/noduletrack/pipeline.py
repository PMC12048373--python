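"""End-to-end study evaluation: register, select, match, adjudicate.

Ties the modules together for a list of case pairs (synthetic or loaded from
disk): ICP-register each pair's landmarks, select the evaluation targets from
the baseline detections, map their centroids into follow-up space, pair them
against all follow-up detections at the distance threshold, and adjudicate
outcomes against truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

from pydantic import BaseModel, Field

from . import evaluation, matching, registration
from .types import AffineTransform, MatchResult, OutcomeRecord
from .synthetic import CasePair


class IcpOptions(BaseModel):
    max_iter: int = Field(100, ge=1)
    rms_tol_mm: float = Field(1e-6, gt=0)
    trim_fraction: float = Field(0.1, ge=0, lt=1)
    use_labels: bool = False


class RunConfig(BaseModel):
    """Pipeline constants; the defaults are the protocol's stated values."""

    threshold_mm: float = Field(15.0, gt=0)
    top_k: int = Field(10, ge=1)
    d_min_mm: float = Field(5.0, gt=0)
    d_max_mm: float = Field(30.0, gt=0)
    pleura_margin_mm: float = Field(10.0, gt=0)
    icp: IcpOptions = IcpOptions()
    seed: int = 0


@dataclass
class PairResult:
    pair_id: str
    transform: AffineTransform
    match: MatchResult
    outcomes: list[OutcomeRecord]
    followup_detected: set[str]


@dataclass
class StudyResult:
    pair_results: list[PairResult]
    outcomes: list[OutcomeRecord] = field(init=False)
    followup_detected: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.outcomes = [o for pr in self.pair_results for o in pr.outcomes]
        self.followup_detected = set().union(
            *(pr.followup_detected for pr in self.pair_results)
        ) if self.pair_results else set()

    def table(self) -> evaluation.OutcomeTable:
        return evaluation.compute_rates(self.outcomes, self.followup_detected)

    def stratified(self, by: str) -> evaluation.StratifiedOutcomes:
        return evaluation.stratify(self.outcomes, by)


def evaluate_pair(pair: CasePair, config: RunConfig | None = None) -> PairResult:
    config = config or RunConfig()
    transform, _ = registration.icp_affine_register(
        pair.baseline_landmarks,
        pair.followup_landmarks,
        **config.icp.model_dump(),
    )
    selected = matching.select_target_lesions(
        pair.baseline_lesions,
        k=config.top_k,
        d_min_mm=config.d_min_mm,
        d_max_mm=config.d_max_mm,
    )
    coreg = [
        # map baseline centroids into follow-up space, keep identities
        dataclasses.replace(r, centroid=transform.apply(r.centroid[None, :])[0])
        for r in selected
    ]
    match = matching.pair_nodules(coreg, pair.followup_lesions, config.threshold_mm)
    counts = {pair.case_id: pair.n_true_nodules}
    outcomes = evaluation.classify_outcomes(
        selected, pair.followup_lesions, match, pair.truth_links, counts
    )
    detected = evaluation.followup_detected_ids(
        selected, pair.followup_lesions, pair.truth_links
    )
    # a baseline lesion is evaluated once per follow-up pair, so the
    # detected-in-both denominator must be counted per pair as well
    detected = {f"{pair.pair_id}:{lid}" for lid in detected}
    return PairResult(pair.pair_id, transform, match, outcomes, detected)


def evaluate_study(
    pairs: Sequence[CasePair], config: RunConfig | None = None
) -> StudyResult:
    config = config or RunConfig()
    return StudyResult([evaluate_pair(p, config) for p in pairs])
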