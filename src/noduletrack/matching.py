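"""Nodule pairing across co-registered exams and target-lesion selection.

After the baseline exam has been mapped into follow-up space, two detections
are candidate counterparts when their centroid-to-centroid Euclidean distance
is strictly below the matching threshold (default 15 mm). Candidates are
resolved into a one-to-one pairing greedily in ascending distance order, which
coincides with the minimum-total-distance assignment whenever nodules are not
pathologically crowded (verified exhaustively in the test suite).

Target-lesion selection mirrors a follow-up reading protocol: at most the k
largest solid baseline nodules with diameters in [d_min, d_max] mm are
evaluated (defaults: 10 lesions, 5-30 mm).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .types import MatchResult, NoduleRecord, records_to_array

__all__ = ["select_target_lesions", "NoduleMatcher", "pair_nodules"]


def select_target_lesions(
    baseline: Sequence[NoduleRecord],
    k: int = 10,
    d_min_mm: float = 5.0,
    d_max_mm: float = 30.0,
) -> list[NoduleRecord]:
    """Pick the evaluation targets from a baseline exam.

    Keeps solid lesions with d_min_mm <= diameter <= d_max_mm (both bounds
    inclusive) and returns the ``k`` largest by diameter. Ties at the cutoff
    are broken by lexicographically smaller lesion_id, so selection is
    deterministic. Exclusion of truly disappeared nodules is a truth-dependent
    step and happens in the evaluation module.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < d_min_mm < d_max_mm:
        raise ValueError("need 0 < d_min_mm < d_max_mm")
    eligible = [
        r
        for r in baseline
        if r.texture == "solid" and d_min_mm <= r.diameter_mm <= d_max_mm
    ]
    eligible.sort(key=lambda r: (-r.diameter_mm, r.lesion_id))
    return eligible[:k]


def _greedy_pairs(
    dist: np.ndarray,
    threshold_mm: float,
    baseline_ids: Sequence,
    followup_ids: Sequence,
) -> list[tuple]:
    """One-to-one greedy assignment over an (nb, nf) distance matrix.

    Candidates with distance strictly below the threshold are taken in
    ascending distance order; exact ties fall back to (baseline id,
    follow-up id) lexicographic order.
    """
    bi, fi = np.nonzero(dist < threshold_mm)
    cand = sorted(
        zip(dist[bi, fi], bi, fi),
        key=lambda c: (c[0], baseline_ids[c[1]], followup_ids[c[2]]),
    )
    used_b: set[int] = set()
    used_f: set[int] = set()
    pairs = []
    for d, b, f in cand:
        if b in used_b or f in used_f:
            continue
        used_b.add(b)
        used_f.add(f)
        pairs.append((baseline_ids[b], followup_ids[f], float(d)))
    return pairs


class NoduleMatcher(BaseEstimator):
    """One-to-one nodule pairing at a Euclidean distance threshold.

    scikit-learn-style estimator: ``fit(baseline, followup)`` computes the
    pairing between two sets of already co-registered centroids and exposes it
    through fitted attributes. Inputs may be (n, 3) coordinate arrays (lesion
    ids default to row indices) or sequences of :class:`NoduleRecord`.

    Parameters
    ----------
    threshold_mm : float, default 15.0
        A pair is admitted only when its distance is *strictly below* this.

    Attributes
    ----------
    pairs_ : list of (baseline_id, followup_id, distance_mm)
    unmatched_baseline_, unmatched_followup_ : list of ids
    match_result_ : MatchResult
    """

    def __init__(self, threshold_mm: float = 15.0):
        self.threshold_mm = threshold_mm

    @staticmethod
    def _coerce(lesions) -> tuple[np.ndarray, list]:
        if len(lesions) and isinstance(lesions[0], NoduleRecord):
            return records_to_array(lesions), [r.lesion_id for r in lesions]
        pts = np.asarray(lesions, dtype=float).reshape(-1, 3)
        return pts, list(range(len(pts)))

    def fit(self, baseline, followup):
        if not self.threshold_mm > 0:
            raise ValueError("threshold_mm must be > 0")
        b_pts, b_ids = self._coerce(baseline)
        f_pts, f_ids = self._coerce(followup)
        if len(b_pts) and len(f_pts):
            pairs = _greedy_pairs(cdist(b_pts, f_pts), self.threshold_mm, b_ids, f_ids)
        else:
            pairs = []
        matched_b = {p[0] for p in pairs}
        matched_f = {p[1] for p in pairs}
        self.pairs_ = pairs
        self.unmatched_baseline_ = [i for i in b_ids if i not in matched_b]
        self.unmatched_followup_ = [i for i in f_ids if i not in matched_f]
        self.match_result_ = MatchResult(
            pairs=pairs,
            unmatched_baseline=self.unmatched_baseline_,
            unmatched_followup=self.unmatched_followup_,
            threshold_mm=self.threshold_mm,
        )
        return self


def pair_nodules(
    baseline_coreg: Sequence[NoduleRecord],
    followup: Sequence[NoduleRecord],
    threshold_mm: float = 15.0,
) -> MatchResult:
    """Pair baseline lesions (centroids already mapped into follow-up space)
    with follow-up lesions; functional wrapper around :class:`NoduleMatcher`."""
    return NoduleMatcher(threshold_mm=threshold_mm).fit(baseline_coreg, followup).match_result_
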