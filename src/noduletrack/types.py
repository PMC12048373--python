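"""Core domain containers for longitudinal nodule tracking.

All coordinates are millimetres in a fixed right-handed patient frame; there is
no voxel grid anywhere in this package. A *case pair* is one baseline exam plus
one follow-up exam of the same patient; the affine transform maps baseline
space into follow-up space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

LOCALIZATIONS = ("parenchymal", "peripheral", "juxtavascular", "juxtaphrenic")
TEXTURES = ("solid", "subsolid", "mixed")
OUTCOMES = (
    "correct_match",
    "missed_matching",
    "incorrect_assignment",
    "false_positive_detection",
)
COUNT_BINS = ("<20", "20-50", ">50")

#: Truth-link sentinel for a nodule that truly vanished between exams.
DISAPPEARED = "disappeared"


class SchemaError(ValueError):
    """A table or JSON document does not conform to the documented schema."""


class InsufficientCorrespondencesError(ValueError):
    """Fewer point correspondences than an affine fit requires."""


class RegistrationError(RuntimeError):
    """ICP could not produce a usable transform (too few landmarks, divergence)."""


class PlacementError(RuntimeError):
    """The simulator could not place a nodule with the requested localization."""


class DegenerateTableError(ValueError):
    """A contingency table has a zero row/column margin."""


class InconsistentMatchError(ValueError):
    """A match result references lesions absent from the detection lists."""


def count_bin(n_nodules: int) -> str:
    """Bin a per-exam total nodule count into <20 / 20-50 / >50.

    The middle bin is inclusive at both ends: [20, 50].
    """
    if n_nodules < 20:
        return "<20"
    if n_nodules <= 50:
        return "20-50"
    return ">50"


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 3)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) array of points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("invalid coordinates: non-finite values in point set")
    return pts


@dataclass
class PointSet:
    """Ordered, optionally labeled 3-D landmark coordinates for one exam."""

    points: np.ndarray
    labels: list[str] | None = None
    exam_id: str = ""

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != len(self.points):
                raise ValueError("labels must match the number of points")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("labels must be unique within an exam")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.points)


@dataclass
class AffineTransform:
    """Affine map p -> linear @ p + translation from baseline to follow-up space.

    ``linear`` is dimensionless; ``translation`` is in mm. ``rank_deficient`` is
    set when the fit that produced the transform had non-unique solutions (the
    minimum-norm solution is returned in that case).
    """

    linear: np.ndarray
    translation: np.ndarray
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.linear)) and np.all(np.isfinite(self.translation))):
            raise ValueError("invalid transform: non-finite entries")

    @property
    def is_plausible(self) -> bool:
        """True iff the linear part is orientation-preserving (det > 0)."""
        return bool(np.linalg.det(self.linear) > 0)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        out = pts @ self.linear.T + self.translation
        if not np.all(np.isfinite(out)):
            raise ValueError("invalid transform: non-finite mapped coordinates")
        return out

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the map q -> self(other(q))."""
        return AffineTransform(
            self.linear @ other.linear,
            self.linear @ other.translation + self.translation,
        )

    def invert(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation)

    def to_dict(self) -> dict:
        return {
            "frame": "baseline_to_followup",
            "linear": self.linear.tolist(),
            "translation_mm": self.translation.tolist(),
            "rank_deficient": bool(self.rank_deficient),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AffineTransform":
        return cls(
            np.asarray(d["linear"], dtype=float),
            np.asarray(d["translation_mm"], dtype=float),
            bool(d.get("rank_deficient", False)),
        )


@dataclass
class IcpDiagnostics:
    """Convergence bookkeeping for one ICP run."""

    iterations: int
    rms_history: list[float]
    converged: bool
    trimmed_fraction: float

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class NoduleRecord:
    """One detected lesion in one exam.

    ``true_lesion_id`` links the detection to the underlying true nodule; None
    means the detection is not a true nodule (a false positive) or the link is
    unknown.
    """

    lesion_id: str
    exam_id: str
    centroid: np.ndarray
    diameter_mm: float
    localization: str
    texture: str = "solid"
    true_lesion_id: str | None = None
    case_id: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.centroid)):
            raise ValueError(f"lesion {self.lesion_id}: non-finite centroid")
        if not (self.diameter_mm > 0 and math.isfinite(self.diameter_mm)):
            raise ValueError(f"lesion {self.lesion_id}: diameter_mm must be > 0")
        if self.localization not in LOCALIZATIONS:
            raise ValueError(
                f"lesion {self.lesion_id}: localization {self.localization!r} "
                f"not in {LOCALIZATIONS}"
            )
        if self.texture not in TEXTURES:
            raise ValueError(
                f"lesion {self.lesion_id}: texture {self.texture!r} not in {TEXTURES}"
            )


@dataclass
class MatchResult:
    """One-to-one baseline-to-follow-up pairing at a distance threshold.

    ``pairs`` holds (baseline lesion_id, follow-up lesion_id, distance_mm)
    triples, every distance strictly below ``threshold_mm``. Together with the
    unmatched lists the pairs partition each exam's lesions.
    """

    pairs: list[tuple[str, str, float]]
    unmatched_baseline: list[str]
    unmatched_followup: list[str]
    threshold_mm: float

    def __post_init__(self) -> None:
        for b, f, d in self.pairs:
            if not d < self.threshold_mm:
                raise ValueError(
                    f"pair ({b}, {f}) at {d} mm violates threshold {self.threshold_mm} mm"
                )
        b_ids = [p[0] for p in self.pairs]
        f_ids = [p[1] for p in self.pairs]
        if len(set(b_ids)) != len(b_ids) or len(set(f_ids)) != len(f_ids):
            raise ValueError("a lesion appears in more than one pair")

    @property
    def baseline_of(self) -> dict[str, str]:
        return {b: f for b, f, _ in self.pairs}

    def to_dict(self) -> dict:
        return {
            "threshold_mm": self.threshold_mm,
            "pairs": [
                {"baseline": b, "followup": f, "distance_mm": d}
                for b, f, d in self.pairs
            ],
            "unmatched_baseline": list(self.unmatched_baseline),
            "unmatched_followup": list(self.unmatched_followup),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MatchResult":
        return cls(
            [(p["baseline"], p["followup"], float(p["distance_mm"])) for p in d["pairs"]],
            list(d["unmatched_baseline"]),
            list(d["unmatched_followup"]),
            float(d["threshold_mm"]),
        )


@dataclass
class OutcomeRecord:
    """Adjudicated outcome for one selected baseline lesion."""

    case_id: str
    lesion_id: str
    outcome: str
    localization: str
    case_nodule_count_bin: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome {self.outcome!r} not in {OUTCOMES}")
        if self.localization not in LOCALIZATIONS:
            raise ValueError(f"localization {self.localization!r} not in {LOCALIZATIONS}")
        if self.case_nodule_count_bin not in ("",) + COUNT_BINS:
            raise ValueError(f"invalid stratum: {self.case_nodule_count_bin!r}")


def records_to_array(records: Sequence[NoduleRecord]) -> np.ndarray:
    """Stack record centroids into an (n, 3) array."""
    if not records:
        return np.zeros((0, 3))
    return np.stack([r.centroid for r in records])
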