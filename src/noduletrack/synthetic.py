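"""Synthetic paired-exam generator with known ground truth.

Emulates a follow-up cohort of thoracic CT exams at the level this pipeline
consumes: per-exam anatomical landmark sets and nodule detection tables, never
images. Each case gets a stylized thorax — two half-ellipsoid lungs truncated
below by a diaphragm dome, with a vessel tree drawn as line segments — which
supports the three distance queries that localization semantics need
(distance to pleura, to diaphragm, to the nearest vessel). True nodules are
placed according to a localization mix with geometric consistency, the
follow-up exam is produced by a random affine plus a caudal diaphragm
displacement that decays away from the diaphragm, and the detection step is
simulated by follow-up dropout and baseline false-positive injection.

Default configuration values emulate the structure of a 100-patient /
153-follow-up metastasis cohort: at most tens of nodules per exam in the three
count regimes (<20 / 20-50 / >50), diameters log-normal with median 9.0 mm,
localization mix 49.7 / 31.3 / 14.9 / 4.1 % (parenchymal / peripheral /
juxtavascular / juxtaphrenic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.spatial.transform import Rotation

from .types import (
    DISAPPEARED,
    LOCALIZATIONS,
    AffineTransform,
    NoduleRecord,
    PlacementError,
    PointSet,
)

__all__ = [
    "SyntheticConfig",
    "NoduleCountSpec",
    "AffineJitterSpec",
    "ThoraxGeometry",
    "CasePair",
    "classify_localization",
    "generate_study",
]


class NoduleCountSpec(BaseModel):
    """Total-nodule-count distribution per exam.

    ``fixed`` draws the same count for every case; ``cohort`` draws a count
    regime (<20 / 20-50 / >50) with the given weights, then a count uniformly
    within the regime's range.
    """

    kind: Literal["fixed", "cohort"] = "cohort"
    n: int = Field(10, ge=1)
    weights: tuple[float, float, float] = (0.608, 0.203, 0.190)
    ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (2, 19),
        (20, 50),
        (51, 110),
    )

    @model_validator(mode="after")
    def _check(self):
        # printed cohort percentages can be off by a rounding unit; normalize
        if any(w < 0 for w in self.weights) or abs(sum(self.weights) - 1) > 0.01:
            raise ValueError("weights must be non-negative and sum to 1")
        return self

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return self.n
        regime = rng.choice(3, p=np.asarray(self.weights) / sum(self.weights))
        lo, hi = self.ranges[regime]
        return int(rng.integers(lo, hi + 1))


class AffineJitterSpec(BaseModel):
    """Ranges of the random affine between baseline and follow-up."""

    rotation_deg: float = Field(10.0, ge=0)
    scale: tuple[float, float] = (0.95, 1.05)
    translation_mm: float = Field(20.0, ge=0)

    @model_validator(mode="after")
    def _check(self):
        if not 0 < self.scale[0] <= self.scale[1]:
            raise ValueError("scale range must satisfy 0 < lo <= hi")
        return self


class SyntheticConfig(BaseModel):
    """Full study-generation configuration; defaults emulate the target cohort."""

    n_cases: int = Field(100, ge=1)
    #: fraction of cases receiving a second follow-up exam (100 cases at 0.53
    #: yields 153 baseline/follow-up pairs).
    second_followup_fraction: float = Field(0.53, ge=0, le=1)
    nodules_per_case: NoduleCountSpec = NoduleCountSpec()
    localization_mix: tuple[float, float, float, float] = (0.497, 0.313, 0.149, 0.041)
    #: log-normal diameter parameters; mu is calibrated so the [5, 30] mm
    #: truncated median is 9.0 mm with IQR ~ [7.2, 11.4] mm.
    diameter_log_mu: float = 2.1666812
    diameter_log_sigma: float = Field(0.3702755, ge=0)
    diameter_range_mm: tuple[float, float] = (5.0, 30.0)
    n_landmarks: int = Field(40, ge=8)
    affine_jitter: AffineJitterSpec = AffineJitterSpec()
    #: magnitude of the caudal diaphragm displacement at the diaphragm surface
    #: (breathing-state difference between exams).
    diaphragm_shift_mm: float = Field(10.0, ge=0)
    #: e-folding length of the displacement with distance from the diaphragm.
    diaphragm_decay_mm: float = Field(30.0, gt=0)
    residual_jitter_mm: float = Field(1.0, ge=0)
    #: baseline follow-up detection dropout; the effective per-nodule dropout is
    #: dropout_prob + dropout_count_coupling * (total nodules in the exam),
    #: modelling harder detection in crowded lungs.
    dropout_prob: float = Field(0.08, ge=0, le=1)
    dropout_count_coupling: float = Field(0.001, ge=0)
    #: detection is not equally hard everywhere: nodules abutting vessels or
    #: the diaphragm, and subpleural ones, are harder for CAD to find than
    #: parenchymal nodules surrounded by air. Multiplies the effective dropout
    #: per localization, ordered (parenchymal, peripheral, juxtavascular,
    #: juxtaphrenic); set to (1, 1, 1, 1) for localization-blind detection.
    localization_dropout_factors: tuple[float, float, float, float] = (0.75, 1.4, 1.7, 2.0)
    #: expected false-positive detections injected per baseline exam.
    fp_rate: float = Field(0.3, ge=0)
    disappear_prob: float = Field(0.03, ge=0, le=1)
    subsolid_prob: float = Field(0.05, ge=0, le=1)
    min_separation_mm: float = Field(2.0, ge=0)
    #: per-landmark occlusion probability per nodule in the exam: crowded lungs
    #: hide anatomical landmarks from the follow-up detector.
    occlusion_per_nodule: float = Field(0.002, ge=0)
    pleura_margin_mm: float = Field(10.0, gt=0)
    contact_tol_mm: float = Field(2.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if any(p < 0 for p in self.localization_mix) or abs(sum(self.localization_mix) - 1) > 0.01:
            raise ValueError("localization_mix must be non-negative and sum to 1")
        if not 0 < self.diameter_range_mm[0] < self.diameter_range_mm[1]:
            raise ValueError("diameter_range_mm must be increasing and positive")
        return self


# --------------------------------------------------------------------------
# geometry


@dataclass
class Lung:
    """One half-ellipsoid lung truncated below by a diaphragm dome."""

    center: np.ndarray  # (3,)
    radii: np.ndarray  # (3,) semi-axes, mm
    dome_center_xy: np.ndarray  # (2,)
    dome_apex_z: float
    dome_radius: float  # curvature scale of the dome, mm
    vessels: np.ndarray  # (m, 2, 3) line segments

    def ellipsoid_coord(self, p: np.ndarray) -> float:
        """Scaled radial coordinate t (t = 1 on the ellipsoid surface)."""
        u = (np.asarray(p) - self.center) / self.radii
        return float(np.linalg.norm(u))

    def dome_z(self, x: float, y: float) -> float:
        r2 = (x - self.dome_center_xy[0]) ** 2 + (y - self.dome_center_xy[1]) ** 2
        return self.dome_apex_z - r2 / (2 * self.dome_radius)


@dataclass
class ThoraxGeometry:
    """Two stylized lungs plus the distance queries localization needs."""

    lungs: list[Lung]

    def _containing(self, p: np.ndarray) -> Lung:
        return min(self.lungs, key=lambda l: l.ellipsoid_coord(p))

    def contains(self, p) -> bool:
        p = np.asarray(p, dtype=float)
        lung = self._containing(p)
        return lung.ellipsoid_coord(p) <= 1.0 and p[2] >= lung.dome_z(p[0], p[1])

    def dist_to_pleura(self, p) -> float:
        """Radial distance from an interior point to the ellipsoid surface."""
        p = np.asarray(p, dtype=float)
        lung = self._containing(p)
        t = lung.ellipsoid_coord(p)
        if t <= 1e-9:
            return float(np.min(lung.radii))
        return float(np.linalg.norm(p - lung.center) * (1 - t) / t)

    def dist_to_diaphragm(self, p) -> float:
        """Vertical clearance above the containing lung's diaphragm dome."""
        p = np.asarray(p, dtype=float)
        lung = self._containing(p)
        return max(float(p[2] - lung.dome_z(p[0], p[1])), 0.0)

    def dist_to_vessel(self, p) -> float:
        p = np.asarray(p, dtype=float)
        best = math.inf
        for lung in self.lungs:
            a = lung.vessels[:, 0, :]
            b = lung.vessels[:, 1, :]
            ab = b - a
            denom = np.einsum("ij,ij->i", ab, ab)
            s = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.maximum(denom, 1e-12), 0, 1)
            proj = a + s[:, None] * ab
            best = min(best, float(np.min(np.linalg.norm(proj - p, axis=1))))
        return best


def classify_localization(
    centroid,
    geometry: ThoraxGeometry,
    pleura_margin_mm: float = 10.0,
    contact_tol_mm: float = 2.0,
) -> str:
    """Label a nodule's localization from the geometry's distance queries.

    Precedence is juxtaphrenic > juxtavascular > peripheral > parenchymal:
    diaphragm contact is rarest and most specific, so it wins; vessel contact
    beats the 10 mm pleural margin; anything else is parenchymal.
    """
    if geometry.dist_to_diaphragm(centroid) <= contact_tol_mm:
        return "juxtaphrenic"
    if geometry.dist_to_vessel(centroid) <= contact_tol_mm:
        return "juxtavascular"
    if geometry.dist_to_pleura(centroid) <= pleura_margin_mm:
        return "peripheral"
    return "parenchymal"


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _sample_geometry(rng: np.random.Generator) -> ThoraxGeometry:
    lungs = []
    for side, cx, radii0 in (("R", 95.0, (55.0, 85.0, 105.0)), ("L", -95.0, (50.0, 80.0, 100.0))):
        radii = np.asarray(radii0) * rng.uniform(0.92, 1.08, size=3)
        center = np.array([cx * rng.uniform(0.95, 1.05), rng.uniform(-8, 8), 0.0])
        dome_center = center[:2] + rng.uniform(-10, 10, size=2)
        dome_apex = center[2] - 0.55 * radii[2]
        dome_radius = rng.uniform(60.0, 90.0)
        hilum = center + np.array([-np.sign(cx) * 0.6 * radii[0], 0.0, 10.0])
        segs = []
        for _ in range(7):
            for _try in range(50):
                end = center + radii * _unit(rng) * rng.uniform(0.35, 0.8)
                lung_tmp = Lung(center, radii, dome_center, dome_apex, dome_radius, np.zeros((0, 2, 3)))
                if end[2] >= lung_tmp.dome_z(end[0], end[1]) + 5:
                    segs.append((hilum, end))
                    break
        # second-generation branches off random points of the primaries
        for _ in range(4):
            a, b = segs[rng.integers(len(segs))]
            start = a + rng.uniform(0.3, 0.8) * (np.asarray(b) - np.asarray(a))
            end = start + radii * _unit(rng) * rng.uniform(0.1, 0.25)
            segs.append((start, end))
        lungs.append(
            Lung(center, radii, dome_center, dome_apex, dome_radius, np.asarray(segs))
        )
    return ThoraxGeometry(lungs)


def _sample_landmarks(rng: np.random.Generator, geom: ThoraxGeometry, n: int) -> PointSet:
    """Named landmarks on the geometry: pleural surface points, vessel
    endpoints, dome apices, and a carina-like midline point."""
    pts: list[np.ndarray] = []
    labels: list[str] = []
    for lung, side in zip(geom.lungs, ("R", "L")):
        apex = np.array([*lung.dome_center_xy, lung.dome_apex_z])
        pts.append(apex)
        labels.append(f"{side}_dome")
        for i in range(3):
            seg = lung.vessels[i]
            pts.append(seg[1].copy())
            labels.append(f"{side}_vessel_{i}")
    pts.append(np.array([0.0, 10.0, 60.0]) + rng.uniform(-5, 5, size=3))
    labels.append("carina")
    n_surface = max(n - len(pts), 0)
    for i in range(n_surface):
        lung = geom.lungs[i % 2]
        side = "RL"[i % 2]
        for _try in range(100):
            p = lung.center + lung.radii * _unit(rng)
            if p[2] >= lung.dome_z(p[0], p[1]):
                break
        pts.append(p)
        labels.append(f"{side}_pleura_{i // 2:02d}")
    return PointSet(np.asarray(pts[:n]), labels=labels[:n])


_MAX_TRIES = 400


def _place_one(
    rng: np.random.Generator,
    geom: ThoraxGeometry,
    target: str,
    cfg: SyntheticConfig,
    existing: list[np.ndarray],
) -> np.ndarray:
    tol = cfg.contact_tol_mm
    for _ in range(_MAX_TRIES):
        lung = geom.lungs[rng.integers(2)]
        if target == "juxtaphrenic":
            r = rng.uniform(0, 0.45) * math.sqrt(2 * lung.dome_radius * 0.45 * lung.radii[2])
            ang = rng.uniform(0, 2 * math.pi)
            x = lung.dome_center_xy[0] + r * math.cos(ang)
            y = lung.dome_center_xy[1] + r * math.sin(ang)
            p = np.array([x, y, lung.dome_z(x, y) + rng.uniform(0.1, 0.9 * tol)])
        elif target == "juxtavascular":
            seg = lung.vessels[rng.integers(len(lung.vessels))]
            on = seg[0] + rng.uniform(0, 1) * (seg[1] - seg[0])
            p = on + _unit(rng) * rng.uniform(0.0, 0.9 * tol)
        else:
            d = _unit(rng)
            r_surface = 1.0 / np.linalg.norm(d / lung.radii)
            if target == "peripheral":
                depth = rng.uniform(0.3 * tol + 0.5, 0.95 * cfg.pleura_margin_mm)
            else:  # parenchymal
                depth = rng.uniform(cfg.pleura_margin_mm + 2.0, 0.75 * r_surface)
            p = lung.center + d * (r_surface - depth)
        if not geom.contains(p):
            continue
        if classify_localization(p, geom, cfg.pleura_margin_mm, cfg.contact_tol_mm) != target:
            continue
        if existing and np.min(np.linalg.norm(np.asarray(existing) - p, axis=1)) < cfg.min_separation_mm:
            continue
        return p
    raise PlacementError(
        f"placement failed: no admissible {target} position after {_MAX_TRIES} tries "
        f"(min_separation_mm={cfg.min_separation_mm})"
    )


def _sample_diameter(rng: np.random.Generator, cfg: SyntheticConfig) -> float:
    lo, hi = cfg.diameter_range_mm
    for _ in range(1000):
        d = float(rng.lognormal(cfg.diameter_log_mu, cfg.diameter_log_sigma))
        if lo <= d <= hi:
            return d
    return float(np.clip(d, lo, hi))


def _sample_affine(rng: np.random.Generator, jitter: AffineJitterSpec) -> AffineTransform:
    angle = math.radians(rng.uniform(-jitter.rotation_deg, jitter.rotation_deg))
    rot = Rotation.from_rotvec(angle * _unit(rng)).as_matrix()
    scale = rng.uniform(*jitter.scale)
    translation = rng.uniform(-jitter.translation_mm, jitter.translation_mm, size=3)
    return AffineTransform(scale * rot, translation)


@dataclass
class CasePair:
    """One baseline/follow-up exam pair with full ground truth."""

    case_id: str
    pair_id: str
    baseline_landmarks: PointSet
    followup_landmarks: PointSet
    baseline_lesions: list[NoduleRecord]
    followup_lesions: list[NoduleRecord]
    true_transform: AffineTransform
    truth_links: dict[str, str]  # baseline true id -> follow-up true id | "disappeared"
    n_true_nodules: int
    geometry: ThoraxGeometry = field(repr=False, default=None)


def generate_study(config: SyntheticConfig) -> list[CasePair]:
    """Generate a deterministic study of baseline/follow-up pairs.

    One master seed spawns an independent random stream per case (and per
    follow-up within the case), so any case is reproducible on its own and
    identical config + seed yields byte-identical lesion tables.
    """
    master = np.random.SeedSequence(config.seed)
    case_seqs = master.spawn(config.n_cases)
    n_double = round(config.second_followup_fraction * config.n_cases)
    pairs: list[CasePair] = []
    for ci, seq in enumerate(case_seqs):
        case_id = f"case{ci:03d}"
        n_followups = 2 if ci < n_double else 1
        geom_seq, base_seq, *fu_seqs = seq.spawn(2 + n_followups)
        geom = _sample_geometry(np.random.default_rng(geom_seq))
        brng = np.random.default_rng(base_seq)

        n_nod = config.nodules_per_case.sample(brng)
        mix = np.asarray(config.localization_mix) / sum(config.localization_mix)
        loc_counts = brng.multinomial(n_nod, mix)
        targets = [
            loc for loc, c in zip(LOCALIZATIONS, loc_counts) for _ in range(c)
        ]
        brng.shuffle(targets)
        positions: list[np.ndarray] = []
        locs: list[str] = []
        for target in targets:
            positions.append(_place_one(brng, geom, target, config, positions))
            locs.append(target)
        diameters = [_sample_diameter(brng, config) for _ in targets]
        textures = [
            "subsolid" if brng.uniform() < config.subsolid_prob else "solid"
            for _ in targets
        ]
        disappeared = {
            f"{case_id}n{i:03d}"
            for i in range(n_nod)
            if brng.uniform() < config.disappear_prob
        }
        # baseline false positives: non-nodular structures picked up by detection
        n_fp = brng.poisson(config.fp_rate)
        fp_positions = []
        for _ in range(n_fp):
            loc = LOCALIZATIONS[brng.choice(4, p=mix)]
            try:
                fp_positions.append(
                    (_place_one(brng, geom, loc, config, positions + [q for q, _ in fp_positions]), loc)
                )
            except PlacementError:
                continue

        base_exam = f"{case_id}_bl"
        baseline: list[NoduleRecord] = []
        for i, (p, loc, dmm, tex) in enumerate(zip(positions, locs, diameters, textures)):
            baseline.append(
                NoduleRecord(
                    lesion_id=f"{case_id}b{i:03d}",
                    exam_id=base_exam,
                    centroid=p,
                    diameter_mm=dmm,
                    localization=loc,
                    texture=tex,
                    true_lesion_id=f"{case_id}n{i:03d}",
                    case_id=case_id,
                )
            )
        for j, (p, loc) in enumerate(fp_positions):
            baseline.append(
                NoduleRecord(
                    lesion_id=f"{case_id}x{j:02d}",
                    exam_id=base_exam,
                    centroid=p,
                    diameter_mm=_sample_diameter(brng, config),
                    localization=loc,
                    texture="solid",
                    true_lesion_id=None,
                    case_id=case_id,
                )
            )

        landmarks = _sample_landmarks(brng, geom, config.n_landmarks)
        landmarks.exam_id = base_exam

        dropout_base = config.dropout_prob + config.dropout_count_coupling * n_nod
        loc_factor = dict(zip(LOCALIZATIONS, config.localization_dropout_factors))
        occl_p = min(config.occlusion_per_nodule * n_nod, 0.6)

        for k, fu_seq in enumerate(fu_seqs, start=1):
            frng = np.random.default_rng(fu_seq)
            pair_id = f"{case_id}_fu{k}"
            fu_exam = f"{pair_id}_ex"
            transform = _sample_affine(frng, config.affine_jitter)

            def warp(pts: np.ndarray) -> np.ndarray:
                if config.diaphragm_shift_mm == 0:
                    return transform.apply(pts)
                shifted = np.array(pts, dtype=float, copy=True)
                for row in shifted:
                    d = geom.dist_to_diaphragm(row)
                    row[2] -= config.diaphragm_shift_mm * math.exp(-d / config.diaphragm_decay_mm)
                return transform.apply(shifted)

            fu_lm_pts = warp(landmarks.points)
            visible = frng.uniform(size=len(fu_lm_pts)) >= occl_p
            if visible.sum() < 4:
                visible[:] = True  # degenerate occlusion draw; keep exam usable
            fu_landmarks = PointSet(
                fu_lm_pts[visible],
                labels=[l for l, v in zip(landmarks.labels, visible) if v],
                exam_id=fu_exam,
            )

            followup: list[NoduleRecord] = []
            truth_links: dict[str, str] = {}
            for i, rec in enumerate(r for r in baseline if r.true_lesion_id is not None):
                nid = rec.true_lesion_id
                if nid in disappeared:
                    truth_links[nid] = DISAPPEARED
                    continue
                truth_links[nid] = nid
                p_drop = min(dropout_base * loc_factor[rec.localization], 0.95)
                if frng.uniform() < p_drop:
                    continue  # present but undetected at follow-up
                pos = warp(rec.centroid[None, :])[0]
                if config.residual_jitter_mm > 0:
                    pos = pos + frng.normal(0, config.residual_jitter_mm, size=3)
                followup.append(
                    NoduleRecord(
                        lesion_id=f"{pair_id}f{i:03d}",
                        exam_id=fu_exam,
                        centroid=pos,
                        diameter_mm=rec.diameter_mm,
                        localization=rec.localization,
                        texture=rec.texture,
                        true_lesion_id=nid,
                        case_id=case_id,
                    )
                )

            pairs.append(
                CasePair(
                    case_id=case_id,
                    pair_id=pair_id,
                    baseline_landmarks=landmarks,
                    followup_landmarks=fu_landmarks,
                    baseline_lesions=list(baseline),
                    followup_lesions=followup,
                    true_transform=transform,
                    truth_links=truth_links,
                    n_true_nodules=n_nod,
                    geometry=geom,
                )
            )
    return pairs
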