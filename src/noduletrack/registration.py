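"""Affine landmark registration between serial chest CT exams.

The inter-exam deformation is modelled as a single affine map estimated from
automatically detected anatomical landmarks by iterative closest point (ICP):
alternate exact nearest-neighbour correspondence with a least-squares affine
fit until the trimmed RMS correspondence distance stops changing. This is the
data-minimalistic registration used when the full prior image volume is no
longer available and only landmark coordinates persist.

`AffineICP` follows the scikit-learn estimator protocol (``fit`` on a moving
and a fixed point set, ``transform`` to map points, fitted attributes with a
trailing underscore); :func:`icp_affine_register` and :func:`fit_affine` are
the functional surface over it.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .types import (
    AffineTransform,
    IcpDiagnostics,
    InsufficientCorrespondencesError,
    PointSet,
    RegistrationError,
    _as_points,
)

__all__ = ["fit_affine", "apply_affine", "AffineICP", "icp_affine_register"]


def _coerce(ps) -> tuple[np.ndarray, list[str] | None, str]:
    if isinstance(ps, PointSet):
        return ps.points, ps.labels, ps.exam_id
    return _as_points(ps), None, ""


def fit_affine(src, dst, pairs) -> AffineTransform:
    """Least-squares affine transform mapping paired source points onto
    destination points.

    Parameters
    ----------
    src, dst : PointSet or (n, 3) array
    pairs : sequence of (src_index, dst_index)
        The correspondences to fit. At least 4 are required; the paired source
        points must be affinely independent (not coplanar) for a unique
        solution. On rank deficiency the minimum-norm solution is returned
        with ``rank_deficient=True``.
    """
    s, _, _ = _coerce(src)
    d, _, _ = _coerce(dst)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if len(pairs) < 4:
        raise InsufficientCorrespondencesError(
            f"insufficient correspondences: affine fit needs >= 4 pairs, got {len(pairs)}"
        )
    X = s[pairs[:, 0]]
    Y = d[pairs[:, 1]]
    # Solve [X 1] @ M = Y for M (4x3); lstsq returns the minimum-norm solution
    # when the design matrix is rank deficient.
    H = np.hstack([X, np.ones((len(X), 1))])
    M, _, rank, _ = np.linalg.lstsq(H, Y, rcond=None)
    return AffineTransform(M[:3].T, M[3], rank_deficient=bool(rank < 4))


def apply_affine(transform: AffineTransform, pts) -> PointSet:
    """Map a point set through an affine transform, preserving labels."""
    points, labels, exam_id = _coerce(pts)
    return PointSet(transform.apply(points), labels=labels, exam_id=exam_id)


class AffineICP(BaseEstimator):
    """Iterative-closest-point affine registration of two landmark sets.

    Starting from a centroid-aligning translation, the estimator alternates
    correspondence search with a least-squares affine fit. Correspondence is
    exact nearest neighbour from each moving point to the fixed set (ties
    broken by lower fixed-point index); with ``use_labels=True`` and labeled
    input, correspondence is by shared landmark label instead, which makes the
    problem a single fit. Each fit discards the ``ceil(trim_fraction * n)``
    worst correspondences, which tolerates occluded or spurious landmarks.

    Parameters
    ----------
    max_iter : int, default 100
        Iteration cap.
    rms_tol_mm : float, default 1e-6
        Convergence declared when the trimmed RMS changes by less than this.
    trim_fraction : float, default 0.1
        Fraction of worst correspondences excluded from every fit. Set to 0
        for exact recovery on clean data.
    use_labels : bool, default False
        Correspond landmarks by label when both sets carry labels.

    Attributes
    ----------
    transform_ : AffineTransform
        Fitted baseline-to-follow-up map.
    linear_ : (3, 3) ndarray, translation_ : (3,) ndarray
        Its components.
    diagnostics_ : IcpDiagnostics
    n_iter_ : int, rms_history_ : list of float, converged_ : bool
    """

    def __init__(
        self,
        max_iter: int = 100,
        rms_tol_mm: float = 1e-6,
        trim_fraction: float = 0.1,
        use_labels: bool = False,
    ):
        self.max_iter = max_iter
        self.rms_tol_mm = rms_tol_mm
        self.trim_fraction = trim_fraction
        self.use_labels = use_labels

    def fit(self, moving, fixed):
        """Estimate the affine map carrying ``moving`` onto ``fixed``."""
        mov, mov_labels, _ = _coerce(moving)
        fix, fix_labels, _ = _coerce(fixed)
        if not (0 <= self.trim_fraction < 1):
            raise ValueError("trim_fraction must be in [0, 1)")
        if len(mov) < 4 or len(fix) < 4:
            raise RegistrationError(
                f"insufficient landmarks: need >= 4 in each set, "
                f"got {len(mov)} moving / {len(fix)} fixed"
            )

        label_pairs = None
        if self.use_labels:
            if mov_labels is None or fix_labels is None:
                raise RegistrationError("use_labels requires labeled point sets")
            fix_index = {lab: j for j, lab in enumerate(fix_labels)}
            label_pairs = np.array(
                [(i, fix_index[lab]) for i, lab in enumerate(mov_labels) if lab in fix_index],
                dtype=int,
            ).reshape(-1, 2)
            if len(label_pairs) < 4:
                raise RegistrationError(
                    f"insufficient landmarks: only {len(label_pairs)} shared labels"
                )

        linear = np.eye(3)
        translation = fix.mean(axis=0) - mov.mean(axis=0)

        n_corr = len(label_pairs) if label_pairs is not None else len(mov)
        n_keep = n_corr - math.ceil(self.trim_fraction * n_corr)
        if n_keep < 4:
            raise RegistrationError(
                "insufficient landmarks: trimming leaves fewer than 4 correspondences"
            )

        initial_rms = None
        rms_history: list[float] = []
        converged = False
        rank_deficient = False
        for _ in range(self.max_iter):
            current = mov @ linear.T + translation
            if label_pairs is not None:
                pairs = label_pairs
                dists = np.linalg.norm(current[pairs[:, 0]] - fix[pairs[:, 1]], axis=1)
            else:
                all_d = cdist(current, fix)
                nn = np.argmin(all_d, axis=1)  # argmin -> lowest index on ties
                pairs = np.column_stack([np.arange(len(mov)), nn])
                dists = all_d[np.arange(len(mov)), nn]
            keep = np.sort(np.argsort(dists, kind="stable")[:n_keep])
            kept = pairs[keep]

            t = fit_affine(mov, fix, kept)
            rank_deficient = rank_deficient or t.rank_deficient
            linear, translation = t.linear, t.translation
            resid = mov[kept[:, 0]] @ linear.T + translation - fix[kept[:, 1]]
            rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
            rms_history.append(rms)
            if initial_rms is None:
                initial_rms = float(np.sqrt(np.mean(dists[keep] ** 2)))
            if initial_rms > 0 and rms > 10 * initial_rms:
                raise RegistrationError(
                    f"registration failed: RMS {rms:.3g} mm exceeds 10x initial "
                    f"{initial_rms:.3g} mm"
                )
            if len(rms_history) >= 2 and abs(rms_history[-2] - rms) < self.rms_tol_mm:
                converged = True
                break
            if rms < self.rms_tol_mm:
                converged = True
                break

        self.transform_ = AffineTransform(linear, translation, rank_deficient=rank_deficient)
        self.linear_ = self.transform_.linear
        self.translation_ = self.transform_.translation
        self.rms_history_ = rms_history
        self.n_iter_ = len(rms_history)
        self.converged_ = converged
        self.diagnostics_ = IcpDiagnostics(
            iterations=self.n_iter_,
            rms_history=rms_history,
            converged=converged,
            trimmed_fraction=self.trim_fraction,
        )
        return self

    def transform(self, X):
        """Map points through the fitted affine; accepts arrays or PointSet."""
        if isinstance(X, PointSet):
            return apply_affine(self.transform_, X)
        return self.transform_.apply(X)


def icp_affine_register(
    moving,
    fixed,
    max_iter: int = 100,
    rms_tol_mm: float = 1e-6,
    trim_fraction: float = 0.1,
    use_labels: bool = False,
) -> tuple[AffineTransform, IcpDiagnostics]:
    """Functional wrapper around :class:`AffineICP`."""
    est = AffineICP(
        max_iter=max_iter,
        rms_tol_mm=rms_tol_mm,
        trim_fraction=trim_fraction,
        use_labels=use_labels,
    ).fit(moving, fixed)
    return est.transform_, est.diagnostics_
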