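"""Rigid registration of cyclic-immunofluorescence rounds.

Two registration steps are supported:

* **Round-to-round**: each staining round is aligned to the reference round
  using the DAPI channel, which is re-imaged every round. The default model
  is a subpixel translation estimated by phase cross-correlation (rotation
  between rounds of the same physical section is negligible); an optional
  small-angle rotation search is available.
* **Control points**: the DTA map is aligned to the marker stack by a
  least-squares rigid (rotation + translation) fit to user-supplied point
  pairs, replacing the interactive line-ROI alignment step of the original
  workflow.

Conventions
-----------
A :class:`RigidTransform` maps (row, col) coordinates as
``x' = R(theta) @ x + (dy, dx)`` — rotation about the coordinate origin
followed by translation. :func:`register_rounds` returns the transform whose
``(dy, dx)`` is the measured displacement of the *moving* image relative to
the *reference* (for pure translations: the shift that was physically
applied). To resample the moving image onto the reference frame, apply the
**inverse** (``apply_transform(moving, tf.inverse())``), which is what the
pipeline does. :func:`apply_transform` applies the transform literally to the
image content with bilinear interpolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .dta import ChannelImage

__all__ = [
    "RigidTransform",
    "RegistrationError",
    "register_rounds",
    "register_control_points",
    "apply_transform",
]

#: Registrations whose alignment confidence falls below this are rejected.
DEFAULT_CONFIDENCE_FLOOR = 0.3

#: Upsampling factor for subpixel phase-correlation peaks (0.05 px grid).
_UPSAMPLE = 20


class RegistrationError(RuntimeError):
    """Raised when image alignment fails or is too uncertain to trust."""


def _rotmat(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class RigidTransform:
    """Rigid 2D map ``x' = R(theta) x + (dy, dx)`` on (row, col) coordinates.

    ``score`` in [0, 1] is the alignment confidence: normalized
    cross-correlation for image registration, an RMS-residual-based score for
    control-point fits.
    """

    dy: float
    dx: float
    theta: float = 0.0
    score: float = 1.0

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.dy, self.dx])

    def inverse(self) -> "RigidTransform":
        """Transform undoing this one: ``x = R^-1 (x' - t)``."""
        t = -(_rotmat(-self.theta) @ self.translation)
        return RigidTransform(dy=float(t[0]), dx=float(t[1]), theta=-self.theta, score=self.score)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        t = self.translation + _rotmat(self.theta) @ other.translation
        return RigidTransform(
            dy=float(t[0]),
            dx=float(t[1]),
            theta=self.theta + other.theta,
            score=min(self.score, other.score),
        )

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Apply the map to an (n, 2) array of (row, col) points."""
        pts = np.asarray(points, dtype=float)
        return pts @ _rotmat(self.theta).T + self.translation

    def is_identity(self, tol: float = 1e-9) -> bool:
        return abs(self.dy) < tol and abs(self.dx) < tol and abs(self.theta) < tol

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        return cls(**json.loads(Path(path).read_text()))


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, ChannelImage) else np.asarray(image, dtype=float)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape images, in [-1, 1]."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _translation_estimate(ref: np.ndarray, mov: np.ndarray) -> np.ndarray:
    """Subpixel displacement of mov relative to ref via phase correlation."""
    shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=_UPSAMPLE)
    # skimage returns the shift that aligns `mov` to `ref`; the displacement
    # of mov relative to ref is its negation.
    return -np.asarray(shift, dtype=float)


def register_rounds(
    reference_dapi: ChannelImage | np.ndarray,
    moving_dapi: ChannelImage | np.ndarray,
    rotation: bool = False,
    max_rotation_deg: float = 5.0,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
) -> RigidTransform:
    """Estimate the displacement of a staining round relative to the reference.

    Phase cross-correlation of the two DAPI images with subpixel peak
    upsampling. With ``rotation=True`` a coarse-to-fine search over small
    angles (within ``±max_rotation_deg``, rotation taken about the image
    center) is wrapped around the translation estimate, scoring each
    candidate by normalized cross-correlation of the aligned pair.

    Returns the transform describing where the moving image sits relative to
    the reference; align with ``apply_transform(moving, tf.inverse())``.

    Raises
    ------
    RegistrationError
        If the post-alignment correlation falls below ``confidence_floor``
        (e.g. structureless/noise images), flagging the round as failed.
    """
    ref = _pixels(reference_dapi)
    mov = _pixels(moving_dapi)
    if ref.shape != mov.shape:
        raise ValueError(f"image shapes differ: {ref.shape} vs {mov.shape}")
    center = (np.asarray(ref.shape, dtype=float) - 1) / 2.0

    def score_candidate(theta: float):
        if theta:
            mov_r = ndi.rotate(
                mov, -np.degrees(theta), reshape=False, order=1, mode="constant", cval=0.0
            )
        else:
            mov_r = mov
        s = _translation_estimate(ref, mov_r)
        aligned = ndi.shift(mov_r, -s, order=1, mode="constant", cval=0.0)
        return s, theta, _ncc(ref, aligned)

    if rotation:
        span = math.radians(max_rotation_deg)
        thetas = np.linspace(-span, span, 11)
        best = None
        for _ in range(3):  # coarse-to-fine
            cands = [score_candidate(float(t)) for t in thetas]
            best = max(cands, key=lambda c: c[2])
            step = float(thetas[1] - thetas[0])
            thetas = np.linspace(best[1] - step, best[1] + step, 7)
        s, theta, score = best
        # moving = rotate-about-center(base, theta) then shift: express as an
        # origin-anchored rigid map t = R s + (I - R) c
        rot = _rotmat(theta)
        t = rot @ s + (np.eye(2) - rot) @ center
    else:
        s, theta, score = score_candidate(0.0)
        t = s

    score01 = max(0.0, score)
    if score01 < confidence_floor:
        raise RegistrationError(
            f"registration confidence {score01:.3f} below floor {confidence_floor:.3f}; "
            "round flagged as failed"
        )
    return RigidTransform(dy=float(t[0]), dx=float(t[1]), theta=theta, score=score01)


def register_control_points(point_pairs) -> RigidTransform:
    """Least-squares rigid fit (rotation + translation) to point pairs.

    ``point_pairs`` is a sequence of ``(fixed_yx, moving_yx)`` pairs in
    (row, col) coordinates. Solves the 2D orthogonal Procrustes problem (SVD
    of the cross-covariance, reflections excluded): the returned transform
    maps moving points onto fixed points, so applying it to the moving image
    aligns it with the fixed frame. ``score = 1 / (1 + RMS residual)``.

    Raises
    ------
    ValueError
        With fewer than 2 pairs or all points coincident.
    """
    pairs = list(point_pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 control-point pairs")
    fixed = np.asarray([p[0] for p in pairs], dtype=float)
    moving = np.asarray([p[1] for p in pairs], dtype=float)
    if fixed.shape != moving.shape or fixed.shape[1] != 2:
        raise ValueError("point pairs must be (fixed_yx, moving_yx) 2-vectors")
    if np.allclose(moving, moving[0]) or np.allclose(fixed, fixed[0]):
        raise ValueError("control points are coincident; transform underdetermined")

    mu_f = fixed.mean(axis=0)
    mu_m = moving.mean(axis=0)
    h = (moving - mu_m).T @ (fixed - mu_f)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, d]) @ u.T
    theta = math.atan2(rot[1, 0], rot[0, 0])
    t = mu_f - rot @ mu_m

    residuals = fixed - (moving @ rot.T + t)
    rms = float(np.sqrt((residuals**2).sum(axis=1).mean()))
    return RigidTransform(dy=float(t[0]), dx=float(t[1]), theta=theta, score=1.0 / (1.0 + rms))


def apply_transform(
    image: ChannelImage | np.ndarray,
    transform: RigidTransform,
    return_valid: bool = False,
):
    """Resample an image under a rigid transform (bilinear interpolation).

    Image content at coordinate x is moved to ``R x + t``. Out-of-field
    pixels are filled with 0; with ``return_valid=True`` a boolean mask of
    in-field pixels is also returned.
    """
    img = _pixels(image)
    if transform.is_identity():
        out = img.copy()
        return (out, np.ones(img.shape, dtype=bool)) if return_valid else out

    inv_rot = _rotmat(-transform.theta)
    offset = -(inv_rot @ transform.translation)
    out = ndi.affine_transform(img, inv_rot, offset=offset, order=1, mode="constant", cval=0.0)
    if not return_valid:
        return out
    ones = np.ones(img.shape, dtype=float)
    valid = (
        ndi.affine_transform(ones, inv_rot, offset=offset, order=1, mode="constant", cval=0.0)
        > 0.999
    )
    return out, valid
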