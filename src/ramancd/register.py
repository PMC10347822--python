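"""Landmark-based registration of Raman maps onto high-resolution micrographs.

Chemical maps rarely share enough texture with an ion- or electron-
microscope image for intensity-based registration, so the transform is
estimated from manually matched landmark pairs on a structure-rich map
(typically the C-H band image, which resembles the root outline).  Linked
registration then applies the *identical* transform to every chemical map
acquired on the same pixel grid (CD%, lignin), so maps too faint to carry
landmarks inherit the registration of the structural one.

Coordinates are (x, y) pixel coordinates of each image (x = column,
y = row); the transform absorbs the scale difference between modalities, so
no metadata-based pre-scaling is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

from .exceptions import (
    CollinearLandmarksError,
    InsufficientLandmarksError,
    NonInvertibleTransformError,
    ShapeMismatchError,
    ValidationError,
)

__all__ = [
    "AffineTransform",
    "fit_landmark_transform",
    "apply_transform",
    "RegisteredSet",
    "linked_register",
]

_MIN_PAIRS = {"affine": 3, "similarity": 3, "projective": 4}
_SK_MODEL = {
    "affine": sktransform.AffineTransform,
    "similarity": sktransform.SimilarityTransform,
    "projective": sktransform.ProjectiveTransform,
}


@dataclass(frozen=True)
class AffineTransform:
    """2-D point transform moving (x, y) -> target (x, y).

    Stored as a homogeneous 3x3 matrix; for the affine and similarity
    models the last row is (0, 0, 1) and :attr:`matrix_2x3` exposes the
    conventional 2x3 coefficient block.  ``rms_residual`` is the RMS
    landmark misfit in target pixels.
    """

    matrix: np.ndarray
    model: str = "affine"
    n_landmarks: int = 0
    rms_residual: float = 0.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValidationError("transform matrix must be 3x3 homogeneous")
        if not np.all(np.isfinite(m)):
            raise ValidationError("transform matrix must be finite")
        if abs(np.linalg.det(m[:2, :2])) < 1e-12:
            raise NonInvertibleTransformError("transform is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def matrix_2x3(self) -> np.ndarray:
        return self.matrix[:2, :]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(
            np.linalg.inv(self.matrix), self.model, self.n_landmarks, self.rms_residual
        )


def _split_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim == 3 and arr.shape[1:] == (2, 2):  # ((mx,my),(tx,ty)) tuples
        return arr[:, 0, :], arr[:, 1, :]
    if arr.ndim == 2 and arr.shape[1] == 4:  # moving_x, moving_y, target_x, target_y
        return arr[:, :2], arr[:, 2:]
    raise ValidationError("landmark pairs must be (N, 4) or N x ((mx,my),(tx,ty))")


def fit_landmark_transform(pairs, model: str = "affine") -> AffineTransform:
    """Least-squares transform from matched landmark pairs.

    ``model`` is 'affine' (default, 6 dof), 'similarity' or 'projective'.
    Raises :class:`InsufficientLandmarksError` for too few pairs and
    :class:`CollinearLandmarksError` for rank-deficient configurations.
    """
    if model not in _SK_MODEL:
        raise ValidationError(f"unknown model {model!r}")
    moving, target = _split_pairs(pairs)
    n = len(moving)
    if n < _MIN_PAIRS[model]:
        raise InsufficientLandmarksError(
            f"{model} needs >= {_MIN_PAIRS[model]} landmark pairs, got {n}"
        )
    for pts, name in ((moving, "moving"), (target, "target")):
        centered = pts - pts.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[-1] < 1e-9 * max(1.0, sv[0]):
            raise CollinearLandmarksError(f"{name} landmarks are collinear")
    tf = _SK_MODEL[model].from_estimate(moving, target)
    if not tf:
        raise CollinearLandmarksError("transform estimation failed (degenerate set)")
    resid = np.sqrt(np.mean(np.sum((tf(moving) - target) ** 2, axis=1)))
    return AffineTransform(
        matrix=np.asarray(tf.params, dtype=float),
        model=model,
        n_landmarks=n,
        rms_residual=float(resid),
    )


def apply_transform(
    image: np.ndarray,
    transform: AffineTransform,
    target_shape: tuple[int, int],
    interpolation: str = "bilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Warp an image onto the target grid through the landmark transform.

    Returns ``(warped, defined)``: the resampled image as floats with NaN on
    out-of-footprint pixels, and the boolean footprint.  Use bilinear
    interpolation for intensity or CD% images and nearest for masks (nearest
    never invents intermediate values, so a {0, 1} mask stays binary).
    """
    orders = {"bilinear": 1, "nearest": 0}
    if interpolation not in orders:
        raise ValidationError("interpolation must be 'bilinear' or 'nearest'")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("only 2-D grayscale images can be warped")
    sk = sktransform.ProjectiveTransform(matrix=transform.matrix)
    warped = sktransform.warp(
        img,
        inverse_map=sk.inverse,
        output_shape=tuple(target_shape),
        order=orders[interpolation],
        cval=np.nan,
        mode="constant",
        preserve_range=True,
    )
    defined = np.isfinite(warped)
    return warped, defined


@dataclass
class RegisteredSet:
    """Result of linked registration: one fitted transform, the warped
    structure image and the warped chemical images (same coefficients)."""

    transform: AffineTransform
    structure: np.ndarray
    chemicals: list
    defined: np.ndarray


def linked_register(
    structure_image: np.ndarray,
    chemical_images,
    landmarks,
    target_shape: tuple[int, int],
    model: str = "affine",
    chemical_interpolations=None,
) -> RegisteredSet:
    """Register the structure image by landmarks; reuse the transform for
    every linked chemical image.

    All chemical images must share the structure image's pixel grid -- the
    linkage contract is that one transform object is applied unchanged to
    all of them.  ``chemical_interpolations`` defaults to bilinear for every
    image; pass 'nearest' for masks.
    """
    structure_image = np.asarray(structure_image)
    chemical_images = list(chemical_images)
    for img in chemical_images:
        if np.asarray(img).shape != structure_image.shape:
            raise ShapeMismatchError(
                "chemical images must share the structure image grid"
            )
    tf = fit_landmark_transform(landmarks, model=model)
    structure_w, defined = apply_transform(structure_image, tf, target_shape, "bilinear")
    if chemical_interpolations is None:
        chemical_interpolations = ["bilinear"] * len(chemical_images)
    warped = [
        apply_transform(img, tf, target_shape, interp)[0]
        for img, interp in zip(chemical_images, chemical_interpolations)
    ]
    return RegisteredSet(transform=tf, structure=structure_w, chemicals=warped, defined=defined)
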