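"""Landmark-based frontal-plane lower-limb alignment geometry.

All angles are computed in a *limb-local* frame in which +x points medially
(for that limb) and +y points superiorly.  In this frame the clinical sign
convention is side-independent: a straight limb measures exactly 180°, values
below 180° denote varus (bow-legged, knee apex lateral) and values above 180°
denote valgus (knock-kneed, knee apex medial).

Two measurement modalities are supported:

photograph
    Skin-surface landmarks: the anterior superior iliac spine (ASIS), the
    medial/lateral femoral condyle borders and the medial/lateral malleoli.
    The femoral topographic axis (pFTA) runs from the ASIS to the knee centre
    (condyle midpoint); the tibial topographic axis (TTA) runs from the knee
    centre to the ankle centre (malleolar midpoint).  Their medial angle is
    the pelvis-knee-ankle angle (PKA).

radiograph
    Bony landmarks: ASIS, femoral head centre, femoral notch centre, tibial
    intercondylar eminence centre and ankle articular-surface centre.  The
    femoral mechanical axis (FMA) runs head→notch, the tibial mechanical axis
    (TMA) eminence→ankle; their medial angle is the hip-knee-ankle angle
    (HKA).  The radiographic femoral topographic axis (rFTA) runs ASIS→notch;
    its unsigned angle to the FMA (the FMA-FTA angle) quantifies the fixed
    offset between topographic and mechanical femoral axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "Point2D",
    "LimbAnnotation",
    "AngleResult",
    "PHOTOGRAPH_LANDMARKS",
    "RADIOGRAPH_LANDMARKS",
    "LandmarkError",
    "to_limb_frame",
    "to_image_frame",
    "midpoint",
    "signed_axis_angle",
    "pka_angle",
    "hka_angle",
    "fma_fta_angle",
    "classify_alignment",
]

#: Landmarks that must be digitized on a photograph.
PHOTOGRAPH_LANDMARKS = frozenset(
    {"ASIS", "MED_CONDYLE", "LAT_CONDYLE", "MED_MALLEOLUS", "LAT_MALLEOLUS"}
)

#: Landmarks that must be digitized on a radiograph.
RADIOGRAPH_LANDMARKS = frozenset(
    {
        "ASIS",
        "FEMORAL_HEAD_CENTER",
        "FEMORAL_NOTCH_CENTER",
        "TIBIAL_EMINENCE_CENTER",
        "ANKLE_ARTICULAR_CENTER",
    }
)

_REQUIRED = {"photograph": PHOTOGRAPH_LANDMARKS, "radiograph": RADIOGRAPH_LANDMARKS}
_SIDES = ("left", "right")


class LandmarkError(ValueError):
    """A landmark set is incomplete, degenerate or otherwise unusable."""


@dataclass(frozen=True)
class Point2D:
    """A 2-D landmark position in millimetres (limb-local frame)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates: ({self.x}, {self.y})")

    def __sub__(self, other: "Point2D") -> "Point2D":
        return Point2D(self.x - other.x, self.y - other.y)

    def __add__(self, other: "Point2D") -> "Point2D":
        return Point2D(self.x + other.x, self.y + other.y)


@dataclass(frozen=True)
class LimbAnnotation:
    """Digitized landmarks for one limb in one modality.

    Landmark coordinates are expected in the limb-local frame (+x medial,
    +y superior), in millimetres; use :func:`to_limb_frame` to convert raw
    image coordinates.  ``scale_mm_per_px`` records the digitization scale
    (1.0 if coordinates are already metric).
    """

    side: str
    modality: str
    landmarks: Mapping[str, Point2D]
    scale_mm_per_px: float = 1.0

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise ValueError(f"unknown side {self.side!r}; expected one of {_SIDES}")
        if self.modality not in _REQUIRED:
            raise ValueError(
                f"unknown modality {self.modality!r}; expected 'photograph' or 'radiograph'"
            )
        if self.scale_mm_per_px <= 0:
            raise ValueError(f"scale_mm_per_px must be positive, got {self.scale_mm_per_px}")
        missing = _REQUIRED[self.modality] - set(self.landmarks)
        if missing:
            raise LandmarkError(
                f"{self.modality} annotation missing landmark(s): {', '.join(sorted(missing))}"
            )
        req = sorted(_REQUIRED[self.modality])
        for i, a in enumerate(req):
            for b in req[i + 1 :]:
                pa, pb = self.landmarks[a], self.landmarks[b]
                if pa.x == pb.x and pa.y == pb.y:
                    raise LandmarkError(f"landmarks {a} and {b} coincide at ({pa.x}, {pa.y})")

    def __getitem__(self, name: str) -> Point2D:
        try:
            return self.landmarks[name]
        except KeyError:
            raise LandmarkError(f"missing landmark {name!r}") from None


@dataclass(frozen=True)
class AngleResult:
    """An alignment angle in degrees.

    For ``kind`` PKA or HKA the value lies in (90, 270) with <180° = varus,
    >180° = valgus.  For ``kind`` FMA_FTA the value is the unsigned
    inter-axis angle in [0, 90).
    """

    value: float
    kind: str
    side: str

    _KINDS = ("PKA", "HKA", "FMA_FTA")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown angle kind {self.kind!r}")
        if self.side not in _SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.kind == "FMA_FTA":
            if not (0.0 <= self.value < 90.0):
                raise ValueError(f"FMA_FTA angle must lie in [0, 90), got {self.value}")
        elif not (90.0 < self.value < 270.0):
            raise ValueError(f"{self.kind} angle must lie in (90, 270), got {self.value}")


def to_limb_frame(
    points: Iterable[Point2D], side: str, scale_mm_per_px: float
) -> list[Point2D]:
    """Convert raw image coordinates to the limb-local frame.

    The image frame is the standard raster convention (x right, y down) of an
    anterior-view picture, the subject facing the camera.  For a right limb
    the medial direction is image-right, so x is preserved and y negated; for
    a left limb x is additionally negated.  Coordinates are scaled uniformly
    by ``scale_mm_per_px``.
    """
    if scale_mm_per_px <= 0:
        raise ValueError(f"scale_mm_per_px must be positive, got {scale_mm_per_px}")
    if side not in _SIDES:
        raise ValueError(f"unknown side {side!r}")
    sx = scale_mm_per_px if side == "right" else -scale_mm_per_px
    return [Point2D(sx * p.x, -scale_mm_per_px * p.y) for p in points]


def to_image_frame(
    points: Iterable[Point2D], side: str, scale_mm_per_px: float
) -> list[Point2D]:
    """Inverse of :func:`to_limb_frame` (limb-local mm → image pixels)."""
    if scale_mm_per_px <= 0:
        raise ValueError(f"scale_mm_per_px must be positive, got {scale_mm_per_px}")
    if side not in _SIDES:
        raise ValueError(f"unknown side {side!r}")
    sx = 1.0 if side == "right" else -1.0
    return [Point2D(sx * p.x / scale_mm_per_px, -p.y / scale_mm_per_px) for p in points]


def midpoint(a: Point2D, b: Point2D) -> Point2D:
    """Arithmetic midpoint of two distinct landmarks."""
    if a.x == b.x and a.y == b.y:
        raise LandmarkError(f"cannot take midpoint of coincident points ({a.x}, {a.y})")
    return Point2D(0.5 * (a.x + b.x), 0.5 * (a.y + b.y))


def signed_axis_angle(d_prox: Point2D, d_dist: Point2D) -> float:
    """Signed CCW rotation (degrees, in (-180, 180]) from proximal to distal axis.

    Computed via atan2 of the 2-D cross and dot products, which is numerically
    stable for near-parallel axes.
    """
    if d_prox.x == 0.0 and d_prox.y == 0.0:
        raise ValueError("proximal axis direction has zero length")
    if d_dist.x == 0.0 and d_dist.y == 0.0:
        raise ValueError("distal axis direction has zero length")
    cross = d_prox.x * d_dist.y - d_prox.y * d_dist.x
    dot = d_prox.x * d_dist.x + d_prox.y * d_dist.y
    return math.degrees(math.atan2(cross, dot))


def pka_angle(ann: LimbAnnotation) -> AngleResult:
    """Pelvis-knee-ankle angle from a photographic annotation.

    The knee centre is the condyle midpoint, the ankle centre the malleolar
    midpoint; PKA = 180° − ψ where ψ is the signed rotation from the pFTA
    (ASIS→knee) onto the TTA (knee→ankle) in the limb-local frame.  A
    laterally displaced knee apex (varus) gives PKA < 180°.
    """
    if ann.modality != "photograph":
        raise ValueError(f"pka_angle requires a photograph annotation, got {ann.modality!r}")
    knee = midpoint(ann["MED_CONDYLE"], ann["LAT_CONDYLE"])
    ankle = midpoint(ann["MED_MALLEOLUS"], ann["LAT_MALLEOLUS"])
    if knee.x == ankle.x and knee.y == ankle.y:
        raise LandmarkError("degenerate annotation: knee and ankle centres coincide")
    psi = signed_axis_angle(knee - ann["ASIS"], ankle - knee)
    return AngleResult(value=180.0 - psi, kind="PKA", side=ann.side)


def hka_angle(ann: LimbAnnotation) -> AngleResult:
    """Hip-knee-ankle angle from a radiographic annotation.

    HKA = 180° − ψ where ψ is the signed rotation from the FMA (femoral head
    →notch) onto the TMA (tibial eminence→ankle centre); varus ⇒ < 180°.
    """
    if ann.modality != "radiograph":
        raise ValueError(f"hka_angle requires a radiograph annotation, got {ann.modality!r}")
    fma = ann["FEMORAL_NOTCH_CENTER"] - ann["FEMORAL_HEAD_CENTER"]
    tma = ann["ANKLE_ARTICULAR_CENTER"] - ann["TIBIAL_EMINENCE_CENTER"]
    psi = signed_axis_angle(fma, tma)
    return AngleResult(value=180.0 - psi, kind="HKA", side=ann.side)


def fma_fta_angle(ann: LimbAnnotation) -> AngleResult:
    """Unsigned angle between the femoral mechanical and topographic axes.

    The rFTA runs from the ASIS to the femoral notch centre; the result lies
    in [0, 90) (only the magnitude of the axis offset is clinically reported).
    """
    if ann.modality != "radiograph":
        raise ValueError(
            f"fma_fta_angle requires a radiograph annotation, got {ann.modality!r}"
        )
    fma = ann["FEMORAL_NOTCH_CENTER"] - ann["FEMORAL_HEAD_CENTER"]
    rfta = ann["FEMORAL_NOTCH_CENTER"] - ann["ASIS"]
    psi = abs(signed_axis_angle(fma, rfta))
    return AngleResult(value=psi, kind="FMA_FTA", side=ann.side)


def classify_alignment(angle: AngleResult, tolerance: float = 0.0) -> str:
    """Classify a PKA/HKA angle as ``varus``, ``neutral`` or ``valgus``.

    ``tolerance`` widens the neutral band to 180° ± tolerance; the default is
    exact equality (no established neutral band exists for these angles).
    """
    if angle.kind == "FMA_FTA":
        raise ValueError("FMA_FTA is an unsigned inter-axis angle; it has no varus/valgus sign")
    if tolerance < 0:
        raise ValueError(f"tolerance must be non-negative, got {tolerance}")
    if angle.value < 180.0 - tolerance:
        return "varus"
    if angle.value > 180.0 + tolerance:
        return "valgus"
    return "neutral"
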