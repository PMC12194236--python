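"""PKA → HKA calibration.

The photographic pelvis-knee-ankle angle (PKA) runs consistently more valgus
than the radiographic hip-knee-ankle angle (HKA), because the topographic
femoral axis (from the anterior superior iliac spine) sits lateral to the
mechanical axis (from the femoral head centre).  The offset is stable enough
across subjects that a single linear map converts a photographic PKA into an
estimated radiographic HKA.

A published calibration, fitted on 33 limbs of 17 orthopedic patients by one
rater,

    HKA = −10.54 + 1.0364 · PKA      (SEE 1.2427°)

ships as :data:`PUBLISHED_MODEL` so that users without radiographs can
estimate HKA directly.  :func:`fit_calibration` refits the same model on new
paired data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .agreement import ols_fit

__all__ = [
    "CalibrationModel",
    "CalibrationEstimate",
    "PUBLISHED_MODEL",
    "fit_calibration",
    "apply_calibration",
]

#: PKA values outside this range are flagged as extrapolation.
_PKA_RANGE = (90.0, 270.0)


@dataclass(frozen=True)
class CalibrationModel:
    """Linear PKA→HKA mapping with fit diagnostics.

    ``see`` is the standard error of the estimate (residual SD, degrees);
    ``source`` is ``"published"`` for the packaged default or ``"fitted"``
    for a model estimated from data (``n_fit`` pairs; 0 if published).
    """

    intercept: float
    slope: float
    see: float
    source: str
    n_fit: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(
                f"calibration slope must be positive (orientation-preserving), got {self.slope}"
            )
        if self.source not in ("published", "fitted"):
            raise ValueError(f"unknown model source {self.source!r}")
        if self.see < 0:
            raise ValueError(f"SEE must be non-negative, got {self.see}")

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "see": self.see,
            "source": self.source,
            "n_fit": self.n_fit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            intercept=float(d["intercept"]),
            slope=float(d["slope"]),
            see=float(d["see"]),
            source=str(d.get("source", "fitted")),
            n_fit=int(d.get("n_fit", 0)),
        )


@dataclass(frozen=True)
class CalibrationEstimate:
    """A single estimated HKA with the model's residual SD and an extrapolation flag."""

    hka: float
    see: float
    extrapolated: bool


#: Calibration fitted on the original accuracy cohort (33 limbs, one rater).
PUBLISHED_MODEL = CalibrationModel(
    intercept=-10.54, slope=1.0364, see=1.2427, source="published", n_fit=0
)

#: Provenance of the packaged default, for report metadata.
PUBLISHED_PROVENANCE = {
    "cohort": "17 orthopedic patients, 33 limbs, single rater",
    "r2": 0.936,
}


def fit_calibration(pka: Sequence[float], hka: Sequence[float]) -> CalibrationModel:
    """Fit HKA = a + b·PKA by ordinary least squares on paired measurements."""
    res = ols_fit(pka, hka)
    return CalibrationModel(
        intercept=res.intercept,
        slope=res.slope,
        see=res.see,
        source="fitted",
        n_fit=res.n,
    )


def apply_calibration(model: CalibrationModel, pka: float) -> CalibrationEstimate:
    """Estimate HKA for one photographic PKA value.

    PKA values outside the anatomically plausible (90°, 270°) window are still
    evaluated but returned with ``extrapolated=True``.
    """
    extrapolated = not (_PKA_RANGE[0] < pka < _PKA_RANGE[1])
    return CalibrationEstimate(
        hka=model.intercept + model.slope * pka,
        see=model.see,
        extrapolated=extrapolated,
    )
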