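"""Synthetic cohorts of limbs, photographs and raters.

No public dataset of digitized limb landmarks exists for this measurement
problem, so validation runs on simulated cohorts with *known* true alignment.
The generator builds, for each limb, a 2-D skeleton in the limb-local frame
(+x medial, +y superior):

* a femoral mechanical axis from the femoral head centre down to the femoral
  notch centre (length ``femur_len_mm``);
* a tibial mechanical axis rotated so the noise-free HKA equals the drawn
  ``true_hka`` (HKA ~ Normal(true_hka_mean, true_hka_sd));
* an ASIS placed so the femoral topographic axis (ASIS→notch) makes a drawn
  FMA–FTA angle with the mechanical axis (Normal, truncated at 0);
* photographic surrogate landmarks (condyles, malleoli) placed so the
  noise-free PKA equals ``true_hka + fma_fta + ankle_center_offset`` — the
  additive construction implied by a near-unit empirical PKA→HKA slope with a
  near-constant offset.

Measurement variability enters at the landmark level, in millimetres, so it
propagates to angles through the very geometry code under test:

* per-marking isotropic noise (``landmark_noise_sd_mm``), independent per
  digitization;
* a per-rater systematic shift of each landmark (``rater_bias_sd_mm``), fixed
  for a given rater across subjects and sessions;
* a per-photograph stance/repositioning perturbation (``session_sd_deg``)
  modelled as a rotation of the tibial segment about the knee centre, shared
  by every rater and reading of that photograph.

Randomness is a single seed fanned out into hierarchical substreams
(subject → session → rater → marking), so e.g. adding raters does not
perturb the subject draws; identical seed and config give bit-identical
datasets.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator

import numpy as np
import pandas as pd

from .geometry import (
    LimbAnnotation,
    Point2D,
    fma_fta_angle,
    hka_angle,
    midpoint,
    pka_angle,
    to_image_frame,
)
from .agreement import RatingsMatrix

__all__ = [
    "SimulationConfig",
    "TrueLimb",
    "ReliabilityData",
    "generate_subject",
    "render_annotations",
    "generate_accuracy_dataset",
    "generate_reliability_dataset",
    "accuracy_landmark_table",
    "reliability_landmark_table",
]

# Fixed skeleton constants (mm): half-widths of the condyle and malleolar
# marker pairs, the eminence's distal offset from the notch along the tibial
# axis, and the ASIS's extra distance above the notch beyond femur length.
_CONDYLE_HALFWIDTH = 45.0
_MALLEOLUS_HALFWIDTH = 30.0
_EMINENCE_OFFSET = 8.0
_ASIS_EXTRA = 80.0


@dataclass(frozen=True)
class SimulationConfig:
    """All distributional parameters of a synthetic cohort, plus the seed.

    Angle parameters are degrees, lengths and landmark noise millimetres.
    ``ankle_center_offset_*`` is the extra photographic-minus-radiographic
    axis discrepancy beyond the FMA–FTA angle (the photographic ankle centre
    is a skin-surface surrogate of the articular centre).
    """

    n_subjects: int = 17
    group: str = "orthopedic"
    true_hka_mean: float = 178.8
    true_hka_sd: float = 5.2
    fma_fta_mean: float = 3.1
    fma_fta_sd: float = 1.0
    ankle_center_offset_mean: float = 0.8
    ankle_center_offset_sd: float = 0.3
    femur_len_mm: float = 420.0
    tibia_len_mm: float = 380.0
    landmark_noise_sd_mm: float = 1.0
    rater_bias_sd_mm: float = 1.0
    session_sd_deg: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError(f"need at least 3 subjects, got {self.n_subjects}")
        if self.group not in ("orthopedic", "healthy"):
            raise ValueError(f"unknown group {self.group!r}")
        for name in (
            "true_hka_sd",
            "fma_fta_sd",
            "ankle_center_offset_sd",
            "landmark_noise_sd_mm",
            "rater_bias_sd_mm",
            "session_sd_deg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        for name in ("femur_len_mm", "tibia_len_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @classmethod
    def orthopedic(cls, **overrides) -> "SimulationConfig":
        """Patient-group defaults (accuracy study): HKA 178.8° ± 5.2°."""
        return cls(**{"n_subjects": 17, "group": "orthopedic", **overrides})

    @classmethod
    def healthy(cls, **overrides) -> "SimulationConfig":
        """Healthy-group defaults (reliability study), targeting PKA 182.6° ± 2.5°.

        The true-HKA parameters are solved from the additive construction:
        mean 182.6 − 3.1 − 0.8 and variance 2.5² − 1.0² − 0.3².
        """
        base = {
            "n_subjects": 50,
            "group": "healthy",
            "true_hka_mean": 182.6 - 3.1 - 0.8,
            "true_hka_sd": math.sqrt(2.5**2 - 1.0**2 - 0.3**2),
        }
        return cls(**{**base, **overrides})

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        group = d.get("group", "orthopedic")
        base = cls.healthy() if group == "healthy" else cls.orthopedic()
        return replace(base, **d)


@dataclass(frozen=True)
class TrueLimb:
    """Ground-truth skeleton for one limb: true angles and noise-free landmarks."""

    subject_index: int
    side: str
    true_hka: float
    true_fma_fta: float
    ankle_center_offset: float
    radiograph_landmarks: dict = field(default_factory=dict)
    photograph_landmarks: dict = field(default_factory=dict)

    @property
    def true_pka(self) -> float:
        return self.true_hka + self.true_fma_fta + self.ankle_center_offset


def _substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator for a hierarchical key path."""
    ints = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            ints.append(int(k) & 0xFFFFFFFF)
        else:
            ints.append(zlib.crc32(str(k).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *ints]))


def _unit(angle_deg: float) -> np.ndarray:
    """Unit vector pointing distally, rotated ``angle_deg`` CCW from straight down."""
    a = math.radians(angle_deg)
    return np.array([math.sin(a), -math.cos(a)])


def generate_subject(
    cfg: SimulationConfig, rng: np.random.Generator, subject_index: int = 0, side: str = "right"
) -> TrueLimb:
    """Draw one limb's true alignment and build its noise-free skeleton.

    The FMA–FTA draw is truncated at 0 by rejection (the offset is an
    unsigned inter-axis angle); all other draws are plain normals.
    """
    true_hka = float(rng.normal(cfg.true_hka_mean, cfg.true_hka_sd))
    fma_fta = float(rng.normal(cfg.fma_fta_mean, cfg.fma_fta_sd))
    while fma_fta < 0.0:
        fma_fta = float(rng.normal(cfg.fma_fta_mean, cfg.fma_fta_sd))
    offset = float(rng.normal(cfg.ankle_center_offset_mean, cfg.ankle_center_offset_sd))

    lt, lf = cfg.tibia_len_mm, cfg.femur_len_mm
    delta = 180.0 - true_hka  # varus deviation, positive = varus

    notch = np.array([0.0, lt])
    head = np.array([0.0, lt + lf])
    tib_dir = _unit(delta)
    eminence = notch + _EMINENCE_OFFSET * tib_dir
    ankle_rad = notch + lt * tib_dir
    # ASIS above the femoral head along the topographic axis through the notch
    asis = notch - (lf + _ASIS_EXTRA) * _unit(fma_fta)

    radiograph = {
        "ASIS": Point2D(*asis),
        "FEMORAL_HEAD_CENTER": Point2D(*head),
        "FEMORAL_NOTCH_CENTER": Point2D(*notch),
        "TIBIAL_EMINENCE_CENTER": Point2D(*eminence),
        "ANKLE_ARTICULAR_CENTER": Point2D(*ankle_rad),
    }

    # photographic knee centre coincides with the notch; the surrogate ankle
    # centre is rotated an extra `offset` degrees valgus-ward
    knee = notch
    ankle_photo = knee + lt * _unit(delta - offset)
    photograph = {
        "ASIS": Point2D(*asis),
        "MED_CONDYLE": Point2D(knee[0] + _CONDYLE_HALFWIDTH, knee[1]),
        "LAT_CONDYLE": Point2D(knee[0] - _CONDYLE_HALFWIDTH, knee[1]),
        "MED_MALLEOLUS": Point2D(ankle_photo[0] + _MALLEOLUS_HALFWIDTH, ankle_photo[1]),
        "LAT_MALLEOLUS": Point2D(ankle_photo[0] - _MALLEOLUS_HALFWIDTH, ankle_photo[1]),
    }

    return TrueLimb(
        subject_index=subject_index,
        side=side,
        true_hka=true_hka,
        true_fma_fta=fma_fta,
        ankle_center_offset=offset,
        radiograph_landmarks=radiograph,
        photograph_landmarks=photograph,
    )


@lru_cache(maxsize=4096)
def _rater_bias(seed: int, sd: float, rater_id: str, landmark: str) -> tuple[float, float]:
    """Per-rater systematic 2-D shift of one landmark, fixed across the study."""
    if sd == 0.0:
        return (0.0, 0.0)
    g = _substream(seed, "rater-bias", rater_id, landmark)
    dx, dy = g.normal(0.0, sd, size=2)
    return (float(dx), float(dy))


def _session_rotation(cfg: SimulationConfig, limb: TrueLimb, session_id: int) -> float:
    """Stance perturbation (degrees) of one photograph, shared by all raters."""
    if cfg.session_sd_deg == 0.0:
        return 0.0
    g = _substream(cfg.seed, "session", limb.subject_index, limb.side, session_id)
    return float(g.normal(0.0, cfg.session_sd_deg))


def render_annotations(
    limb: TrueLimb,
    modality: str,
    rater_id: str,
    session_id: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> LimbAnnotation:
    """One rater's digitization of one image of one limb.

    For photographs, the session's stance perturbation rotates the malleolar
    landmarks about the knee centre (repositioning changes the projected
    tibial axis, not the pelvis or knee markers).  The per-rater systematic
    shift is deterministic given the config seed; ``rng`` supplies the
    per-marking noise and must be keyed by reading upstream.
    """
    if modality == "photograph":
        marks = dict(limb.photograph_landmarks)
        theta = _session_rotation(cfg, limb, session_id)
        if theta != 0.0:
            knee = midpoint(marks["MED_CONDYLE"], marks["LAT_CONDYLE"])
            c, s = math.cos(math.radians(theta)), math.sin(math.radians(theta))
            for name in ("MED_MALLEOLUS", "LAT_MALLEOLUS"):
                p = marks[name]
                dx, dy = p.x - knee.x, p.y - knee.y
                marks[name] = Point2D(knee.x + c * dx - s * dy, knee.y + s * dx + c * dy)
    elif modality == "radiograph":
        marks = dict(limb.radiograph_landmarks)
    else:
        raise ValueError(f"unknown modality {modality!r}")

    out = {}
    for name in sorted(marks):
        p = marks[name]
        bx, by = _rater_bias(cfg.seed, cfg.rater_bias_sd_mm, rater_id, name)
        nx, ny = (
            rng.normal(0.0, cfg.landmark_noise_sd_mm, size=2)
            if cfg.landmark_noise_sd_mm > 0
            else (0.0, 0.0)
        )
        out[name] = Point2D(p.x + bx + float(nx), p.y + by + float(ny))
    return LimbAnnotation(side=limb.side, modality=modality, landmarks=out)


def _accuracy_limbs(cfg: SimulationConfig, n_limbs: int | None) -> list[tuple[int, str]]:
    if n_limbs is None:
        n_limbs = 2 * cfg.n_subjects - 1  # one subject contributes a single limb
    if not 1 <= n_limbs <= 2 * cfg.n_subjects:
        raise ValueError(
            f"n_limbs must lie in [1, {2 * cfg.n_subjects}] for {cfg.n_subjects} subjects"
        )
    pairs = [(s, side) for s in range(cfg.n_subjects) for side in ("right", "left")]
    return pairs[:n_limbs]


def _iter_accuracy(
    cfg: SimulationConfig, n_limbs: int | None
) -> Iterator[tuple[int, str, TrueLimb, LimbAnnotation, LimbAnnotation]]:
    for s, side in _accuracy_limbs(cfg, n_limbs):
        limb = generate_subject(cfg, _substream(cfg.seed, "subject", s, side), s, side)
        photo = render_annotations(
            limb, "photograph", "R1", 1, cfg,
            _substream(cfg.seed, "mark", s, side, "photograph", "R1", 1, 1),
        )
        radio = render_annotations(
            limb, "radiograph", "R1", 1, cfg,
            _substream(cfg.seed, "mark", s, side, "radiograph", "R1", 1, 1),
        )
        yield s, side, limb, photo, radio


def generate_accuracy_dataset(cfg: SimulationConfig, n_limbs: int | None = None) -> pd.DataFrame:
    """Paired PKA/HKA measurements, one rater, one session, both modalities.

    By default 2·n_subjects − 1 limbs (the study design this emulates lost
    one limb to an external fixator).  Columns include the true angles for
    recovery checks alongside the measured ``pka_deg``/``hka_deg``.
    """
    rows = []
    for s, side, limb, photo, radio in _iter_accuracy(cfg, n_limbs):
        rows.append(
            {
                "subject_id": f"S{s + 1:04d}",
                "limb_side": side,
                "pka_deg": pka_angle(photo).value,
                "hka_deg": hka_angle(radio).value,
                "fma_fta_deg": fma_fta_angle(radio).value,
                "true_hka": limb.true_hka,
                "true_pka": limb.true_pka,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReliabilityData:
    """Reliability-study measurements and the three derived rating designs.

    ``intrarater`` maps rater id → n×2 matrix (readings 1 vs 2 of photo 1);
    ``interrater`` is the n×3 matrix of first readings of photo 1;
    ``test_retest`` is the n×2 matrix of photo 1 vs photo 2, each column the
    mean of the raters' first readings of that photograph.
    """

    long: pd.DataFrame
    intrarater: dict
    interrater: RatingsMatrix
    test_retest: RatingsMatrix


def _iter_reliability(cfg: SimulationConfig, n_raters: int, n_sessions: int, n_readings: int):
    side = "right"  # reliability is reported for the right limb
    for s in range(cfg.n_subjects):
        limb = generate_subject(cfg, _substream(cfg.seed, "subject", s, side), s, side)
        for session in range(1, n_sessions + 1):
            for r in range(1, n_raters + 1):
                rater = f"R{r}"
                for reading in range(1, n_readings + 1):
                    rng = _substream(
                        cfg.seed, "mark", s, side, "photograph", rater, session, reading
                    )
                    ann = render_annotations(limb, "photograph", rater, session, cfg, rng)
                    yield s, limb, session, rater, reading, ann


def generate_reliability_dataset(
    cfg: SimulationConfig, n_raters: int = 3, n_sessions: int = 2, n_readings: int = 2
) -> ReliabilityData:
    """Simulate the three-rater, two-photograph, two-reading reliability study."""
    if n_raters < 2 or n_sessions < 2 or n_readings < 2:
        raise ValueError("reliability design needs ≥2 raters, sessions and readings")
    rows = [
        {
            "subject_id": f"S{s + 1:04d}",
            "limb_side": limb.side,
            "session": session,
            "rater": rater,
            "reading": reading,
            "pka_deg": pka_angle(ann).value,
        }
        for s, limb, session, rater, reading, ann in _iter_reliability(
            cfg, n_raters, n_sessions, n_readings
        )
    ]
    long = pd.DataFrame(rows)
    subjects = tuple(sorted(long["subject_id"].unique()))

    def _pivot(df: pd.DataFrame, col: str) -> np.ndarray:
        wide = df.pivot(index="subject_id", columns=col, values="pka_deg").loc[list(subjects)]
        return wide.to_numpy(), tuple(str(c) for c in wide.columns)

    intrarater = {}
    for r in range(1, n_raters + 1):
        rater = f"R{r}"
        sel = long[(long["rater"] == rater) & (long["session"] == 1)]
        vals, labels = _pivot(sel, "reading")
        intrarater[rater] = RatingsMatrix(
            vals, subject_ids=subjects, measurement_labels=tuple(f"reading{c}" for c in labels)
        )

    first = long[(long["session"] == 1) & (long["reading"] == 1)]
    vals, labels = _pivot(first, "rater")
    interrater = RatingsMatrix(vals, subject_ids=subjects, measurement_labels=labels)

    retest = (
        long[long["reading"] == 1]
        .groupby(["subject_id", "session"], as_index=False)["pka_deg"]
        .mean()
    )
    vals, labels = _pivot(retest, "session")
    test_retest = RatingsMatrix(
        vals, subject_ids=subjects, measurement_labels=tuple(f"photo{c}" for c in labels)
    )
    return ReliabilityData(
        long=long, intrarater=intrarater, interrater=interrater, test_retest=test_retest
    )


def _landmark_rows(
    ann: LimbAnnotation, subject_id: str, session: int, rater: str, scale: float
) -> list[dict]:
    names = sorted(ann.landmarks)
    img = to_image_frame([ann.landmarks[n] for n in names], ann.side, scale)
    return [
        {
            "subject_id": subject_id,
            "limb_side": ann.side,
            "modality": ann.modality,
            "session": session,
            "rater": rater,
            "landmark_name": name,
            "x_px": p.x,
            "y_px": p.y,
            "scale_mm_per_px": scale,
        }
        for name, p in zip(names, img)
    ]


def accuracy_landmark_table(
    cfg: SimulationConfig, n_limbs: int | None = None, scale_mm_per_px: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy-study landmarks in raw image coordinates, plus ground truth.

    Feeding the landmark table through the measurement pipeline reproduces
    :func:`generate_accuracy_dataset` exactly (same random substreams).
    """
    lm_rows: list[dict] = []
    truth_rows: list[dict] = []
    for s, side, limb, photo, radio in _iter_accuracy(cfg, n_limbs):
        sid = f"S{s + 1:04d}"
        lm_rows += _landmark_rows(photo, sid, 1, "R1", scale_mm_per_px)
        lm_rows += _landmark_rows(radio, sid, 1, "R1", scale_mm_per_px)
        truth_rows.append(
            {
                "subject_id": sid,
                "limb_side": side,
                "true_hka": limb.true_hka,
                "true_pka": limb.true_pka,
                "true_fma_fta": limb.true_fma_fta,
                "ankle_center_offset": limb.ankle_center_offset,
            }
        )
    return pd.DataFrame(lm_rows), pd.DataFrame(truth_rows)


def reliability_landmark_table(
    cfg: SimulationConfig,
    n_raters: int = 3,
    n_sessions: int = 2,
    n_readings: int = 2,
    scale_mm_per_px: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reliability-study landmarks in raw image coordinates, plus ground truth.

    The ``session`` column indexes photographs; the reading is appended to the
    rater label (``R1.2`` = rater 1, second reading) so the long landmark
    schema stays the same as for the accuracy study.
    """
    lm_rows: list[dict] = []
    truth: dict[str, dict] = {}
    for s, limb, session, rater, reading, ann in _iter_reliability(
        cfg, n_raters, n_sessions, n_readings
    ):
        sid = f"S{s + 1:04d}"
        lm_rows += _landmark_rows(ann, sid, session, f"{rater}.{reading}", scale_mm_per_px)
        truth.setdefault(
            sid,
            {
                "subject_id": sid,
                "limb_side": limb.side,
                "true_hka": limb.true_hka,
                "true_pka": limb.true_pka,
                "true_fma_fta": limb.true_fma_fta,
                "ankle_center_offset": limb.ankle_center_offset,
            },
        )
    return pd.DataFrame(lm_rows), pd.DataFrame(list(truth.values()))
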