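"""Study orchestration: landmarks → angles → accuracy/reliability reports.

The accuracy study compares photographic PKA against radiographic HKA on
paired limbs (Pearson correlation, HKA~PKA regression, Bland–Altman on
HKA − PKA, group summaries).  The reliability study assesses repeated PKA
ratings in the three standard designs: intrarater (two readings of the first
photograph, per rater), interrater (first readings of the first photograph,
all raters pooled for the ICC, pairwise for Bland–Altman) and test–retest
(first vs second photograph).

Reports retain full precision internally; a ``display`` block applies the
conventional clinical rounding (angles 1 decimal, bias and limits of
agreement 3 decimals, correlations 2 decimals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import (
    BlandAltmanResult,
    ICCResult,
    RatingsMatrix,
    RegressionResult,
    bland_altman,
    icc2k,
    ols_fit,
    pearson_r,
)
from .geometry import (
    LimbAnnotation,
    Point2D,
    classify_alignment,
    fma_fta_angle,
    hka_angle,
    pka_angle,
    to_limb_frame,
)

__all__ = [
    "SCHEMA_VERSION",
    "AccuracyReport",
    "ReliabilityReport",
    "measure_angles",
    "read_landmark_csv",
    "read_ratings_csv",
    "run_accuracy_study",
    "run_reliability_study",
    "pairs_from_angles",
]

SCHEMA_VERSION = "1.0"

log = logging.getLogger("flla")

_LANDMARK_COLUMNS = [
    "subject_id",
    "limb_side",
    "modality",
    "session",
    "rater",
    "landmark_name",
    "x_px",
    "y_px",
    "scale_mm_per_px",
]


def read_landmark_csv(path) -> pd.DataFrame:
    """Read a long-format landmark table, checking the required schema."""
    df = pd.read_csv(path)
    missing = set(_LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing column(s): {', '.join(sorted(missing))}")
    return df


def read_ratings_csv(path) -> RatingsMatrix:
    """Read a wide ratings table: subject_id column, one column per measurement."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("ratings CSV must have a subject_id column")
    before = len(df)
    df = df.dropna()
    if len(df) < before:
        log.warning("ratings CSV: dropped %d incomplete row(s)", before - len(df))
    cols = [c for c in df.columns if c != "subject_id"]
    return RatingsMatrix(
        df[cols].to_numpy(dtype=float),
        subject_ids=tuple(df["subject_id"].astype(str)),
        measurement_labels=tuple(cols),
    )


def measure_angles(landmarks: pd.DataFrame) -> pd.DataFrame:
    """Compute all alignment angles from a long-format landmark table.

    One output row per angle: PKA for photographs, HKA and FMA–FTA for
    radiographs, with the varus/neutral/valgus classification attached
    (FMA–FTA, being unsigned, gets none).
    """
    missing = set(_LANDMARK_COLUMNS) - set(landmarks.columns)
    if missing:
        raise ValueError(f"landmark table missing column(s): {', '.join(sorted(missing))}")
    rows = []
    keys = ["subject_id", "limb_side", "modality", "session", "rater"]
    for (sid, side, modality, session, rater), grp in landmarks.groupby(keys, sort=True):
        scales = grp["scale_mm_per_px"].unique()
        if len(scales) != 1:
            raise ValueError(
                f"inconsistent scale_mm_per_px for {sid}/{side}/{modality}/{session}/{rater}"
            )
        names = list(grp["landmark_name"])
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate landmark rows for {sid}/{side}/{modality}")
        pts_img = [Point2D(x, y) for x, y in zip(grp["x_px"], grp["y_px"])]
        pts = to_limb_frame(pts_img, side, float(scales[0]))
        ann = LimbAnnotation(
            side=side, modality=modality, landmarks=dict(zip(names, pts)),
            scale_mm_per_px=float(scales[0]),
        )
        if modality == "photograph":
            results = [pka_angle(ann)]
        else:
            results = [hka_angle(ann), fma_fta_angle(ann)]
        for res in results:
            rows.append(
                {
                    "subject_id": sid,
                    "limb_side": side,
                    "modality": modality,
                    "session": session,
                    "rater": rater,
                    "angle_kind": res.kind,
                    "value_deg": res.value,
                    "classification": (
                        classify_alignment(res) if res.kind != "FMA_FTA" else ""
                    ),
                }
            )
    return pd.DataFrame(rows)


def pairs_from_angles(angles: pd.DataFrame) -> pd.DataFrame:
    """Pivot a measured-angles table into accuracy pairs (PKA vs HKA per limb)."""
    keys = ["subject_id", "limb_side"]
    wide = (
        angles.pivot_table(index=keys, columns="angle_kind", values="value_deg", aggfunc="first")
        .reset_index()
    )
    for kind, col in (("PKA", "pka_deg"), ("HKA", "hka_deg"), ("FMA_FTA", "fma_fta_deg")):
        if kind in wide.columns:
            wide = wide.rename(columns={kind: col})
    wide.columns.name = None
    return wide


def _summary(values: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def _ba_dict(ba: BlandAltmanResult) -> dict:
    return {
        "bias": ba.bias,
        "sd_diff": ba.sd_diff,
        "loa_low": ba.loa_low,
        "loa_high": ba.loa_high,
        "multiplier": ba.multiplier,
        "n": ba.n,
    }


def _icc_dict(res: ICCResult) -> dict:
    return {
        "estimate": res.estimate,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "confidence": res.confidence,
        "ms_rows": res.ms_rows,
        "ms_cols": res.ms_cols,
        "ms_error": res.ms_error,
        "n": res.n,
        "k": res.k,
        "interpretation": res.interpretation,
    }


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy-study results: correlation, regression, agreement, summaries."""

    n_pairs: int
    pearson_r: float
    pearson_p: float
    regression: RegressionResult
    bland_altman: BlandAltmanResult
    summaries: dict
    normality: Optional[dict] = None

    def to_dict(self) -> dict:
        reg = self.regression
        out = {
            "schema_version": SCHEMA_VERSION,
            "study": "accuracy",
            "n_pairs": self.n_pairs,
            "pearson": {"r": self.pearson_r, "p_value": self.pearson_p},
            "regression": {
                "intercept": reg.intercept,
                "slope": reg.slope,
                "r2": reg.r2,
                "see": reg.see,
                "n": reg.n,
            },
            "bland_altman": _ba_dict(self.bland_altman),
            "summaries": self.summaries,
            "display": {
                "pearson_r": round(self.pearson_r, 2),
                "bias": round(self.bland_altman.bias, 3),
                "loa_low": round(self.bland_altman.loa_low, 3),
                "loa_high": round(self.bland_altman.loa_high, 3),
                "summaries": {
                    k: {kk: round(vv, 1) for kk, vv in v.items()}
                    for k, v in self.summaries.items()
                },
            },
        }
        if self.normality is not None:
            out["normality"] = self.normality
        return out


@dataclass(frozen=True)
class ReliabilityReport:
    """Reliability-study results in the intrarater / interrater / test–retest layout."""

    intrarater: dict
    interrater_icc: ICCResult
    interrater_pairwise_ba: dict
    test_retest_icc: ICCResult
    test_retest_ba: BlandAltmanResult

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "study": "reliability",
            "intrarater": {
                rater: {"icc": _icc_dict(icc), "bland_altman": _ba_dict(ba)}
                for rater, (icc, ba) in self.intrarater.items()
            },
            "interrater": {
                "icc": _icc_dict(self.interrater_icc),
                "pairwise_bland_altman": {
                    pair: _ba_dict(ba) for pair, ba in self.interrater_pairwise_ba.items()
                },
            },
            "test_retest": {
                "icc": _icc_dict(self.test_retest_icc),
                "bland_altman": _ba_dict(self.test_retest_ba),
            },
        }


def run_accuracy_study(pairs: pd.DataFrame, normality: bool = False) -> AccuracyReport:
    """Full accuracy battery on paired PKA/HKA measurements.

    Incomplete pairs are dropped (loudly); fewer than 3 complete pairs is an
    error.  The Bland–Altman differences are oriented HKA − PKA: the
    radiographic angle runs more varus than the photographic one, so the
    topographic offset appears as a negative bias.
    """
    for col in ("pka_deg", "hka_deg"):
        if col not in pairs.columns:
            raise ValueError(f"accuracy table missing column {col!r}")
    complete = pairs.dropna(subset=["pka_deg", "hka_deg"])
    dropped = len(pairs) - len(complete)
    if dropped:
        log.warning("accuracy study: dropped %d incomplete pair(s)", dropped)
    if len(complete) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(complete)}")

    pka = complete["pka_deg"].to_numpy(dtype=float)
    hka = complete["hka_deg"].to_numpy(dtype=float)
    r, p = pearson_r(pka, hka)
    reg = ols_fit(pka, hka)  # HKA as response, PKA as predictor
    ba = bland_altman(hka, pka)

    summaries = {"pka": _summary(pka), "hka": _summary(hka)}
    if "fma_fta_deg" in complete.columns and complete["fma_fta_deg"].notna().all():
        summaries["fma_fta"] = _summary(complete["fma_fta_deg"].to_numpy(dtype=float))

    norm = None
    if normality:
        norm = {
            name: {"statistic": float(w), "p_value": float(pv)}
            for name, (w, pv) in (
                ("pka", stats.shapiro(pka)),
                ("hka", stats.shapiro(hka)),
                ("difference", stats.shapiro(pka - hka)),
            )
        }
    return AccuracyReport(
        n_pairs=len(complete),
        pearson_r=r,
        pearson_p=p,
        regression=reg,
        bland_altman=ba,
        summaries=summaries,
        normality=norm,
    )


def run_reliability_study(
    intrarater: Mapping[str, RatingsMatrix],
    interrater: RatingsMatrix,
    test_retest: RatingsMatrix,
) -> ReliabilityReport:
    """Reliability battery over the three rating designs.

    ``intrarater`` matrices must have k=2 (two readings), ``interrater`` k=3
    (three raters) and ``test_retest`` k=2 (two photographs); a wrong k is an
    error naming the design.
    """
    for rater, m in intrarater.items():
        if m.k != 2:
            raise ValueError(f"intrarater design ({rater}) requires k=2 readings, got k={m.k}")
    if interrater.k != 3:
        raise ValueError(f"interrater design requires k=3 raters, got k={interrater.k}")
    if test_retest.k != 2:
        raise ValueError(f"test-retest design requires k=2 photographs, got k={test_retest.k}")

    intra = {}
    for rater, m in intrarater.items():
        icc = icc2k(m)
        ba = bland_altman(m.values[:, 0], m.values[:, 1])
        intra[rater] = (icc, ba)

    inter_icc = icc2k(interrater)
    labels = interrater.measurement_labels or tuple(
        f"M{i + 1}" for i in range(interrater.k)
    )
    pairwise = {
        f"{labels[i]}-{labels[j]}": bland_altman(
            interrater.values[:, i], interrater.values[:, j]
        )
        for i, j in combinations(range(interrater.k), 2)
    }

    tr_icc = icc2k(test_retest)
    tr_ba = bland_altman(test_retest.values[:, 0], test_retest.values[:, 1])
    return ReliabilityReport(
        intrarater=intra,
        interrater_icc=inter_icc,
        interrater_pairwise_ba=pairwise,
        test_retest_icc=tr_icc,
        test_retest_ba=tr_ba,
    )
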