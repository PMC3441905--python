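"""Blood-pool segmentation and extracellular volume (ECV) mapping.

ECV(%) = 100 * (1 - hematocrit) * dR1_pixel / dR1_blood, where
dR1 = 1/T1_post - 1/T1_pre.  The blood dR1 is taken from median blood
T1s measured in an automatically segmented blood pool on the
pre-contrast T1 map (threshold 1250 ms, isolated-pixel removal,
erosion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import disk, erosion as _gray_erosion

from .t1fit import T1MapResult

__all__ = [
    "BloodMask",
    "ECVMap",
    "BLOOD_T1_THRESHOLD_MS",
    "GD_RELAXIVITY",
    "segment_blood",
    "delta_r1",
    "gd_delta_r1",
    "compute_ecv",
    "ecv_value",
    "partition_coefficient_map",
    "normal_range",
    "parse_hematocrit",
]

#: Pre-contrast T1 threshold separating blood from tissue (ms).
BLOOD_T1_THRESHOLD_MS = 1250.0

#: Gd-DTPA relaxivity, L mmol^-1 s^-1.
GD_RELAXIVITY = 4.5


class EmptyBloodMaskError(RuntimeError):
    """No blood pixels survive segmentation; enter blood T1s manually."""


@dataclass
class BloodMask:
    """Automatically segmented blood pool and its median T1s."""

    mask: np.ndarray
    t1_blood_pre: float
    t1_blood_post: float | None
    n_pixels: int
    threshold_used: float
    erosion_radius: int
    min_component: int


@dataclass
class ECVMap:
    """Pixel-wise ECV in percent with provenance."""

    ecv: np.ndarray  # clipped to [0, 100] on valid pixels
    ecv_raw: np.ndarray  # unclipped
    valid_mask: np.ndarray
    hematocrit: float
    delta_r1_blood: float  # 1/ms
    provenance: dict = field(default_factory=dict)


def delta_r1(t1_pre: float, t1_post: float):
    """Change in relaxation rate, ``1/t1_post - 1/t1_pre`` (1/ms).

    Works elementwise on arrays; scalar inputs must be positive.
    """
    t1_pre = np.asarray(t1_pre, dtype=float)
    t1_post = np.asarray(t1_post, dtype=float)
    if t1_pre.ndim == 0 and t1_post.ndim == 0:
        if t1_pre <= 0 or t1_post <= 0:
            raise ValueError("T1 values must be > 0 ms")
        return float(1.0 / t1_post - 1.0 / t1_pre)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1.0 / t1_post - 1.0 / t1_pre


def gd_delta_r1(concentration: float, relaxivity: float = GD_RELAXIVITY) -> float:
    """dR1 (1/s) produced by a gadolinium concentration in mmol/L."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return relaxivity * concentration


def normal_range(mean: float, sd: float) -> tuple[float, float]:
    """Normal range as mean +/- 2 SD (same units as the inputs)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return (mean - 2.0 * sd, mean + 2.0 * sd)


def parse_hematocrit(value) -> float:
    """Accept a hematocrit as a fraction (0.42), percent (42 or '42%')."""
    if isinstance(value, str):
        value = value.strip().rstrip("%")
        value = float(value)
    value = float(value)
    if value >= 1.0:
        value /= 100.0
    if not 0.0 < value < 1.0:
        raise ValueError("hematocrit must be in (0, 1) or (0, 100)%")
    return value


def segment_blood(
    pre_t1: T1MapResult,
    post_t1: T1MapResult | None = None,
    threshold: float = BLOOD_T1_THRESHOLD_MS,
    min_component: int = 10,
    erosion_radius: int = 1,
) -> BloodMask:
    """Segment the blood pool on the pre-contrast T1 map.

    Thresholds the map strictly above ``threshold`` (default 1250 ms),
    removes isolated connected components smaller than ``min_component``
    pixels (8-connected) that might be attributed to noise, and erodes the
    mask by a disk of ``erosion_radius`` pixels to drop blood-tissue
    boundary pixels with partial-volume values.  Median blood T1s are then
    read off the pre (and, if given, co-registered post) T1 maps.

    Raises
    ------
    EmptyBloodMaskError
        If no pixels survive; blood T1s must then be entered manually.
    """
    t1 = pre_t1.t1_map
    mask = pre_t1.fit_ok_mask & np.isfinite(t1) & (t1 > threshold)

    if min_component > 0 and mask.any():
        labels = cc_label(mask, connectivity=2)
        keep = np.zeros_like(mask)
        for lab in range(1, labels.max() + 1):
            comp = labels == lab
            if comp.sum() >= min_component:
                keep |= comp
        mask = keep
    if erosion_radius > 0 and mask.any():
        mask = _gray_erosion(mask, disk(erosion_radius)).astype(bool)

    n = int(mask.sum())
    if n == 0:
        raise EmptyBloodMaskError(
            "blood-pool segmentation produced an empty mask; supply blood "
            "T1 values manually (e.g. CLI --blood-t1-pre/--blood-t1-post)"
        )

    t1_pre_med = float(np.median(t1[mask]))
    t1_post_med = None
    if post_t1 is not None:
        post_vals = post_t1.t1_map[mask]
        post_vals = post_vals[np.isfinite(post_vals)]
        if post_vals.size == 0:
            raise EmptyBloodMaskError(
                "no valid post-contrast T1 values inside the blood mask"
            )
        t1_post_med = float(np.median(post_vals))
    return BloodMask(
        mask=mask,
        t1_blood_pre=t1_pre_med,
        t1_blood_post=t1_post_med,
        n_pixels=n,
        threshold_used=float(threshold),
        erosion_radius=int(erosion_radius),
        min_component=int(min_component),
    )


def ecv_value(
    t1_myo_pre: float,
    t1_myo_post: float,
    t1_blood_pre: float,
    t1_blood_post: float,
    hematocrit: float,
) -> float:
    """Scalar ECV as a fraction: (1-hct) * dR1_tissue / dR1_blood."""
    dr1_blood = delta_r1(t1_blood_pre, t1_blood_post)
    if dr1_blood <= 0:
        raise ValueError("blood dR1 must be > 0; check pre/post labelling")
    dr1_tissue = delta_r1(t1_myo_pre, t1_myo_post)
    return (1.0 - hematocrit) * dr1_tissue / dr1_blood


def _pixel_delta_r1(pre_t1: T1MapResult, post_t1: T1MapResult):
    valid = (
        pre_t1.fit_ok_mask
        & post_t1.fit_ok_mask
        & np.isfinite(pre_t1.t1_map)
        & np.isfinite(post_t1.t1_map)
        & (pre_t1.t1_map > 0)
        & (post_t1.t1_map > 0)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        dr1 = 1.0 / post_t1.t1_map - 1.0 / pre_t1.t1_map
    return dr1, valid


def compute_ecv(
    pre_t1: T1MapResult,
    post_t1_coreg: T1MapResult,
    blood: BloodMask,
    hematocrit,
) -> ECVMap:
    """Pixel-wise ECV map in percent, calibrated by hematocrit.

    ``ECV(%) = 100 * (1 - hct) * dR1_pixel / dR1_blood``.  Pixels where
    either fit failed are invalid; negative raw ECV is kept in
    ``ecv_raw`` but marked invalid, and the display map is clipped to
    [0, 100].  Blood pixels evaluate to ~(1 - hct) * 100, the blood's own
    distribution volume.
    """
    hct = parse_hematocrit(hematocrit)
    if pre_t1.shape != post_t1_coreg.shape:
        raise ValueError("pre and post maps must be co-registered (same shape)")
    if blood.t1_blood_post is None:
        raise ValueError("BloodMask lacks a post-contrast median blood T1")
    dr1_blood = delta_r1(blood.t1_blood_pre, blood.t1_blood_post)
    if dr1_blood <= 0:
        raise ValueError(
            "blood dR1 <= 0: pre/post series appear mislabelled"
        )
    dr1, valid = _pixel_delta_r1(pre_t1, post_t1_coreg)
    raw = 100.0 * (1.0 - hct) * dr1 / dr1_blood
    raw = np.where(valid, raw, np.nan)
    valid = valid & (raw >= 0)
    clipped = np.clip(raw, 0.0, 100.0)
    return ECVMap(
        ecv=np.where(valid, clipped, np.nan),
        ecv_raw=raw,
        valid_mask=valid,
        hematocrit=hct,
        delta_r1_blood=float(dr1_blood),
        provenance={
            "t1_blood_pre": blood.t1_blood_pre,
            "t1_blood_post": blood.t1_blood_post,
            "blood_n_pixels": blood.n_pixels,
            "threshold_ms": blood.threshold_used,
        },
    )


def partition_coefficient_map(
    pre_t1: T1MapResult,
    post_t1_coreg: T1MapResult,
    blood: BloodMask,
) -> np.ndarray:
    """Unitless partition coefficient map, lambda = dR1_pixel / dR1_blood.

    Computable without a hematocrit; ECV(%) = (1 - hct) * lambda * 100.
    """
    if blood.t1_blood_post is None:
        raise ValueError("BloodMask lacks a post-contrast median blood T1")
    dr1_blood = delta_r1(blood.t1_blood_pre, blood.t1_blood_post)
    if dr1_blood <= 0:
        raise ValueError("blood dR1 <= 0: pre/post series appear mislabelled")
    dr1, valid = _pixel_delta_r1(pre_t1, post_t1_coreg)
    return np.where(valid, dr1 / dr1_blood, np.nan)
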