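"""Respiratory motion correction of a MOLLI series.

Each measured image is registered to a motion-free synthetic image of
matching inversion-recovery contrast, synthesized from the current T1
estimate.  Registration is a non-rigid optical-flow method; warping uses
a 5th-order B-spline interpolator to minimise loss of spatial
resolution.  Displacement fields are composed across iterations so that
every corrected image is interpolated exactly once from the original
data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.registration import optical_flow_tvl1, phase_cross_correlation

from .t1fit import (
    MolliSeries,
    T1MapResult,
    fit_map,
    initial_t1_estimate,
    synthesize_image,
)

__all__ = [
    "DeformationField",
    "RegistrationParams",
    "register_nonrigid",
    "warp",
    "compose_fields",
    "moco_series",
    "MocoResult",
]

logger = logging.getLogger(__name__)

#: Cap on the crude two-point T1 seed used inside MOCO (ms).  Long-T1
#: species are not fully recovered even at the longest TI, which makes the
#: closed-form estimate blow up; capping keeps the synthetic-image nulls
#: near their true positions.
CRUDE_T1_CAP_MS = 2000.0


@dataclass
class DeformationField:
    """Dense 2-D displacement field in pixel units.

    ``displacement`` has shape ``(2, nrow, ncol)`` holding ``(dy, dx)``:
    warping samples the moving image at ``x + displacement(x)``.
    """

    displacement: np.ndarray
    provenance: str = "moco"
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 3 or self.displacement.shape[0] != 2:
            raise ValueError("displacement must have shape (2, nrow, ncol)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite everywhere")

    @classmethod
    def identity(cls, shape: tuple[int, int], provenance: str = "identity"):
        return cls(np.zeros((2, *shape)), provenance=provenance)

    @classmethod
    def translation(cls, shape, dy: float, dx: float, provenance="translation"):
        d = np.empty((2, *shape))
        d[0] = dy
        d[1] = dx
        return cls(d, provenance=provenance)

    @property
    def reference_shape(self) -> tuple[int, int]:
        return self.displacement.shape[1:]

    def max_abs(self) -> float:
        return float(np.max(np.abs(self.displacement)))

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.displacement[0], self.displacement[1])


@dataclass(frozen=True)
class RegistrationParams:
    """Tunables of the optical-flow registration (engineering defaults).

    Respiratory motion is dominated by bulk translation, so the global
    translation is estimated first (phase cross-correlation) and the
    optical-flow step only refines the non-rigid residual; this keeps the
    flow well-behaved where synthetic and measured contrast differ
    locally (e.g. around tissue nulls).
    """

    attachment: float = 10.0
    tightness: float = 0.3
    num_warp: int = 5
    num_iter: int = 10
    tol: float = 1e-4
    field_sigma: float = 4.0  # Gaussian regularisation of the field, px
    translation_upsample: int = 16  # subpixel factor of the global shift
    max_displacement: float = 20.0  # safety clip, px
    nonrigid: bool = True  # False: stop after the translation stage


def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(img, [1, 99])
    if hi - lo < 1e-12:
        return np.zeros_like(img, dtype=float)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.5)


def register_nonrigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    params: RegistrationParams | None = None,
) -> DeformationField:
    """Estimate a dense field aligning ``moving`` onto ``fixed``.

    Multi-resolution TV-L1 optical flow on intensity-normalised images,
    with Gaussian post-smoothing of the field.  Degenerate (constant)
    inputs return an identity field flagged low-confidence.

    Returns a :class:`DeformationField` ``d`` such that
    ``warp(moving, d)`` approximates ``fixed``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed images must have the same shape")
    if not (np.all(np.isfinite(moving)) and np.all(np.isfinite(fixed))):
        raise ValueError("images must be finite")
    params = params or RegistrationParams()

    if np.ptp(moving) < 1e-12 or np.ptp(fixed) < 1e-12:
        warnings.warn(
            "degenerate (constant) image in registration; returning identity",
            stacklevel=2,
        )
        out = DeformationField.identity(moving.shape, provenance="moco")
        out.low_confidence = True
        return out

    mv = _normalize(moving)
    fx = _normalize(fixed)
    # stage 1: global translation (phase correlation, subpixel)
    shift, _, _ = phase_cross_correlation(
        fx, mv, upsample_factor=params.translation_upsample,
        normalization=None,
    )
    if not np.all(np.isfinite(shift)):
        shift = np.zeros(2)
    # warping samples the moving image at x + d, so the displacement that
    # moves mv onto fx is the negated phase-correlation shift
    trans = np.clip(-np.asarray(shift, dtype=float),
                    -params.max_displacement, params.max_displacement)
    tfield = DeformationField.translation(mv.shape, trans[0], trans[1])
    if not params.nonrigid:
        return DeformationField(tfield.displacement, provenance="moco")
    mv_shifted = warp(mv, tfield, interpolation_order=3)
    # stage 2: regularised non-rigid residual
    flow = optical_flow_tvl1(
        fx,
        mv_shifted,
        attachment=params.attachment,
        tightness=params.tightness,
        num_warp=params.num_warp,
        num_iter=params.num_iter,
        tol=params.tol,
        dtype=np.float64,
    )
    disp = np.asarray(flow, dtype=float)
    if params.field_sigma > 0:
        disp = np.stack(
            [gaussian_filter(disp[c], params.field_sigma) for c in range(2)]
        )
    disp += tfield.displacement  # residual on top of the constant shift
    np.clip(disp, -params.max_displacement, params.max_displacement, out=disp)
    low_conf = not np.all(np.isfinite(disp))
    if low_conf:
        disp = np.zeros_like(disp)
    return DeformationField(disp, provenance="moco", low_confidence=low_conf)


def warp(
    image: np.ndarray,
    field: DeformationField,
    interpolation_order: int = 5,
) -> np.ndarray:
    """Resample ``image`` at ``x + displacement(x)``.

    5th-order B-spline interpolation by default; samples falling outside
    the domain take nearest-edge values.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != field.reference_shape:
        raise ValueError("image shape does not match deformation field")
    rows, cols = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    coords = np.stack(
        [rows + field.displacement[0], cols + field.displacement[1]]
    )
    return map_coordinates(image, coords, order=interpolation_order,
                           mode="nearest")


def compose_fields(
    first: DeformationField, second: DeformationField
) -> DeformationField:
    """Compose two fields so one warp equals warping by ``first`` then ``second``.

    Returns ``c`` with ``c(x) = first(x + second(x)) + second(x)``, i.e.
    ``warp(img, c) ~= warp(warp(img, first), second)`` up to interpolation
    tolerance.
    """
    if first.reference_shape != second.reference_shape:
        raise ValueError("fields must share a reference shape")
    shape = first.reference_shape
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    coords = np.stack(
        [rows + second.displacement[0], cols + second.displacement[1]]
    )
    # fields are smooth: linear interpolation avoids spline overshoot
    sampled = np.stack(
        [
            map_coordinates(first.displacement[c], coords, order=1,
                            mode="nearest")
            for c in range(2)
        ]
    )
    return DeformationField(
        sampled + second.displacement, provenance="composite"
    )


@dataclass
class MocoResult:
    """Output bundle of :func:`moco_series`."""

    corrected: MolliSeries
    fields: list[DeformationField]
    t1: T1MapResult
    original: MolliSeries
    n_iterations_run: int = 0


def moco_series(
    series: MolliSeries,
    n_iterations: int = 2,
    update_tolerance: float = 0.5,
    params: RegistrationParams | None = None,
    fit_signal_floor: float = 0.0,
) -> MocoResult:
    """Iterative synthetic-image motion correction of one MOLLI series.

    The reference respiratory position is that of the longest-TI image
    (fully recovered, highest SNR).  Iteration 0 registers the shortest-TI
    image to the longest-TI image — a pair that avoids tissue nulling —
    and seeds a crude two-point T1 estimate.  Each subsequent iteration
    synthesizes a motion-free image per acquired TI, registers every
    measured image to its synthetic counterpart, composes the update with
    the accumulated field, warps the ORIGINAL images exactly once, and
    refits the T1 map.  Stops after ``n_iterations`` or when the largest
    displacement update drops below ``update_tolerance`` pixels.
    """
    params = params or RegistrationParams()
    n = series.n_images
    shape = series.shape
    fields = [DeformationField.identity(shape, provenance="moco")
              for _ in range(n)]

    i_min = series.shortest_ti_index()
    i_max = series.longest_ti_index()

    # seed: align the shortest-TI image to the longest-TI anchor, then take
    # a crude two-point T1 estimate from the aligned pair
    try:
        fields[i_min] = register_nonrigid(
            series.images[i_min], series.images[i_max], params
        )
    except Exception:  # pragma: no cover - defensive
        logger.exception("seed registration failed; using identity")
    seed_pair = MolliSeries(
        images=np.stack(
            [warp(series.images[i_min], fields[i_min]),
             series.images[i_max]]
        ),
        ti_values=series.ti_values[[i_min, i_max]],
        pixel_spacing=series.pixel_spacing,
        contrast_phase=series.contrast_phase,
    )
    result: T1MapResult = initial_t1_estimate(seed_pair, t1_cap=CRUDE_T1_CAP_MS)

    # "current" images must always reflect the accumulated fields, or the
    # next registration update double-counts corrections already applied
    corrected = series.images.copy()
    corrected[i_min] = seed_pair.images[0]
    iterations_run = 0
    for iteration in range(n_iterations):
        iterations_run += 1
        # synthetics of the first iteration come from the crude seed, whose
        # mispredicted nulls can mislead the non-rigid stage: correct only
        # the dominant translation until a real fit is available
        it_params = (replace(params, nonrigid=False) if iteration == 0
                     else params)
        max_update = 0.0
        for i in range(n):
            synth = synthesize_image(result, series.ti_values[i])
            current = corrected[i]
            try:
                update = register_nonrigid(current, synth, it_params)
            except Exception:
                logger.exception(
                    "registration failed for image %d; keeping previous field", i
                )
                continue
            max_update = max(max_update, update.max_abs())
            fields[i] = compose_fields(fields[i], update)
            fields[i] = replace(fields[i], provenance="moco")
        # single warp from the originals with the accumulated field
        corrected = np.stack(
            [warp(series.images[i], fields[i]) for i in range(n)]
        )
        result = fit_map(series.replace_images(corrected),
                         signal_floor=fit_signal_floor)
        if max_update < update_tolerance:
            break

    corrected_series = series.replace_images(corrected)
    corrected_series.meta["moco"] = True
    return MocoResult(
        corrected=corrected_series,
        fields=fields,
        t1=result,
        original=series,
        n_iterations_run=iterations_run,
    )
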