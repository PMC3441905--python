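"""Co-registration of the post-contrast series to the pre-contrast frame.

Pre- and post-contrast series come from separate breath-holds.  The
longest-TI images of both motion-corrected series have almost completely
recovered magnetization, so their contrast is very similar and intensity
based registration works directly.  The estimated field is combined with
each post image's respiratory-motion field into a composite deformation
that is applied to the ORIGINAL post images a single time (avoiding an
unnecessary loss of spatial resolution), after which the final
post-contrast T1 map is refitted pixel-wise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .moco import (
    DeformationField,
    MocoResult,
    RegistrationParams,
    compose_fields,
    register_nonrigid,
    warp,
)
from .t1fit import MolliSeries, T1MapResult, fit_map

__all__ = ["CoregResult", "coregister_pre_post"]

logger = logging.getLogger(__name__)


@dataclass
class CoregResult:
    coreg_field: DeformationField
    post_t1: T1MapResult
    post_corrected: MolliSeries
    composite_fields: list[DeformationField]


def coregister_pre_post(
    pre: MocoResult,
    post: MocoResult,
    params: RegistrationParams | None = None,
    fit_signal_floor: float = 0.0,
    refit: bool = True,
) -> CoregResult:
    """Align the post-contrast series/map onto the pre-contrast frame.

    Registers the post longest-TI motion-corrected image (moving) to the
    pre longest-TI motion-corrected image (fixed); composes the resulting
    field with each post image's accumulated motion-correction field and
    warps the original post images exactly once; refits the post T1 map
    from the composite-warped images.

    If registration fails, an identity co-registration field is used with
    a prominent warning — the ECV map remains computable at degraded
    quality.  Set ``refit=False`` (debug only) to warp the fitted T1/A/B
    maps directly instead of refitting from warped images.
    """
    if pre.corrected.shape != post.corrected.shape:
        raise ValueError("pre and post series must have the same shape")
    if pre.corrected.pixel_spacing != post.corrected.pixel_spacing:
        raise ValueError("pre and post series must share pixel spacing")
    params = params or RegistrationParams()

    fixed = pre.corrected.images[pre.corrected.longest_ti_index()]
    moving = post.corrected.images[post.corrected.longest_ti_index()]
    try:
        coreg_field = register_nonrigid(moving, fixed, params)
        coreg_field.provenance = "coreg"
    except Exception:
        logger.exception("co-registration failed")
        warnings.warn(
            "co-registration FAILED; proceeding with identity field — "
            "ECV map quality will be degraded",
            stacklevel=2,
        )
        coreg_field = DeformationField.identity(
            pre.corrected.shape, provenance="coreg"
        )
        coreg_field.low_confidence = True

    composite = [
        compose_fields(f, coreg_field) for f in post.fields
    ]
    corrected = np.stack(
        [
            warp(post.original.images[i], composite[i])
            for i in range(post.original.n_images)
        ]
    )
    post_series = post.original.replace_images(corrected)
    post_series.meta["coreg"] = True

    if refit:
        post_t1 = fit_map(post_series, signal_floor=fit_signal_floor)
    else:  # debug mode: warp the already fitted maps instead of refitting
        t1 = post.t1
        post_t1 = T1MapResult(
            a_map=warp(t1.a_map, coreg_field),
            b_map=warp(t1.b_map, coreg_field),
            t1_star_map=warp(np.nan_to_num(t1.t1_star_map), coreg_field),
            t1_map=warp(np.nan_to_num(t1.t1_map), coreg_field),
            rss_map=warp(t1.rss_map, coreg_field),
            fit_ok_mask=warp(
                t1.fit_ok_mask.astype(float), coreg_field, 1
            ) > 0.5,
            meta={**t1.meta, "warped_map": True},
        )
    return CoregResult(
        coreg_field=coreg_field,
        post_t1=post_t1,
        post_corrected=post_series,
        composite_fields=composite,
    )
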