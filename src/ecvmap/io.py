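"""Readers, writers, configuration, and the orchestrated pipeline.

NIfTI (one 3-D file per series, slices ordered by acquisition) plus a
JSON sidecar carrying the TI list is the canonical interchange format.
DICOM series with per-image InversionTime tags are read when pydicom is
installed (optional extra).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .coreg import coregister_pre_post
from .ecv import compute_ecv, partition_coefficient_map, segment_blood
from .moco import DeformationField, MocoResult, RegistrationParams, moco_series
from .t1fit import MolliSeries, fit_map

__all__ = [
    "PipelineConfig",
    "read_series",
    "write_series",
    "write_map",
    "read_map",
    "write_field",
    "run_pipeline",
    "process_study",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline knobs in one serializable object.

    Every default is the documented engineering choice; the config hash
    is recorded in all outputs so runs are attributable.
    """

    # motion correction
    moco: bool = True
    moco_iterations: int = 2
    moco_update_tolerance_px: float = 0.5
    # co-registration
    coreg: bool = True
    # registration
    reg_attachment: float = 10.0
    reg_tightness: float = 0.3
    reg_num_warp: int = 5
    reg_num_iter: int = 10
    reg_tol: float = 1e-4
    reg_field_sigma_px: float = 4.0
    # fitting
    fit_signal_floor: float = 0.0
    fit_multi_start: bool = False
    # blood segmentation
    blood_threshold_ms: float = 1250.0
    blood_min_component_px: int = 10
    blood_erosion_radius_px: int = 1
    # output
    write_nifti: bool = True
    seed: int = 0

    def registration_params(self) -> RegistrationParams:
        return RegistrationParams(
            attachment=self.reg_attachment,
            tightness=self.reg_tightness,
            num_warp=self.reg_num_warp,
            num_iter=self.reg_num_iter,
            tol=self.reg_tol,
            field_sigma=self.reg_field_sigma_px,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _affine(pixel_spacing) -> np.ndarray:
    return np.diag([pixel_spacing[0], pixel_spacing[1], 1.0, 1.0])


def write_series(series: MolliSeries, nifti_path, sidecar_path=None) -> None:
    """Write a MOLLI series as 3-D NIfTI plus a JSON TI sidecar."""
    nifti_path = Path(nifti_path)
    # (row, col, ti) on disk
    data = np.moveaxis(series.images, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(series.pixel_spacing))
    nib.save(img, nifti_path)
    sidecar = Path(sidecar_path) if sidecar_path else nifti_path.with_suffix(
        "").with_suffix(".json")
    payload = {
        "ti_values_ms": list(map(float, series.ti_values)),
        "pixel_spacing_mm": list(series.pixel_spacing),
        "contrast_phase": series.contrast_phase,
        "meta": _jsonable(series.meta),
    }
    sidecar.write_text(json.dumps(payload, indent=2))


def read_series(path, ti_source=None) -> MolliSeries:
    """Read a MOLLI series from NIfTI + JSON sidecar or a DICOM directory.

    Parameters
    ----------
    path : str or Path
        NIfTI file, or a directory of single-frame DICOM files (requires
        pydicom) each carrying an InversionTime tag.
    ti_source : str or Path, optional
        JSON sidecar path; defaults to ``<path>.json`` next to the NIfTI.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_dicom_series(path)

    sidecar = Path(ti_source) if ti_source else path.with_suffix(
        "").with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"TI sidecar not found: {sidecar}; pass ti_source explicitly"
        )
    meta = json.loads(sidecar.read_text())
    ti = np.asarray(meta["ti_values_ms"], dtype=float)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI, got shape {data.shape}")
    images = np.moveaxis(data, -1, 0)
    if len(images) != len(ti):
        raise ValueError(
            f"series has {len(images)} images but sidecar lists {len(ti)} "
            "inversion times — they must match one-to-one"
        )
    spacing = tuple(meta.get("pixel_spacing_mm",
                             np.abs(np.diag(img.affine)[:2]).tolist()))
    return MolliSeries(
        images=images,
        ti_values=ti,
        pixel_spacing=(float(spacing[0]), float(spacing[1])),
        contrast_phase=meta.get("contrast_phase", "pre"),
        meta=meta.get("meta", {}),
    )


def _read_dicom_series(directory: Path) -> MolliSeries:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading DICOM series requires pydicom "
            "(pip install ecvmap[dicom])"
        ) from exc
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    frames = []
    for f in files:
        ds = pydicom.dcmread(f)
        ti = getattr(ds, "InversionTime", None)
        if ti is None:
            raise ValueError(f"{f.name}: missing InversionTime tag")
        frames.append((float(ti), ds.pixel_array.astype(float), ds))
    frames.sort(key=lambda t: t[0])
    tis = [t[0] for t in frames]
    if len(set(tis)) != len(tis):
        raise ValueError("duplicate InversionTime values in DICOM series")
    ds0 = frames[0][2]
    spacing = tuple(float(v) for v in getattr(ds0, "PixelSpacing", (1.0, 1.0)))
    return MolliSeries(
        images=np.stack([t[1] for t in frames]),
        ti_values=np.asarray(tis),
        pixel_spacing=spacing,
        meta={"source": "dicom"},
    )


def write_map(array: np.ndarray, path, pixel_spacing=(1.9, 1.9)) -> None:
    """Write a 2-D map (e.g. T1 in ms, ECV in %) as float32 NIfTI."""
    img = nib.Nifti1Image(
        np.asarray(array, dtype=np.float32), _affine(pixel_spacing)
    )
    nib.save(img, Path(path))


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj, dtype=float)


def write_field(fld: DeformationField, path, pixel_spacing=(1.9, 1.9)) -> None:
    """Write a deformation field as a 2-channel (dy, dx) NIfTI in pixels."""
    data = np.moveaxis(fld.displacement, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine(pixel_spacing)), Path(path))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def process_study(
    pre: MolliSeries,
    post: MolliSeries,
    hematocrit=None,
    config: PipelineConfig | None = None,
):
    """Run MOCO, co-registration, segmentation and ECV on two series.

    Returns a dict of in-memory results: ``pre_moco``, ``post_moco``
    (:class:`MocoResult` or plain fit results when MOCO is disabled),
    ``coreg`` (or None), ``pre_t1``, ``post_t1``, ``blood``, ``ecv_map``
    (None without hematocrit), ``lambda_map`` and ``timings``.
    """
    config = config or PipelineConfig()
    params = config.registration_params()
    timings: dict[str, float] = {}
    results: dict = {"timings": timings, "config_hash": config.hash()}

    def _timed(name, fn):
        t0 = time.perf_counter()
        out = fn()
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %-12s %.2f s", name, timings[name])
        return out

    if config.moco:
        pre_m = _timed("moco_pre", lambda: moco_series(
            pre, config.moco_iterations, config.moco_update_tolerance_px,
            params, config.fit_signal_floor))
        post_m = _timed("moco_post", lambda: moco_series(
            post, config.moco_iterations, config.moco_update_tolerance_px,
            params, config.fit_signal_floor))
    else:
        pre_fit = _timed("fit_pre", lambda: fit_map(
            pre, signal_floor=config.fit_signal_floor,
            multi_start=config.fit_multi_start))
        post_fit = _timed("fit_post", lambda: fit_map(
            post, signal_floor=config.fit_signal_floor,
            multi_start=config.fit_multi_start))
        n_pre, n_post = pre.n_images, post.n_images
        pre_m = MocoResult(pre, [DeformationField.identity(pre.shape)
                                 for _ in range(n_pre)], pre_fit, pre)
        post_m = MocoResult(post, [DeformationField.identity(post.shape)
                                   for _ in range(n_post)], post_fit, post)
    results["pre_moco"] = pre_m
    results["post_moco"] = post_m
    results["pre_t1"] = pre_m.t1

    if config.coreg:
        cr = _timed("coreg", lambda: coregister_pre_post(
            pre_m, post_m, params, config.fit_signal_floor))
        results["coreg"] = cr
        results["post_t1"] = cr.post_t1
    else:
        results["coreg"] = None
        results["post_t1"] = post_m.t1

    blood = _timed("blood", lambda: segment_blood(
        results["pre_t1"], results["post_t1"],
        threshold=config.blood_threshold_ms,
        min_component=config.blood_min_component_px,
        erosion_radius=config.blood_erosion_radius_px))
    results["blood"] = blood
    results["lambda_map"] = partition_coefficient_map(
        results["pre_t1"], results["post_t1"], blood)

    if hematocrit is None:
        logger.warning(
            "no hematocrit given: skipping ECV, emitting the partition-"
            "coefficient map only")
        results["ecv_map"] = None
    else:
        results["ecv_map"] = _timed("ecv", lambda: compute_ecv(
            results["pre_t1"], results["post_t1"], blood, hematocrit))
    return results


def run_pipeline(
    pre_path,
    post_path,
    hematocrit=None,
    config: PipelineConfig | None = None,
    out_dir="ecvmap_out",
    ti_pre=None,
    ti_post=None,
) -> dict:
    """End-to-end pipeline from files on disk to artifacts on disk.

    Writes pre/post T1 maps, rss maps, deformation fields, the blood
    mask, the ECV map (or partition-coefficient map when no hematocrit is
    given) and a JSON report.  Deterministic given config; the config
    hash is embedded in the report.  Returns the report dict.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pre = read_series(pre_path, ti_pre)
    post = read_series(post_path, ti_post)
    res = process_study(pre, post, hematocrit, config)

    sp = pre.pixel_spacing
    write_map(res["pre_t1"].t1_map, out / "t1_pre.nii", sp)
    write_map(res["post_t1"].t1_map, out / "t1_post.nii", sp)
    write_map(res["pre_t1"].rss_map, out / "rss_pre.nii", sp)
    write_map(res["post_t1"].rss_map, out / "rss_post.nii", sp)
    write_map(res["blood"].mask.astype(np.float32), out / "blood_mask.nii", sp)
    write_map(res["lambda_map"], out / "lambda.nii", sp)
    for i, f in enumerate(res["pre_moco"].fields):
        write_field(f, out / f"field_pre_{i:02d}.nii", sp)
    if res["coreg"] is not None:
        for i, f in enumerate(res["coreg"].composite_fields):
            write_field(f, out / f"field_post_composite_{i:02d}.nii", sp)
        write_field(res["coreg"].coreg_field, out / "field_coreg.nii", sp)

    report = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": res["config_hash"],
        "stages": {
            "moco": bool(config.moco),
            "coreg": bool(config.coreg),
            "ecv": hematocrit is not None,
        },
        "blood": {
            "t1_pre_ms": _round_sig(res["blood"].t1_blood_pre),
            "t1_post_ms": _round_sig(res["blood"].t1_blood_post),
            "n_pixels": res["blood"].n_pixels,
            "threshold_ms": res["blood"].threshold_used,
        },
        "timings_s": res["timings"],
    }
    if res["ecv_map"] is not None:
        emap = res["ecv_map"]
        write_map(emap.ecv, out / "ecv.nii", sp)
        report["ecv"] = {
            "hematocrit": emap.hematocrit,
            "delta_r1_blood_per_ms": _round_sig(emap.delta_r1_blood),
            "median_valid_ecv_pct": _round_sig(
                float(np.nanmedian(emap.ecv[emap.valid_mask]))
            ),
            "n_valid_pixels": int(emap.valid_mask.sum()),
        }
    else:
        report["ecv"] = None
        report["warning"] = (
            "hematocrit missing: partition-coefficient map written instead "
            "of ECV"
        )
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report
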