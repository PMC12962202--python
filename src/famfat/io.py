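"""NIfTI and JSON serialization for echo series, maps, and ROI masks."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition_sim import EchoSeries
from .fitting import FitResult
from .sequence_design import AcquisitionParams


def _affine(params: AcquisitionParams) -> np.ndarray:
    dx, dy = params.voxel_cm
    aff = np.diag([dx * 10.0, dy * 10.0, params.slice_thickness_mm, 1.0])  # mm
    return aff


def save_echo_series(series: EchoSeries, prefix) -> dict:
    """Write per-echo real/imag NIfTI volumes plus a JSON sidecar.

    Produces ``<prefix>_real.nii``, ``<prefix>_imag.nii`` (x, y, echo) and
    ``<prefix>.json`` holding echo times, field strength, noise level and
    seed.  Returns the sidecar payload.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.params)
    data = np.moveaxis(series.images, 0, -1)  # (nx, ny, n_echoes)
    nib.save(nib.Nifti1Image(np.ascontiguousarray(data.real), aff), str(prefix) + "_real.nii")
    nib.save(nib.Nifti1Image(np.ascontiguousarray(data.imag), aff), str(prefix) + "_imag.nii")
    sidecar = {
        "tes_ms": list(map(float, series.tes_ms)),
        "b0_t": series.params.b0_t,
        "tr_ms": series.params.tr_ms,
        "matrix": list(series.params.matrix),
        "fov_cm": list(series.params.fov_cm),
        "noise_sd": series.noise_sd,
        "seed": series.seed,
        "label": series.params.label,
    }
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return sidecar


def load_echo_series(prefix) -> EchoSeries:
    """Load an echo series saved by :func:`save_echo_series`."""
    prefix = Path(prefix)
    with open(str(prefix) + ".json") as fh:
        sidecar = json.load(fh)
    real = np.asanyarray(nib.load(str(prefix) + "_real.nii").dataobj)
    imag = np.asanyarray(nib.load(str(prefix) + "_imag.nii").dataobj)
    images = np.moveaxis(real + 1j * imag, -1, 0)
    tes = np.asarray(sidecar["tes_ms"], float)
    params = AcquisitionParams(
        b0_t=sidecar["b0_t"],
        tr_ms=sidecar["tr_ms"],
        te1_ms=float(tes[0]),
        dte_ms=float(tes[1] - tes[0]),
        n_echoes=len(tes),
        matrix=tuple(sidecar["matrix"]),
        fov_cm=tuple(sidecar["fov_cm"]),
        label=sidecar.get("label", ""),
    )
    return EchoSeries(images=images, tes_ms=tes, params=params,
                      noise_sd=sidecar.get("noise_sd", 0.0), seed=sidecar.get("seed"))


def save_fit_result(result: FitResult, params: AcquisitionParams, prefix,
                    provenance: dict | None = None) -> None:
    """Write the quantitative maps as NIfTI plus a JSON provenance sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(params)
    maps = {
        "pdff": result.pdff_pct,
        "r2star": result.r2star_map,
        "fieldmap": result.psi_map,
        "water": result.water_map,
        "fat": result.fat_map,
        "residual": result.residual_map,
    }
    for name, arr in maps.items():
        nib.save(nib.Nifti1Image(np.ascontiguousarray(arr, dtype=np.float64), aff),
                 f"{prefix}_{name}.nii")
    payload = {"method": result.method_tag}
    payload.update(provenance or {})
    with open(str(prefix) + "_fit.json", "w") as fh:
        json.dump(payload, fh, indent=2)


def save_mask(mask: np.ndarray, params: AcquisitionParams, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(params)), str(path))
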