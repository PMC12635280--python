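"""NIfTI and sidecar I/O.

Volumes are written as NIfTI-1 with the voxel size in the affine diagonal
(float32 data, uint8 masks); acquisition metadata (echo times, flip
angles, frame timing) travels in JSON sidecars next to the volumes.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import DynamicSeries, LabelMap, MultiEchoGRE, VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "read_multi_echo",
    "write_multi_echo",
    "read_dynamic",
    "write_dynamic",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def _voxel_size(img) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def write_volume(vol: VolumeGrid | np.ndarray, path: str | Path,
                 voxel_size_mm=(2.0, 2.0, 2.0)) -> Path:
    if isinstance(vol, VolumeGrid):
        data, vs = vol.data, vol.voxel_size_mm
    else:
        data, vs = np.asarray(vol), voxel_size_mm
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    path = Path(path)
    nib.save(nib.Nifti1Image(data, _affine(vs)), str(path))
    return path


def read_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    return VolumeGrid(np.asarray(img.dataobj), _voxel_size(img))


def write_label_map(labels: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(labels.data.astype(np.int16),
                             _affine(labels.voxel_size_mm)), str(path))
    sidecar = path.with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps({"label_codes": labels.codes}, indent=2))
    return path


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    img = nib.load(str(path))
    codes = {}
    sidecar = path.with_suffix("").with_suffix(".json")
    if sidecar.exists():
        codes = json.loads(sidecar.read_text()).get("label_codes", {})
    return LabelMap(np.asarray(img.dataobj).astype(np.int16),
                    _voxel_size(img), codes=codes)


def write_multi_echo(gre: MultiEchoGRE, stem: str | Path) -> tuple[Path, Path, Path]:
    stem = Path(stem)
    mag = np.moveaxis(np.abs(gre.echoes), 0, -1).astype(np.float32)
    pha = np.moveaxis(np.angle(gre.echoes), 0, -1).astype(np.float32)
    aff = _affine(gre.voxel_size_mm)
    mag_p = stem.with_name(stem.name + "_mag.nii.gz")
    pha_p = stem.with_name(stem.name + "_phase.nii.gz")
    nib.save(nib.Nifti1Image(mag, aff), str(mag_p))
    nib.save(nib.Nifti1Image(pha, aff), str(pha_p))
    side = stem.with_name(stem.name + ".json")
    side.write_text(json.dumps({"te_ms": list(map(float, gre.te_ms)),
                                "b0_tesla": gre.b0_tesla}, indent=2))
    return mag_p, pha_p, side


def read_multi_echo(stem: str | Path) -> MultiEchoGRE:
    stem = Path(stem)
    side = json.loads(stem.with_name(stem.name + ".json").read_text())
    mag_img = nib.load(str(stem.with_name(stem.name + "_mag.nii.gz")))
    pha_img = nib.load(str(stem.with_name(stem.name + "_phase.nii.gz")))
    mag = np.moveaxis(np.asarray(mag_img.dataobj), -1, 0)
    pha = np.moveaxis(np.asarray(pha_img.dataobj), -1, 0)
    te = np.asarray(side["te_ms"], dtype=float)
    if mag.shape[0] != te.size:
        raise ValueError(f"echo count {mag.shape[0]} != TE vector length {te.size}")
    return MultiEchoGRE(mag * np.exp(1j * pha), te, side["b0_tesla"],
                        _voxel_size(mag_img))


def write_dynamic(series: DynamicSeries, stem: str | Path) -> tuple[Path, Path]:
    stem = Path(stem)
    data = np.moveaxis(series.frames, 0, -1).astype(np.float32)
    p = stem.with_name(stem.name + ".nii.gz")
    nib.save(nib.Nifti1Image(data, _affine(series.voxel_size_mm)), str(p))
    side = stem.with_name(stem.name + ".json")
    side.write_text(json.dumps({
        "times_s": list(map(float, series.times_s)),
        "te_ms": series.te_ms, "tr_ms": series.tr_ms,
        "flip_angle_deg": series.flip_angle_deg}, indent=2))
    return p, side


def read_dynamic(stem: str | Path) -> DynamicSeries:
    stem = Path(stem)
    side = json.loads(stem.with_name(stem.name + ".json").read_text())
    img = nib.load(str(stem.with_name(stem.name + ".nii.gz")))
    frames = np.moveaxis(np.asarray(img.dataobj), -1, 0)
    return DynamicSeries(frames, np.asarray(side["times_s"], dtype=float),
                         te_ms=side.get("te_ms", 0.0),
                         tr_ms=side.get("tr_ms", 0.0),
                         flip_angle_deg=side.get("flip_angle_deg", 0.0),
                         voxel_size_mm=_voxel_size(img))
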