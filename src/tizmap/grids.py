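"""Raster containers shared by every stage of the pipeline.

All volumes live in voxel-index space, 0-based, axis order (x, y, z).
Axis 0 is the left-right axis: the mid-sagittal symmetry plane sits between
index ``(n-1)/2`` and reflection is ``i -> n-1-i``.  Axis 2 is the B0 axis.
No world-space affine handling happens here; geometry is shape + spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeGrid",
    "LabelMap",
    "MultiEchoGRE",
    "DynamicSeries",
    "check_same_geometry",
]


@dataclass
class VolumeGrid:
    """A 3D scalar or complex field with voxel spacing in mm.

    ``symmetry_axis`` declares which index axis the mid-sagittal plane
    bisects (default 0, the left-right axis).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    symmetry_axis: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid expects 3D data, got ndim={self.data.ndim}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """New grid sharing this geometry."""
        return VolumeGrid(data, self.voxel_size_mm, self.symmetry_axis)

    def mirrored(self) -> "VolumeGrid":
        return self.like(np.flip(self.data, axis=self.symmetry_axis))


@dataclass
class LabelMap:
    """Integer-coded tissue/ROI volume sharing VolumeGrid geometry."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    symmetry_axis: int = 0
    codes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelMap expects 3D data")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap data must be integer-coded")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def mask(self, *names: str) -> np.ndarray:
        """Boolean union of the named tissue classes."""
        out = np.zeros(self.data.shape, dtype=bool)
        for name in names:
            out |= self.data == self.codes[name]
        return out


@dataclass
class MultiEchoGRE:
    """Per-echo complex volumes, echo times (ms) and field strength (T)."""

    echoes: np.ndarray  # (n_echo, nx, ny, nz) complex
    te_ms: np.ndarray
    b0_tesla: float
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.echoes = np.asarray(self.echoes)
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        if self.echoes.ndim != 4:
            raise ValueError("echoes must be (n_echo, nx, ny, nz)")
        if self.echoes.shape[0] != self.te_ms.size:
            raise ValueError("echo count does not match TE vector")
        if np.any(self.te_ms <= 0) or np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("te_ms must be strictly increasing and positive")

    @property
    def n_echoes(self) -> int:
        return int(self.te_ms.size)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.echoes)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.echoes)


@dataclass
class DynamicSeries:
    """4D dynamic acquisition: (n_frames, nx, ny, nz) + frame times (s)."""

    frames: np.ndarray
    times_s: np.ndarray
    te_ms: float = 0.0
    tr_ms: float = 0.0
    flip_angle_deg: float = 0.0
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError("frames must be (n_frames, nx, ny, nz)")
        if self.frames.shape[0] != self.times_s.size:
            raise ValueError("frame count does not match time vector")

    @property
    def n_frames(self) -> int:
        return int(self.times_s.size)


def check_same_geometry(*objs, atol_mm: float = 1e-3) -> None:
    """Raise if shapes differ or voxel sizes differ by more than ``atol_mm``."""
    shapes = set()
    spacings = []
    for o in objs:
        data = getattr(o, "data", None)
        if data is None:
            data = getattr(o, "frames", getattr(o, "echoes", o))
            shapes.add(tuple(data.shape[-3:]))
        else:
            shapes.add(tuple(data.shape))
        spacings.append(tuple(getattr(o, "voxel_size_mm", (np.nan,) * 3)))
    if len(shapes) > 1:
        raise ValueError(f"geometry mismatch: shapes {sorted(shapes)}")
    ref = spacings[0]
    for sp in spacings[1:]:
        if any(abs(a - b) > atol_mm for a, b in zip(ref, sp)):
            raise ValueError(f"geometry mismatch: voxel sizes {ref} vs {sp}")
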