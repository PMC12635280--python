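"""PDR computation and infiltration-zone (TIZ) delineation.

PDR is the ratio of the paramagnetic to the absolute diamagnetic component
susceptibility, ``PDR = PCS / max(|DCS|, eps)``.  The TIZ is the set of
edema voxels (outside the blood-exclusion mask) whose PDR exceeds an
automatic, subject-specific threshold: the maximum PDR of the contralateral
gray matter after removing subcortical structures and trimming each
reference tissue's values above its own 95th percentile.  Reproducibility
across dipole-inversion algorithms is quantified with the Dice-Sorensen
coefficient of the two TIZ masks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PdrMap",
    "TizResult",
    "mirror_mask",
    "compute_pdr",
    "reference_trim",
    "tiz_threshold",
    "segment_tiz",
    "dice",
]

log = logging.getLogger(__name__)


@dataclass
class PdrMap:
    pdr: np.ndarray  # dimensionless, >= 0
    epsilon_ppm: float
    valid_mask: np.ndarray  # analysis support
    capped_mask: np.ndarray  # voxels where |DCS| hit the epsilon floor


@dataclass
class TizResult:
    tiz_mask: np.ndarray
    threshold: float
    trimmed_gm_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    trimmed_wm_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    provenance: str = ""


def mirror_mask(mask: np.ndarray, symmetry_axis: int = 0) -> np.ndarray:
    """Reflect a mask across the mid-sagittal index plane (i -> n-1-i)."""
    return np.flip(np.asarray(mask), axis=symmetry_axis)


def compute_pdr(pcs_map: np.ndarray, dcs_map: np.ndarray,
                mask: np.ndarray | None = None,
                epsilon_ppm: float = 1e-4) -> PdrMap:
    """PDR = PCS / max(|DCS|, epsilon); epsilon floors near-zero |DCS|.

    Capped voxels are retained (large finite PDR is signal, not error) but
    flagged for provenance.
    """
    if epsilon_ppm < 0:
        raise ValueError("epsilon_ppm must be >= 0")
    pcs = np.asarray(pcs_map, dtype=float)
    dcs = np.asarray(dcs_map, dtype=float)
    if mask is None:
        mask = np.ones(pcs.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    absdcs = np.abs(dcs)
    capped = mask & (absdcs < epsilon_ppm)
    denom = np.maximum(absdcs, epsilon_ppm)
    pdr = np.where(mask, pcs / denom, 0.0)
    return PdrMap(pdr, epsilon_ppm, mask, capped)


def reference_trim(pdr_map: np.ndarray, gm_mask: np.ndarray,
                   wm_mask: np.ndarray, subcortical_mask: np.ndarray | None = None,
                   trim_pct: float = 95.0, pooled: bool = False
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Build the trimmed contralateral reference distributions.

    Subcortical voxels are removed from gray matter, then values above the
    trim percentile (per tissue by default, pooled behind the flag) are
    eliminated to guard against outliers and registration error.
    """
    gm = np.asarray(gm_mask, dtype=bool)
    wm = np.asarray(wm_mask, dtype=bool)
    if subcortical_mask is not None:
        gm = gm & ~np.asarray(subcortical_mask, dtype=bool)
    if not gm.any():
        raise ValueError("GM reference empty after subcortical removal")
    gm_vals = np.asarray(pdr_map)[gm]
    wm_vals = np.asarray(pdr_map)[wm]
    if pooled:
        cut = np.percentile(np.concatenate([gm_vals, wm_vals]), trim_pct)
        return gm_vals[gm_vals <= cut], wm_vals[wm_vals <= cut]
    gm_cut = np.percentile(gm_vals, trim_pct)
    wm_cut = np.percentile(wm_vals, trim_pct) if wm_vals.size else np.inf
    return gm_vals[gm_vals <= gm_cut], wm_vals[wm_vals <= wm_cut]


def tiz_threshold(trimmed_gm_values: np.ndarray) -> float:
    """The TIZ threshold: maximum of the retained GM PDR values.

    GM PDR exceeds WM PDR, so the GM maximum is the operative bound for
    "above any healthy reference tissue".
    """
    vals = np.asarray(trimmed_gm_values, dtype=float)
    if vals.size == 0:
        raise ValueError("trimmed GM reference is empty")
    return float(vals.max())


def segment_tiz(pdr_map: np.ndarray, edema_mask: np.ndarray,
                blood_exclusion_mask: np.ndarray | None,
                threshold: float, provenance: str = "") -> TizResult:
    """TIZ = edema voxels outside the exclusion mask with PDR strictly above
    the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    edema = np.asarray(edema_mask, dtype=bool)
    excl = np.zeros(edema.shape, dtype=bool) if blood_exclusion_mask is None \
        else np.asarray(blood_exclusion_mask, dtype=bool)
    tiz = edema & ~excl & (np.asarray(pdr_map) > threshold)
    return TizResult(tiz, float(threshold), provenance=provenance)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice-Sorensen coefficient 2|A&B|/(|A|+|B|); two empty masks -> 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        log.info("dice of two empty masks defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)
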