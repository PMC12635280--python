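"""End-to-end orchestration: phantom -> QSM -> decomposition -> hemodynamics
-> PDR/TIZ (per inversion algorithm) -> statistics report.

Every tunable lives in :class:`RunConfig`; every computed per-subject
threshold (nCBV P95, Ktrans P5, the TIZ GM-max threshold) is logged and
recorded in the report for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import decompose as dcmp
from . import hemodynamics as hemo
from . import io as tio
from . import pdr_tiz as pt
from . import qsm
from . import stats as st
from .phantom import LABEL_CODES, PhantomSpec, GroundTruth, build_labels, \
    assign_sources, simulate_gre, simulate_dsc, simulate_dce

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single source of truth for every tunable of a run."""

    out_dir: str = "tizmap_out"
    seed: int = 1234
    noise_sigma: float = 0.02
    # QSM
    erosion_mm: float = 3.0
    vsharp_max_radius_mm: float = 12.0
    vsharp_lam: float = 0.05
    tkd_threshold: float = 0.2
    iter_lam: float = 1e-2
    algorithms: tuple[str, ...] = ("tkd", "iterative")
    per_echo: bool = False  # reconstruct chi per echo and average
    # decomposition
    kappa: float | None = None  # None -> static-dephasing default at B0
    r2_baseline_mode: str = "label_table"  # or "contralateral_nawm"
    # in-mask Gaussian smoothing of echo magnitudes before the R2* fit;
    # the R2' map is SNR-starved voxelwise and PDR is an extreme-value
    # statistic, so the rate map is regularized at ~1 cm FWHM
    r2star_smooth_vox: float = 2.5
    # PDR / TIZ
    epsilon_ppm: float = 1e-4
    trim_pct: float = 95.0
    pooled_trim: bool = False
    # exclusion
    ncbv_percentile: float = 95.0
    ktrans_percentile: float = 5.0
    with_dsc_dce: bool = True
    # stats
    alpha: float = 0.05
    # phantom overrides (merged into PhantomSpec)
    phantom: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "algorithms" in raw:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["algorithms"] = list(d["algorithms"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["algorithms"] = list(d["algorithms"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]

    def phantom_spec(self) -> PhantomSpec:
        overrides = dict(self.phantom)
        return PhantomSpec(seed=self.seed, noise_sigma=self.noise_sigma, **overrides)


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline produced."""

    ground_truth: GroundTruth
    fields: qsm.FieldMaps
    chi_maps: dict[str, qsm.ChiMap]
    decompositions: dict[str, dcmp.DecompositionResult]
    perfusion: hemo.PerfusionResult | None
    permeability: hemo.PermeabilityResult | None
    exclusion: hemo.BloodExclusionMask | None
    pdr_maps: dict[str, pt.PdrMap]
    tiz_results: dict[str, pt.TizResult]
    report: st.StatsReport
    out_dir: Path


def _masks(labels) -> dict[str, np.ndarray]:
    lm = labels
    tumor = lm.mask("ed", "ncr", "et", "tiz")
    m = {
        "brain": lm.data > 0,
        "tumor": tumor,
        "edema": lm.mask("ed", "tiz"),
        "et": lm.mask("et"),
        "vessel": lm.mask("vessel"),
        "gm": lm.mask("gm"),
        "wm": lm.mask("wm"),
        "subcortical": lm.mask("subcortical"),
        "contralateral_tumor": pt.mirror_mask(tumor),
    }
    n = lm.shape[0]
    contra = np.zeros(lm.shape, dtype=bool)
    contra[: int(np.ceil((n - 1) / 2.0)), :, :] = True  # hemisphere opposite tumor
    m["contralateral_hemisphere"] = contra
    m["contra_gm"] = m["gm"] & contra
    m["contra_wm"] = m["wm"] & contra
    m["contra_subcortical"] = m["subcortical"] & contra
    return m


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.phantom_spec()
    vs = spec.voxel_size_mm

    # ---- phantom ---------------------------------------------------------
    labels = build_labels(spec)
    gt = assign_sources(labels, spec)
    gre = simulate_gre(gt, spec)
    masks = _masks(labels)
    tio.write_label_map(labels, out / "labels.nii.gz")
    tio.write_multi_echo(gre, out / "gre")

    # ---- qsm -------------------------------------------------------------
    radii = np.arange(config.vsharp_max_radius_mm, 0.0, -1.0)
    fields, chi_maps = qsm.reconstruct_chi(
        gre, masks["brain"], masks["tumor"], erosion_mm=config.erosion_mm,
        vsharp_radii_mm=radii, vsharp_lam=config.vsharp_lam,
        tkd_threshold=config.tkd_threshold, iter_lam=config.iter_lam,
        algorithms=config.algorithms, per_echo=config.per_echo)
    for tag, cm in chi_maps.items():
        tio.write_volume(cm.chi_ppm, out / f"chi_{tag}.nii.gz", vs)

    # ---- decomposition ---------------------------------------------------
    mags = np.stack([qsm.masked_gaussian_smooth(m, masks["brain"],
                                                config.r2star_smooth_vox)
                     for m in gre.magnitude])
    r2star, _ = qsm.fit_r2star(mags, gre.te_ms)
    if config.r2_baseline_mode == "label_table":
        baseline = np.zeros(labels.shape)
        code_to_name = {v: k for k, v in LABEL_CODES.items()}
        for code in np.unique(labels.data):
            tp = spec.tissue_params[code_to_name[int(code)]]
            baseline[labels.data == code] = tp.r2_s_inv
    else:  # contralateral NAWM median
        baseline = np.full(labels.shape, float(np.median(r2star[masks["contra_wm"]])))
    r2prime, clipped = dcmp.estimate_r2prime(r2star, baseline)
    kappa = config.kappa if config.kappa is not None else spec.kappa
    decomps = {}
    for tag, cm in chi_maps.items():
        decomps[tag] = dcmp.decompose_map(cm.chi_ppm, r2prime, kappa,
                                          mask=cm.mask, clipped_mask=clipped)
        tio.write_volume(decomps[tag].pcs_ppm, out / f"pcs_{tag}.nii.gz", vs)
        tio.write_volume(decomps[tag].dcs_ppm, out / f"dcs_{tag}.nii.gz", vs)

    # ---- hemodynamics ----------------------------------------------------
    perfusion = permeability = exclusion = None
    thresholds: dict[str, float] = {}
    if config.with_dsc_dce:
        dsc, _dsc_truth = simulate_dsc(labels, spec)
        n_baseline = max(int(spec.dsc_t0_s / spec.dsc_tr_s) - 2, 3)
        dr2s = hemo.dsc_to_delta_r2star(dsc.frames, dsc.te_ms, n_baseline)
        aif = hemo.select_aif(dr2s, masks["vessel"])
        ref_mask = (masks["wm"] | masks["gm"]) & ~masks["tumor"]
        corrected, k2 = hemo.leakage_correct(dr2s, ref_mask, dsc.times_s,
                                             fit_mask=masks["brain"])
        cbv = hemo.compute_cbv(corrected, aif, dsc.times_s)
        ncbv = hemo.normalize_cbv(cbv, masks["contra_wm"])
        perfusion = hemo.PerfusionResult(dr2s, aif, dsc.times_s, cbv, ncbv, k2)
        tio.write_volume(ncbv, out / "ncbv.nii.gz", vs)

        dce, vfa, _dce_truth = simulate_dce(labels, spec)
        t10, _m0, t1_flags = hemo.vfa_t1_fit(
            [v.data for v in vfa], spec.vfa_flip_deg, spec.dce_tr_ms)
        conc = hemo.dce_to_concentration(dce.frames, t10, dce.flip_angle_deg,
                                         dce.tr_ms, spec.r1_relaxivity)
        vif = conc[:, masks["vessel"]].mean(axis=1)
        permeability = hemo.fit_tofts_map(conc, vif, dce.times_s, masks["tumor"])
        permeability.t10_map_ms = t10
        tio.write_volume(permeability.ktrans_map, out / "ktrans.nii.gz", vs)

        exclusion = hemo.blood_exclusion_mask(
            ncbv, permeability.ktrans_map, masks["tumor"],
            masks["contralateral_tumor"], masks["et"],
            ktrans_valid=permeability.fit_flags)
        thresholds["thr_ncbv"] = exclusion.thr_ncbv
        log.info("threshold thr_ncbv=%.4f", exclusion.thr_ncbv)
        if exclusion.thr_ktrans is not None:
            thresholds["thr_ktrans"] = exclusion.thr_ktrans
            log.info("threshold thr_ktrans=%.4f", exclusion.thr_ktrans)
        tio.write_volume(exclusion.mask, out / "blood_exclusion.nii.gz", vs)
    else:
        log.warning("DSC/DCE disabled: TIZ computed with empty exclusion mask")

    # ---- PDR + TIZ per algorithm ----------------------------------------
    excl_mask = exclusion.mask if exclusion is not None else None
    pdr_maps: dict[str, pt.PdrMap] = {}
    tiz_results: dict[str, pt.TizResult] = {}
    pdr_by_roi: dict[str, np.ndarray] = {}
    for tag, dec in decomps.items():
        pm = pt.compute_pdr(dec.pcs_ppm, dec.dcs_ppm, chi_maps[tag].mask,
                            config.epsilon_ppm)
        pdr_maps[tag] = pm
        valid = pm.valid_mask
        gm_ref = masks["contra_gm"] & valid
        wm_ref = masks["contra_wm"] & valid
        trimmed_gm, trimmed_wm = pt.reference_trim(
            pm.pdr, gm_ref, wm_ref, masks["contra_subcortical"],
            trim_pct=config.trim_pct, pooled=config.pooled_trim)
        thr = pt.tiz_threshold(trimmed_gm)
        tiz = pt.segment_tiz(pm.pdr, masks["edema"] & valid, excl_mask, thr,
                             provenance=tag)
        tiz.trimmed_gm_values = trimmed_gm
        tiz.trimmed_wm_values = trimmed_wm
        tiz_results[tag] = tiz
        thresholds[f"theta_tiz_{tag}"] = thr
        log.info("threshold theta_tiz[%s]=%.4f", tag, thr)
        tio.write_volume(pm.pdr, out / f"pdr_{tag}.nii.gz", vs)
        tio.write_volume(tiz.tiz_mask, out / f"tiz_{tag}.nii.gz", vs)
        if tiz.tiz_mask.any():
            pdr_by_roi[f"tiz_{tag}"] = pm.pdr[tiz.tiz_mask]
            contra_tiz = pt.mirror_mask(tiz.tiz_mask) & valid
            if contra_tiz.any():
                pdr_by_roi[f"contralateral_tiz_{tag}"] = pm.pdr[contra_tiz]
            rest = masks["edema"] & valid & ~tiz.tiz_mask
            if excl_mask is not None:
                rest &= ~excl_mask
            if rest.any():
                pdr_by_roi[f"edema_rest_{tag}"] = pm.pdr[rest]

    dice_values = {}
    tags = list(tiz_results)
    if len(tags) == 2:
        dice_values["tiz_cross_algorithm"] = pt.dice(
            tiz_results[tags[0]].tiz_mask, tiz_results[tags[1]].tiz_mask)
    for tag, tiz in tiz_results.items():
        dice_values[f"tiz_{tag}_vs_truth"] = pt.dice(tiz.tiz_mask, gt.tiz_truth)

    # ---- statistics ------------------------------------------------------
    comparisons = []
    for tag in tags:
        comparisons.append((f"tiz_{tag}", f"contralateral_tiz_{tag}"))
        comparisons.append((f"tiz_{tag}", f"edema_rest_{tag}"))
    volumes = {f"tiz_{t}_voxels": float(tiz_results[t].tiz_mask.sum()) for t in tags}
    volumes["edema_voxels"] = float(masks["edema"].sum())
    # floor PDR values for log features (epsilon already floors the ratio
    # denominator; zero PCS still yields PDR = 0)
    pdr_by_roi = {k: np.clip(v, 1e-6, None) for k, v in pdr_by_roi.items()}
    report = st.build_report(
        pdr_by_roi=pdr_by_roi, comparisons=comparisons,
        dice_values=dice_values, thresholds=thresholds, volumes=volumes,
        alpha=config.alpha,
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "kappa": kappa})
    (out / "report.json").write_text(report.to_json(indent=2))
    config.to_yaml(out / "config.yaml")
    return PipelineResult(gt, fields, chi_maps, decomps, perfusion,
                          permeability, exclusion, pdr_maps, tiz_results,
                          report, out)
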