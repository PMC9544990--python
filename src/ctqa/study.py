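"""End-to-end synthetic study: simulate, measure, compare.

``run_study`` reproduces the design of a multi-dose, multi-preset phantom
study on synthetic data: for every (preset, dose) it simulates a uniform
section for the NPS (pooling ROIs across the acquisitions) and an insert
section for the circular-edge TTF, computes the NPWE detectability of each
chest task from the measured TTF/NPS, then summarizes every preset against
the flagged reference (mean relative differences over the dose levels) and
converts the d'-dose curves into dose-reduction potentials at the matching
reference dose.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dose as dose_mod
from .config import StudyConfig
from .nps import NPSResult, RoiSpec, compute_nps, extract_rois
from .observer import designer_task_function, dprime_npwe
from .phantom import (
    AcquisitionPlan,
    Insert,
    NoiseSpectrum,
    PhantomGeometry,
    ReconPreset,
    simulate_stack,
)
from .ttf import TTFResult, measure_ttf

logger = logging.getLogger("ctqa.study")

__all__ = [
    "StudyReport",
    "default_study_config",
    "run_study",
    "measure_nps_point",
    "measure_ttf_point",
]


@dataclass
class StudyReport:
    """Tables produced by one full study run."""

    nps: pd.DataFrame            # preset, dose, noise_magnitude, f_av, f_peak, n_rois
    ttf: pd.DataFrame            # preset, dose, insert, ttf50, contrast, cnr, conditioned
    dprime: pd.DataFrame         # task, preset, dose, d_prime, inputs_hash
    comparisons: pd.DataFrame    # metric, preset, mean_pct, sd_pct
    dose_reduction: pd.DataFrame # task, preset, matched dose, reduction
    nps_results: dict = field(default_factory=dict)   # (preset, dose) -> NPSResult
    ttf_results: dict = field(default_factory=dict)   # (preset, dose, insert) -> TTFResult
    logs: list = field(default_factory=list)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("nps", "ttf", "dprime", "comparisons", "dose_reduction"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)


def default_study_config(seed: int = 0) -> StudyConfig:
    """The synthetic study emulating the phantom protocol.

    20-cm water-equivalent body with 25-mm polyethylene (-95 HU) and air
    (-1000 HU) inserts; doses 9.5/7.5/6/2.5/0.4 mGy, five acquisitions per
    dose, 50 slices per acquisition for NPS and 30 for TTF; three presets
    spanning a smooth/standard/sharp noise-resolution trade-off with the
    middle one flagged as the clinical reference.
    """
    geometry = PhantomGeometry(
        body_diameter=200.0,
        background_hu=0.0,
        inserts=(
            Insert("polyethylene", (-45.0, 0.0), 25.0, -95.0),
            Insert("air", (45.0, 0.0), 25.0, -1000.0),
        ),
    )
    presets = (
        ReconPreset("smoother", psf_sigma=1.1, noise_scale=0.45,
                    nps_shape=NoiseSpectrum(f_peak=0.15)),
        ReconPreset("reference", psf_sigma=0.8, noise_scale=1.0,
                    nps_shape=NoiseSpectrum(f_peak=0.25)),
        ReconPreset("sharper", psf_sigma=0.6, noise_scale=1.6,
                    nps_shape=NoiseSpectrum(f_peak=0.40)),
    )
    plan = AcquisitionPlan(
        ctdivol_levels=(9.5, 7.5, 6.0, 2.5, 0.4),
        reference_dose=9.5,
        reference_noise_sd=10.0,
        n_slices_per_acquisition=50,
        n_acquisitions=5,
        seed=int(seed),
    )
    # four 128-px ROIs at (+/-35, +/-35) mm, fully inside the uniform body
    n = plan.n_pixels
    off = int(round(35.0 / plan.pixel_mm))
    centers = tuple(
        (n // 2 + sy * off, n // 2 + sx * off) for sy, sx in
        ((-1, -1), (-1, 1), (1, -1), (1, 1))
    )
    return StudyConfig(
        geometry=geometry,
        presets=presets,
        reference_preset="reference",
        plan=plan,
        roi=RoiSpec(centers=centers, size=128),
    )


def measure_nps_point(cfg: StudyConfig, preset: ReconPreset, dose: float) -> NPSResult:
    """NPS of the uniform section for one (preset, dose)."""
    stack = simulate_stack(
        cfg.uniform_geometry, preset, cfg.plan, dose,
        n_slices=cfg.plan.n_slices_total, module="nps",
    )
    rois = extract_rois(stack, cfg.roi)
    return compute_nps(rois, stack.pixel_mm)


def measure_ttf_point(
    cfg: StudyConfig, preset: ReconPreset, dose: float
) -> dict[str, TTFResult]:
    """Circular-edge TTF of every insert for one (preset, dose)."""
    n_slices = cfg.ttf_slices_per_acquisition * cfg.plan.n_acquisitions
    stack = simulate_stack(
        cfg.geometry, preset, cfg.plan, dose, n_slices=n_slices, module="ttf",
    )
    return {
        ins.label: measure_ttf(stack, ins.label)
        for ins in cfg.geometry.inserts
    }


def run_study(cfg: StudyConfig, outdir=None) -> StudyReport:
    """Run the full study described by ``cfg``; deterministic given its seed."""
    tasks = {
        name: designer_task_function(
            contrast, diameter=cfg.task_diameter_mm, matrix=cfg.task_matrix,
            pixel_mm=cfg.task_pixel_mm,
            transition_fraction=cfg.task_transition_fraction, label=name,
        )
        for name, contrast in sorted(cfg.task_contrasts.items())
    }

    nps_rows, ttf_rows, dp_rows, logs = [], [], [], []
    nps_results, ttf_results = {}, {}
    doses = sorted(cfg.plan.ctdivol_levels)
    for preset, dose in itertools.product(cfg.presets, doses):
        logger.info("measuring preset=%s dose=%.2f mGy", preset.name, dose)
        nps_res = measure_nps_point(cfg, preset, dose)
        nps_results[(preset.name, dose)] = nps_res
        nps_rows.append({
            "preset": preset.name, "dose_mgy": dose,
            "noise_magnitude_hu": nps_res.noise_magnitude,
            "f_av_cyc_mm": nps_res.f_av, "f_peak_cyc_mm": nps_res.f_peak,
            "n_rois": nps_res.n_rois,
        })
        ttfs = measure_ttf_point(cfg, preset, dose)
        for label, res in ttfs.items():
            ttf_results[(preset.name, dose, label)] = res
            ttf_rows.append({
                "preset": preset.name, "dose_mgy": dose, "insert": label,
                "ttf50_cyc_mm": res.ttf50, "contrast_hu": res.contrast,
                "cnr_total": res.cnr_total,
                "conditioning_applied": res.conditioning_applied,
                "n_slices_averaged": res.n_slices_averaged,
            })
            if res.conditioning_applied:
                logs.append({
                    "stage": "ttf", "event": "esf_conditioning",
                    "preset": preset.name, "dose_mgy": dose, "insert": label,
                    "cnr_total": res.cnr_total,
                })
        for name, task in tasks.items():
            ttf_res = ttfs[cfg.task_insert[name]]
            point = dprime_npwe(task, ttf=ttf_res, nps=nps_res,
                                viewing=cfg.viewing, dose_mgy=dose,
                                preset=preset.name)
            dp_rows.append({
                "task": name, "preset": preset.name, "dose_mgy": dose,
                "d_prime": point.d_prime, "insert": cfg.task_insert[name],
                "inputs_hash": point.inputs_hash,
            })

    nps_df = pd.DataFrame(nps_rows)
    ttf_df = pd.DataFrame(ttf_rows)
    dp_df = pd.DataFrame(dp_rows)

    comparisons = _compare_to_reference(cfg, nps_df, ttf_df, dp_df)
    reduction_df = _dose_reduction(cfg, dp_df, logs)

    report = StudyReport(
        nps=nps_df, ttf=ttf_df, dprime=dp_df,
        comparisons=comparisons, dose_reduction=reduction_df,
        nps_results=nps_results, ttf_results=ttf_results, logs=logs,
    )
    if outdir is not None:
        report.write(outdir)
    return report


def _series(df: pd.DataFrame, preset: str, value: str, by: dict | None = None) -> np.ndarray:
    sel = df[df["preset"] == preset]
    for col, val in (by or {}).items():
        sel = sel[sel[col] == val]
    return sel.sort_values("dose_mgy")[value].to_numpy()


def _compare_to_reference(cfg, nps_df, ttf_df, dp_df) -> pd.DataFrame:
    ref = cfg.reference_preset
    rows = []
    others = [p.name for p in cfg.presets if p.name != ref]
    doses = np.sort(np.unique(nps_df["dose_mgy"]))
    for preset in others:
        for metric, df, value, by_col in (
            ("noise_magnitude", nps_df, "noise_magnitude_hu", None),
            ("f_av", nps_df, "f_av_cyc_mm", None),
            ("ttf50", ttf_df, "ttf50_cyc_mm", "insert"),
            ("d_prime", dp_df, "d_prime", "task"),
        ):
            groups = [None] if by_col is None else sorted(df[by_col].unique())
            for g in groups:
                by = None if g is None else {by_col: g}
                summary = dose_mod.summarize_pair(
                    doses,
                    _series(df, preset, value, by),
                    _series(df, ref, value, by),
                    metric=metric if g is None else f"{metric}[{g}]",
                )
                rows.append({
                    "metric": summary.metric, "preset": preset,
                    "reference": ref, "mean_pct": summary.mean_pct,
                    "sd_pct": summary.sd_pct,
                })
    return pd.DataFrame(rows)


def _dose_reduction(cfg, dp_df, logs) -> pd.DataFrame:
    ref = cfg.reference_preset
    ref_dose = cfg.matching_reference_dose
    rows = []
    for task in sorted(dp_df["task"].unique()):
        sub = dp_df[dp_df["task"] == task]
        ref_sub = sub[sub["preset"] == ref].sort_values("dose_mgy")
        ref_curve = dose_mod.fit_dose_curve(
            ref_sub["dose_mgy"], ref_sub["d_prime"], task=task, preset=ref
        )
        ref_dprime = float(ref_curve.predict(ref_dose))
        if ref_dose > ref_curve.doses.max():
            logs.append({
                "stage": "dose_matching", "event": "reference_extrapolated",
                "task": task, "reference_dose": ref_dose,
                "max_measured_dose": float(ref_curve.doses.max()),
            })
        for preset in sorted(sub["preset"].unique()):
            if preset == ref:
                continue
            psub = sub[sub["preset"] == preset].sort_values("dose_mgy")
            curve = dose_mod.fit_dose_curve(
                psub["dose_mgy"], psub["d_prime"], task=task, preset=preset
            )
            res = dose_mod.dose_reduction_potential(curve, ref_dprime, ref_dose)
            rows.append({
                "task": task, "preset": preset,
                "reference_dprime": ref_dprime,
                "reference_dose_mgy": ref_dose,
                "fit_a": curve.a, "fit_b": curve.b,
                **res,
            })
    return pd.DataFrame(rows)
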