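"""Study configuration: geometry, presets, plan, tasks, viewing conditions.

A :class:`StudyConfig` bundles everything needed to reproduce the full
synthetic study: the insert-module geometry, the reconstruction presets
(one flagged as the clinical reference), the dose/acquisition plan, the
ROI layout for NPS, the detection tasks with their insert pairing, and the
display conditions.  Configurations round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .nps import RoiSpec
from .observer import ViewingConditions
from .phantom import AcquisitionPlan, Insert, NoiseSpectrum, PhantomGeometry, ReconPreset

__all__ = ["StudyConfig", "load_config", "save_config"]


@dataclass
class StudyConfig:
    geometry: PhantomGeometry
    presets: tuple[ReconPreset, ...]
    reference_preset: str
    plan: AcquisitionPlan
    roi: RoiSpec
    task_contrasts: dict[str, float] = field(
        default_factory=lambda: {"LCN": 50.0, "GGO": 200.0, "HCP": 950.0}
    )
    task_insert: dict[str, str] = field(
        default_factory=lambda: {"LCN": "polyethylene", "GGO": "polyethylene", "HCP": "air"}
    )
    task_diameter_mm: float = 5.0
    task_matrix: int = 300
    task_pixel_mm: float = 0.05
    task_transition_fraction: float = 0.1
    viewing: ViewingConditions = field(default_factory=ViewingConditions)
    ttf_slices_per_acquisition: int = 30
    matching_reference_dose: float = 10.0

    def __post_init__(self) -> None:
        self.presets = tuple(self.presets)
        names = [p.name for p in self.presets]
        if len(set(names)) != len(names):
            raise ValueError("preset names must be unique")
        if self.reference_preset not in names:
            raise ValueError(
                f"reference preset {self.reference_preset!r} is not among the presets"
            )
        labels = {ins.label for ins in self.geometry.inserts}
        for task, insert in self.task_insert.items():
            if insert not in labels:
                raise ValueError(f"task {task!r} paired with unknown insert {insert!r}")
        missing = set(self.task_contrasts) - set(self.task_insert)
        if missing:
            raise ValueError(f"tasks without an insert pairing: {sorted(missing)}")

    @property
    def uniform_geometry(self) -> PhantomGeometry:
        """The insert-free (uniform-section) geometry used for NPS stacks."""
        return PhantomGeometry(
            body_diameter=self.geometry.body_diameter,
            background_hu=self.geometry.background_hu,
            inserts=(),
        )

    def preset(self, name: str) -> ReconPreset:
        for p in self.presets:
            if p.name == name:
                return p
        raise KeyError(name)


def _geometry_to_dict(g: PhantomGeometry) -> dict:
    return {
        "body_diameter": g.body_diameter,
        "background_hu": g.background_hu,
        "inserts": [
            {
                "label": i.label,
                "center_offset": list(i.center_offset),
                "diameter": i.diameter,
                "hu": i.hu,
            }
            for i in g.inserts
        ],
    }


def _geometry_from_dict(d: dict) -> PhantomGeometry:
    return PhantomGeometry(
        body_diameter=d.get("body_diameter", 200.0),
        background_hu=d.get("background_hu", 0.0),
        inserts=tuple(
            Insert(
                label=i["label"],
                center_offset=tuple(i["center_offset"]),
                diameter=i["diameter"],
                hu=i["hu"],
            )
            for i in d.get("inserts", [])
        ),
    )


def _preset_to_dict(p: ReconPreset) -> dict:
    return {
        "name": p.name,
        "psf_sigma": p.psf_sigma,
        "noise_scale": p.noise_scale,
        "nps_shape": {"f_peak": p.nps_shape.f_peak, "bandwidth": p.nps_shape.bandwidth},
    }


def _preset_from_dict(d: dict) -> ReconPreset:
    shape = d.get("nps_shape", {})
    return ReconPreset(
        name=d["name"],
        psf_sigma=d["psf_sigma"],
        noise_scale=d.get("noise_scale", 1.0),
        nps_shape=NoiseSpectrum(
            f_peak=shape.get("f_peak", 0.0), bandwidth=shape.get("bandwidth")
        ),
    )


def to_dict(cfg: StudyConfig) -> dict:
    return {
        "geometry": _geometry_to_dict(cfg.geometry),
        "presets": [_preset_to_dict(p) for p in cfg.presets],
        "reference_preset": cfg.reference_preset,
        "plan": {
            "ctdivol_levels": list(cfg.plan.ctdivol_levels),
            "reference_dose": cfg.plan.reference_dose,
            "reference_noise_sd": cfg.plan.reference_noise_sd,
            "n_slices_per_acquisition": cfg.plan.n_slices_per_acquisition,
            "n_acquisitions": cfg.plan.n_acquisitions,
            "seed": cfg.plan.seed,
            "n_pixels": cfg.plan.n_pixels,
            "pixel_mm": cfg.plan.pixel_mm,
        },
        "roi": {"centers": [list(c) for c in cfg.roi.centers], "size": cfg.roi.size},
        "tasks": {
            "contrasts": dict(cfg.task_contrasts),
            "inserts": dict(cfg.task_insert),
            "diameter_mm": cfg.task_diameter_mm,
            "matrix": cfg.task_matrix,
            "pixel_mm": cfg.task_pixel_mm,
            "transition_fraction": cfg.task_transition_fraction,
        },
        "viewing": {
            "zoom": cfg.viewing.zoom,
            "distance_mm": cfg.viewing.distance_mm,
            "gamma": cfg.viewing.gamma,
            "c": cfg.viewing.c,
        },
        "ttf_slices_per_acquisition": cfg.ttf_slices_per_acquisition,
        "matching_reference_dose": cfg.matching_reference_dose,
    }


def from_dict(d: dict) -> StudyConfig:
    tasks = d.get("tasks", {})
    viewing = d.get("viewing", {})
    plan = d["plan"]
    return StudyConfig(
        geometry=_geometry_from_dict(d["geometry"]),
        presets=tuple(_preset_from_dict(p) for p in d["presets"]),
        reference_preset=d["reference_preset"],
        plan=AcquisitionPlan(
            ctdivol_levels=tuple(plan["ctdivol_levels"]),
            reference_dose=plan["reference_dose"],
            reference_noise_sd=plan["reference_noise_sd"],
            n_slices_per_acquisition=plan["n_slices_per_acquisition"],
            n_acquisitions=plan["n_acquisitions"],
            seed=plan.get("seed", 0),
            n_pixels=plan.get("n_pixels", 512),
            pixel_mm=plan.get("pixel_mm", 250.0 / 512.0),
        ),
        roi=RoiSpec(
            centers=tuple(tuple(c) for c in d["roi"]["centers"]),
            size=d["roi"].get("size", 128),
        ),
        task_contrasts=dict(tasks.get("contrasts", {"LCN": 50.0, "GGO": 200.0, "HCP": 950.0})),
        task_insert=dict(tasks.get("inserts", {"LCN": "polyethylene", "GGO": "polyethylene", "HCP": "air"})),
        task_diameter_mm=tasks.get("diameter_mm", 5.0),
        task_matrix=tasks.get("matrix", 300),
        task_pixel_mm=tasks.get("pixel_mm", 0.05),
        task_transition_fraction=tasks.get("transition_fraction", 0.1),
        viewing=ViewingConditions(
            zoom=viewing.get("zoom", 1.5),
            distance_mm=viewing.get("distance_mm", 500.0),
            gamma=viewing.get("gamma", 1.3),
            c=viewing.get("c", 0.325),
        ),
        ttf_slices_per_acquisition=d.get("ttf_slices_per_acquisition", 30),
        matching_reference_dose=d.get("matching_reference_dose", 10.0),
    )


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))


def save_config(cfg: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=False)
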