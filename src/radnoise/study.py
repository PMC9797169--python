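"""Study orchestration: the two synthetic phantom experiments.

``run_chest_experiment`` sweeps the chest scene over five dose stations and
all configured denoiser settings: repeat pairs are generated, both members
processed, noise-only images formed, ROI noise reductions, lung/rib line
profiles and 10-90 rise distances computed, and pixel-identical settings
collapsed into equivalence classes.

``run_solid_water_experiment`` sweeps two uniform phantom arms (10 and 20 cm)
over their dose grids: for every (thickness, dose, setting) it estimates the
repeat-subtraction NPS (pair-subtraction convention) and the texture NPS of
processed - baseline, tabulating radial spectra, peak frequencies and
high-frequency indices.

``write_report`` emits CSV tables, overview plots and a JSON run manifest;
identical config + seed reproduce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .denoise import DenoiserParams, apply_surrogate_denoiser
from .metrics import (
    ROISpec,
    deviation_index,
    edge_rise_distance,
    extract_line_profile,
    group_identical,
    roi_sd,
    subtract_repeats,
    synthetic_exposure_index,
    NoEdgeError,
)
from .nps import NPSGeometry, high_frequency_index, repeat_subtraction_nps, texture_nps
from .radiograph import InvalidArgumentError, NoiseModel, Radiograph
from .scene import ChestSceneSpec
from .simulate import derive_seed, generate_chest_pair, generate_uniform_pair

logger = logging.getLogger("radnoise")

BASELINE_CODE = "none"

#: Noise model shared by the study arms: quantum gain, small electronic
#: floor, pre-sampling blur and the processing-chain unsharp term that gives
#: the baseline NPS its mid-band peak.
_DEFAULT_NOISE = NoiseModel(gain=1.5, electronic_sd=4.0, blur_sigma=0.7,
                            sharpen_amount=0.8, sharpen_sigma=1.5)


@dataclass(frozen=True)
class ChestArmConfig:
    """Chest-phantom experiment: dose grid, scene, ROIs and profile."""

    doses: tuple[float, ...] = (0.7, 1.0, 1.4, 1.8, 2.2)
    ref_mas: float = 1.4
    scene: ChestSceneSpec = field(default_factory=ChestSceneSpec)
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(
        gain=1.0, electronic_sd=3.0, blur_sigma=0.7, sharpen_amount=0.8, sharpen_sigma=1.5))
    pitch: float = 0.15
    lung_roi: ROISpec = field(default_factory=lambda: ROISpec("lung", 186, 118, 36, 56))
    liver_roi: ROISpec = field(default_factory=lambda: ROISpec("liver", 400, 200, 56, 80))
    profile_start: tuple[float, float] = (132.0, 150.0)
    profile_end: tuple[float, float] = (176.0, 150.0)
    profile_width: int = 5
    profile_samples: int = 241


@dataclass(frozen=True)
class SolidWaterArmConfig:
    """One uniform-phantom arm: thickness label, dose grid and signal level.

    The 20 cm arm transmits less, so at its (higher) reference mAs it reaches
    the same detector signal as the 10 cm arm at its reference — the
    deviation index is 0 at ``ref_mas`` in both arms.
    """

    thickness: str
    doses: tuple[float, ...]
    ref_mas: float
    mean_at_ref: float = 2000.0
    shape: tuple[int, int] = (768, 768)
    noise: NoiseModel = field(default_factory=lambda: _DEFAULT_NOISE)
    pitch: float = 0.15


def _default_solid_water_arms() -> tuple[SolidWaterArmConfig, ...]:
    return (
        SolidWaterArmConfig("10cm", (0.32, 0.4, 0.5, 0.63, 0.8), ref_mas=0.4),
        SolidWaterArmConfig("20cm", (0.9, 1.4, 1.8, 2.2, 2.8, 3.6), ref_mas=1.8),
    )


@dataclass(frozen=True)
class StudyConfig:
    """Full sweep specification for both experiments.

    ``settings`` are denoiser code strings; ``"none"`` (the unprocessed
    baseline) is always included.  ``quantization_step`` (detector units) is
    the output quantization at which pixel-identity of settings is judged.
    """

    settings: tuple[str, ...] = (
        BASELINE_CODE, "CGA0.5", "CGB0.5", "CGC0.5", "FGA0.5", "FGB0.5", "FGC0.5",
    )
    chest: ChestArmConfig = field(default_factory=ChestArmConfig)
    solid_water: tuple[SolidWaterArmConfig, ...] = field(default_factory=_default_solid_water_arms)
    nps_geometry: NPSGeometry = field(default_factory=NPSGeometry)
    target_ei: float = 625.0
    quantization_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if BASELINE_CODE not in self.settings:
            object.__setattr__(self, "settings", (BASELINE_CODE, *self.settings))
        for code in self.settings:
            if code != BASELINE_CODE:
                DenoiserParams.from_code(code)  # validates
        if any(d <= 0 for arm in self.solid_water for d in arm.doses):
            raise InvalidArgumentError("all dose values must be > 0")
        if any(d <= 0 for d in self.chest.doses):
            raise InvalidArgumentError("all dose values must be > 0")

    @classmethod
    def default(cls) -> "StudyConfig":
        return cls()

    def to_yaml(self) -> str:
        return yaml.safe_dump(_to_plain(dataclasses.asdict(self)), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        data = yaml.safe_load(text) or {}
        return cls(
            settings=tuple(data.get("settings", cls().settings)),
            chest=_chest_from_dict(data.get("chest", {})),
            solid_water=tuple(_arm_from_dict(a) for a in data["solid_water"])
            if "solid_water" in data else _default_solid_water_arms(),
            nps_geometry=_geom_from_dict(data.get("nps_geometry", {})),
            target_ei=float(data.get("target_ei", 625.0)),
            quantization_step=float(data.get("quantization_step", 1.0)),
            seed=int(data.get("seed", 0)),
        )


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _noise_from_dict(d: dict) -> NoiseModel:
    return NoiseModel(**d) if d else _DEFAULT_NOISE


def _geom_from_dict(d: dict) -> NPSGeometry:
    if not d:
        return NPSGeometry()
    if d.get("center") is not None:
        d = {**d, "center": tuple(d["center"])}
    return NPSGeometry(**d)


def _roi_from_dict(d: dict) -> ROISpec:
    return ROISpec(**d)


def _scene_from_dict(d: dict) -> ChestSceneSpec:
    if not d:
        return ChestSceneSpec()
    kw = dict(d)
    for key in ("shape", "rib_rows", "rib_col_range", "liver_box"):
        if key in kw:
            kw[key] = tuple(kw[key])
    if "lung_ellipses" in kw:
        kw["lung_ellipses"] = tuple(tuple(e) for e in kw["lung_ellipses"])
    return ChestSceneSpec(**kw)


def _chest_from_dict(d: dict) -> ChestArmConfig:
    if not d:
        return ChestArmConfig()
    kw = dict(d)
    if "doses" in kw:
        kw["doses"] = tuple(kw["doses"])
    if "scene" in kw:
        kw["scene"] = _scene_from_dict(kw["scene"])
    if "noise" in kw:
        kw["noise"] = NoiseModel(**kw["noise"])
    for key in ("lung_roi", "liver_roi"):
        if key in kw:
            kw[key] = _roi_from_dict(kw[key])
    for key in ("profile_start", "profile_end"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return ChestArmConfig(**kw)


def _arm_from_dict(d: dict) -> SolidWaterArmConfig:
    kw = dict(d)
    kw["doses"] = tuple(kw["doses"])
    if "shape" in kw:
        kw["shape"] = tuple(kw["shape"])
    if "noise" in kw:
        kw["noise"] = NoiseModel(**kw["noise"])
    return SolidWaterArmConfig(**kw)


def _parse_settings(settings: tuple[str, ...]) -> dict[str, DenoiserParams | None]:
    return {
        code: (None if code == BASELINE_CODE else DenoiserParams.from_code(code))
        for code in settings
    }


def _process(img: Radiograph, params: DenoiserParams | None, ref_mas: float) -> Radiograph:
    if params is None:
        return img
    return apply_surrogate_denoiser(img, params, ref_mas)


@dataclass
class ChestStudyResult:
    """Tables of the chest-phantom experiment."""

    reductions: pd.DataFrame     # setting_code, mas, di, roi, sd_baseline, sd_processed, reduction_percent
    profiles: pd.DataFrame       # setting_code, mas, position_mm, value
    rise_distances: pd.DataFrame  # setting_code, mas, rise_mm
    classes: pd.DataFrame        # mas, class_id, setting_code


@dataclass
class SolidWaterStudyResult:
    """Tables of the solid-water NPS experiment."""

    radial: pd.DataFrame   # thickness, mas, setting_code, kind, frequency, nps
    summary: pd.DataFrame  # thickness, mas, setting_code, peak_frequency, texture_variance, hf_index
    classes: pd.DataFrame  # thickness, mas, class_id, setting_code


def run_chest_experiment(config: StudyConfig) -> ChestStudyResult:
    """Chest-phantom noise, profile and redundancy analysis over the dose grid."""
    arm = config.chest
    settings = _parse_settings(config.settings)
    red_rows, prof_rows, rise_rows, class_rows = [], [], [], []
    for i, mas in enumerate(arm.doses):
        seed = derive_seed(config.seed, 0, i)
        a, b = generate_chest_pair(arm.scene, mas, arm.ref_mas, arm.noise,
                                   pitch=arm.pitch, seed=seed)
        di = deviation_index(synthetic_exposure_index(mas, arm.ref_mas, config.target_ei),
                             config.target_ei)
        baseline_noise_only = subtract_repeats(a, b)
        sd_base = {roi.label: roi_sd(baseline_noise_only, roi)
                   for roi in (arm.lung_roi, arm.liver_roi)}
        processed_a: dict[str, Radiograph] = {}
        for code, params in settings.items():
            pa = _process(a, params, arm.ref_mas)
            pb = _process(b, params, arm.ref_mas)
            processed_a[code] = pa
            noise_only = subtract_repeats(pa, pb)
            if code != BASELINE_CODE:
                for roi in (arm.lung_roi, arm.liver_roi):
                    sd_proc = roi_sd(noise_only, roi)
                    red_rows.append({
                        "setting_code": code, "mas": mas, "di": di, "roi": roi.label,
                        "sd_baseline": sd_base[roi.label], "sd_processed": sd_proc,
                        "reduction_percent":
                            100.0 * (sd_base[roi.label] - sd_proc) / sd_base[roi.label],
                    })
            profile = extract_line_profile(pa, arm.profile_start, arm.profile_end,
                                           arm.profile_width, arm.profile_samples)
            for pos, val in zip(profile.positions, profile.values):
                prof_rows.append({"setting_code": code, "mas": mas,
                                  "position_mm": pos, "value": val})
            try:
                rise = edge_rise_distance(profile)
            except NoEdgeError:
                rise = np.nan
            rise_rows.append({"setting_code": code, "mas": mas, "rise_mm": rise})
        for class_id, members in enumerate(
                group_identical(processed_a, config.quantization_step)):
            for code in members:
                class_rows.append({"mas": mas, "class_id": class_id, "setting_code": code})
        logger.info("chest: mas=%.2f done (%d settings)", mas, len(settings))
    return ChestStudyResult(
        reductions=pd.DataFrame(red_rows),
        profiles=pd.DataFrame(prof_rows),
        rise_distances=pd.DataFrame(rise_rows),
        classes=pd.DataFrame(class_rows),
    )


def run_solid_water_experiment(config: StudyConfig) -> SolidWaterStudyResult:
    """Solid-water NPS analysis over both thickness arms and dose grids."""
    geom = config.nps_geometry
    settings = _parse_settings(config.settings)
    radial_rows, summary_rows, class_rows = [], [], []
    for t, arm in enumerate(config.solid_water):
        min_side = geom.min_side
        if arm.shape[0] < min_side or arm.shape[1] < min_side:
            raise InvalidArgumentError(
                f"solid-water image {arm.shape} smaller than NPS geometry minimum {min_side}")
        for i, mas in enumerate(arm.doses):
            seed = derive_seed(config.seed, 1, t, i)
            a, b = generate_uniform_pair(arm.shape, arm.mean_at_ref, mas, arm.ref_mas,
                                         arm.noise, pitch=arm.pitch, seed=seed,
                                         label=f"solid_water_{arm.thickness}")
            processed_a: dict[str, Radiograph] = {}
            for code, params in settings.items():
                pa = _process(a, params, arm.ref_mas)
                pb = _process(b, params, arm.ref_mas)
                processed_a[code] = pa
                rep = repeat_subtraction_nps(pa, pb, geom)
                for f, v in zip(rep.freq, rep.nps1d):
                    if np.isfinite(v):
                        radial_rows.append({
                            "thickness": arm.thickness, "mas": mas, "setting_code": code,
                            "kind": "repeat_subtraction", "frequency": f, "nps": v})
                row = {"thickness": arm.thickness, "mas": mas, "setting_code": code,
                       "peak_frequency": rep.peak_frequency,
                       "texture_variance": 0.0, "hf_index": 0.0}
                if code != BASELINE_CODE:
                    tex = texture_nps(pa, a, geom)
                    for f, v in zip(tex.freq, tex.nps1d):
                        if np.isfinite(v):
                            radial_rows.append({
                                "thickness": arm.thickness, "mas": mas, "setting_code": code,
                                "kind": "texture", "frequency": f, "nps": v})
                    row["texture_variance"] = tex.variance_integral
                    row["hf_index"] = high_frequency_index(tex)
                summary_rows.append(row)
            for class_id, members in enumerate(
                    group_identical(processed_a, config.quantization_step)):
                for code in members:
                    class_rows.append({"thickness": arm.thickness, "mas": mas,
                                       "class_id": class_id, "setting_code": code})
            logger.info("solid water %s: mas=%.2f done", arm.thickness, mas)
    return SolidWaterStudyResult(
        radial=pd.DataFrame(radial_rows),
        summary=pd.DataFrame(summary_rows),
        classes=pd.DataFrame(class_rows),
    )


def write_report(
    outdir: str | Path,
    config: StudyConfig,
    chest: ChestStudyResult | None = None,
    solid_water: SolidWaterStudyResult | None = None,
    version: str | None = None,
) -> list[Path]:
    """Write CSV tables, overview plots and the run manifest to ``outdir``.

    Returns the list of files written.  An empty result set still produces a
    manifest (with a warning logged).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    if chest is not None and len(chest.reductions):
        _csv(chest.reductions, "chest_reductions.csv")
        _csv(chest.profiles, "chest_profiles.csv")
        _csv(chest.rise_distances, "chest_rise_distances.csv")
        _csv(chest.classes, "chest_equivalence_classes.csv")

        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, roi in zip(axes, ("lung", "liver")):
            sub = chest.reductions[chest.reductions.roi == roi]
            for code, grp in sub.groupby("setting_code"):
                ax.plot(grp.mas, grp.reduction_percent, marker="o", label=code)
            ax.set_xlabel("mAs")
            ax.set_title(f"{roi} ROI")
        axes[0].set_ylabel("noise reduction (%)")
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        path = outdir / "chest_reduction_vs_dose.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

        fig, ax = plt.subplots(figsize=(6, 4))
        mid_mas = sorted(chest.profiles.mas.unique())[len(chest.profiles.mas.unique()) // 2]
        sub = chest.profiles[chest.profiles.mas == mid_mas]
        for code, grp in sub.groupby("setting_code"):
            ax.plot(grp.position_mm, grp.value, label=code, lw=0.9)
        ax.set_xlabel("position (mm)")
        ax.set_ylabel("signal (detector units)")
        ax.set_title(f"lung/rib profile, {mid_mas} mAs")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / "chest_profiles.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if solid_water is not None and len(solid_water.radial):
        _csv(solid_water.radial, "solid_water_radial_nps.csv")
        _csv(solid_water.summary, "solid_water_summary.csv")
        _csv(solid_water.classes, "solid_water_equivalence_classes.csv")

        for thickness, tsub in solid_water.radial.groupby("thickness"):
            lowest = tsub.mas.min()
            dsub = tsub[tsub.mas == lowest]
            fig, axes = plt.subplots(1, 2, figsize=(10, 4))
            for ax, kind in zip(axes, ("repeat_subtraction", "texture")):
                ksub = dsub[dsub.kind == kind]
                for code, grp in ksub.groupby("setting_code"):
                    ax.plot(grp.frequency, grp.nps, label=code, lw=0.9)
                ax.set_xlabel("spatial frequency (cycles/mm)")
                ax.set_ylabel("NPS (units$^2$ mm$^2$)")
                ax.set_title(f"{kind}, {thickness}, {lowest} mAs")
                ax.legend(fontsize=7)
            fig.tight_layout()
            path = outdir / f"solid_water_nps_{thickness}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)

    if not written:
        logger.warning("write_report called with no result tables; manifest only")

    config_yaml = config.to_yaml()
    manifest = {
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "version": version or _package_version(),
        "files": sorted(p.name for p in written),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    (outdir / "config.yaml").write_text(config_yaml)
    written.append(outdir / "config.yaml")
    return written


def _package_version() -> str:
    from . import __version__
    return __version__
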