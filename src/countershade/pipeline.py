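"""End-to-end orchestration: stimuli -> simulation -> fitting -> report.

A single :class:`PipelineConfig` (YAML-serializable) carries every
parameter: the two skies, body geometry, scene layout, the synthetic
observer, and which models to fit. All randomness descends from one master
seed, so every table and image is regenerable from the config alone.

The default analysis mirrors the per-weather treatment of search
performance: within each weather, a binomial (accuracy) and a gamma
(reaction time) mixed model with pattern + session fixed effects and a
participant random intercept, a likelihood-ratio test for the pattern
factor (df = 2), and Tukey-adjusted pairwise pattern contrasts. A full
factorial (weather x pattern interaction) model is available as a variant,
and every analysis can be repeated on correct trials only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .body_geometry import (
    EllipsoidSpec,
    LayoutParams,
    LeafSpec,
    layout_scene,
    make_ellipsoid,
    make_leaf,
)
from .countershading import (
    PatternLabel,
    apparent_radiance,
    compute_irradiance_field,
    matched_uniform_level,
    optimal_pattern,
    shading_metrics,
    uniform_pattern,
)
from .glmm_analysis import (
    ModelSpec,
    TrialTable,
    fit_glmm,
    lr_test,
    read_trial_data,
    tukey_pairwise,
)
from .render import CameraSpec, render_scene, rescale_for_display
from .sky_irradiance import SkyModel
from .synthetic_observer import (
    PATTERNS,
    WEATHERS,
    ObserverParams,
    records_to_frame,
    simulate_experiment,
    write_trial_table,
)

__all__ = ["PipelineConfig", "RunReport", "run_stimuli",
           "run_simulation_and_fit", "reanalyze"]


def _default_skies() -> dict:
    return {
        "cloudy": SkyModel("overcast").to_config(),
        "sunny": SkyModel("clear_sun").to_config(),
    }


@dataclass
class PipelineConfig:
    master_seed: int = 0
    skies: dict = field(default_factory=_default_skies)
    ellipsoid: dict = field(default_factory=dict)
    leaf: dict = field(default_factory=dict)
    layout: dict = field(default_factory=dict)
    observer: dict = field(default_factory=dict)
    analysis_variants: tuple = ("all_trials",)
    factorial_model: bool = False
    n_quadrature: int = 8
    image_size: int = 512
    output_dir: str = "countershade_output"

    # -- construction helpers -------------------------------------------
    def sky(self, weather: str) -> SkyModel:
        return SkyModel.from_config(self.skies[weather])

    def ellipsoid_spec(self) -> EllipsoidSpec:
        return EllipsoidSpec(**self.ellipsoid)

    def leaf_spec(self) -> LeafSpec:
        return LeafSpec(**self.leaf)

    def layout_params(self, n_distractors: int = 20) -> LayoutParams:
        kw = dict(self.layout)
        kw.setdefault("n_distractors", n_distractors)
        return LayoutParams(**kw)

    def observer_params(self) -> ObserverParams:
        kw = dict(self.observer)
        for key in ("accuracy_cell_effects", "rt_cell_effects"):
            if key in kw:
                kw[key] = {
                    tuple(k.split("/")): v for k, v in kw[key].items()
                }
        return ObserverParams(**kw)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analysis_variants"] = list(self.analysis_variants)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "analysis_variants" in d:
            d["analysis_variants"] = tuple(d["analysis_variants"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Every numeric table of one pipeline run plus its provenance."""

    shading: dict
    data_summary: dict
    models: dict
    provenance: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "shading": self.shading,
                "data_summary": self.data_summary,
                "models": self.models,
                "provenance": self.provenance,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def build_target_patterns(config: PipelineConfig,
                          quadrature_resolution: int = 64) -> dict:
    """The three target reflectance patterns on the ellipsoid: the two
    sky-specific optima plus the brightness-matched uniform pattern."""
    mesh = make_ellipsoid(config.ellipsoid_spec())
    fields = {
        w: compute_irradiance_field(mesh, config.sky(w), quadrature_resolution)
        for w in WEATHERS
    }
    patterns = {
        "cloudy_CS": optimal_pattern(fields["cloudy"], PatternLabel.CLOUDY_CS),
        "sunny_CS": optimal_pattern(fields["sunny"], PatternLabel.SUNNY_CS),
    }
    level = matched_uniform_level(list(patterns.values()))
    patterns["no_CS"] = uniform_pattern(mesh, level, PatternLabel.NO_CS)
    return {"mesh": mesh, "fields": fields, "patterns": patterns,
            "uniform_level": level}


def shading_table(config: PipelineConfig) -> dict:
    """Shading metrics of every pattern x weather combination."""
    bundle = build_target_patterns(config)
    out = {}
    for w in WEATHERS:
        for p in PATTERNS:
            rad = apparent_radiance(bundle["patterns"][p], bundle["fields"][w])
            out[f"{w}/{p}"] = shading_metrics(rad)
    out["top_bottom_ratio"] = {
        "cloudy_CS": bundle["patterns"]["cloudy_CS"].top_bottom_ratio(),
        "sunny_CS": bundle["patterns"]["sunny_CS"].top_bottom_ratio(),
    }
    return out


def run_stimuli(config: PipelineConfig, out_dir=None,
                scenes_per_cell: int = 1) -> dict:
    """Render >= 1 display-rescaled scene for each weather x pattern cell.

    Returns a bundle mapping each cell to image/mask/metadata paths and
    target-mask statistics; writes PNGs and JSON sidecars under
    ``out_dir`` (defaults to ``config.output_dir``).
    """
    out_dir = Path(out_dir if out_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = build_target_patterns(config)
    rng = np.random.default_rng(config.master_seed)
    camera = CameraSpec.for_layout(
        config.layout_params(), image_size=config.image_size
    )
    results = {}
    for w in WEATHERS:
        sky = config.sky(w)
        for p in PATTERNS:
            for rep in range(scenes_per_cell):
                scene_seed = int(rng.integers(2**31))
                layout = config.layout_params()
                layout = dataclasses.replace(layout, rng_seed=scene_seed)
                scene = layout_scene(layout)
                leaf_rng = np.random.default_rng(scene_seed + 1)
                patterns = []
                for i in range(scene.n_items):
                    if i == scene.target_index:
                        patterns.append(bundle["patterns"][p])
                    else:
                        leaf = make_leaf(config.leaf_spec(), leaf_rng)
                        patterns.append(
                            uniform_pattern(
                                leaf, bundle["uniform_level"], PatternLabel.NO_CS
                            )
                        )
                img = rescale_for_display(
                    render_scene(scene, sky, patterns, camera)
                )
                stem = f"{w}_{p}" + (f"_{rep}" if scenes_per_cell > 1 else "")
                img.to_png(out_dir / f"{stem}.png")
                target = img.item_pixels(scene.target_index)
                meta = {
                    "weather": w,
                    "pattern": p,
                    "scene_seed": scene_seed,
                    "target_index": int(scene.target_index),
                    "n_distractors": layout.n_distractors,
                    "target_pixels": int(target.size),
                    "target_luminance_cv": float(target.std() / target.mean()),
                    "config_hash": config.config_hash(),
                }
                (out_dir / f"{stem}.json").write_text(
                    json.dumps(meta, indent=2, sort_keys=True)
                )
                results[(w, p, rep)] = meta
    return results


def _analyze(records, config: PipelineConfig, provenance: dict) -> RunReport:
    frame = records_to_frame(records)
    summary = (
        frame.groupby(["weather", "pattern"])
        .agg(accuracy=("correct", "mean"), mean_rt_s=("rt_s", "mean"),
             n=("correct", "size"))
        .reset_index()
        .to_dict(orient="records")
    )
    models: dict = {}
    for variant in config.analysis_variants:
        vmodels: dict = {}
        for w in WEATHERS:
            base_filter = f"{w}_only"
            for response in ("accuracy", "rt"):
                if variant == "correct_only" and response == "accuracy":
                    continue  # accuracy is degenerate on correct trials
                spec = ModelSpec(
                    response=response,
                    fixed_effects=("pattern", "session"),
                    data_filter=base_filter,
                )
                data = frame
                if variant == "correct_only":
                    data = frame[frame["correct"] == 1]
                full = fit_glmm(data, spec, n_quadrature=config.n_quadrature)
                tests = {
                    fct: dataclasses.asdict(
                        lr_test(
                            full,
                            fit_glmm(data, spec.without(fct),
                                     n_quadrature=config.n_quadrature,
                                     compute_cov=False),
                        )
                    )
                    for fct in ("pattern", "session")
                }
                pairwise = [
                    dataclasses.asdict(r)
                    for r in tukey_pairwise(full, "pattern")
                ]
                vmodels[f"{w}/{response}"] = {
                    "coefficients": full.summary().to_dict(orient="index"),
                    "sigma_u": full.sigma_u,
                    "gamma_shape": full.gamma_shape,
                    "loglik": full.loglik,
                    "converged": full.converged,
                    "lr_tests": tests,
                    "pairwise_pattern": pairwise,
                }
        if config.factorial_model:
            for response in ("accuracy", "rt"):
                if variant == "correct_only" and response == "accuracy":
                    continue
                spec = ModelSpec(
                    response=response,
                    fixed_effects=("weather", "pattern", "session"),
                    interaction=True,
                )
                data = frame
                if variant == "correct_only":
                    data = frame[frame["correct"] == 1]
                full = fit_glmm(data, spec, n_quadrature=config.n_quadrature)
                vmodels[f"factorial/{response}"] = {
                    "coefficients": full.summary().to_dict(orient="index"),
                    "sigma_u": full.sigma_u,
                    "gamma_shape": full.gamma_shape,
                    "loglik": full.loglik,
                    "converged": full.converged,
                }
        models[variant] = vmodels
    return RunReport(
        shading=shading_table(config),
        data_summary=summary,
        models=models,
        provenance=provenance,
    )


def run_simulation_and_fit(config: PipelineConfig,
                           out_dir=None) -> RunReport:
    """Simulate the full experiment under the config's observer model,
    write the trial table, fit every configured model and collect the
    report."""
    out_dir = Path(out_dir if out_dir is not None else config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    records = simulate_experiment(
        config.observer_params(), seed=config.master_seed
    )
    table_path = out_dir / "simulated_trials.tsv"
    write_trial_table(records, table_path)
    provenance = {
        "source": "simulated",
        "seed": config.master_seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_trials": len(records),
        "trial_table": str(table_path),
    }
    report = _analyze(records, config, provenance)
    report.provenance["elapsed_s"] = round(time.time() - t0, 2)
    report.to_json(out_dir / "report.json")
    return report


def reanalyze(path, config: PipelineConfig, out_dir=None,
              convert_ms: bool = False) -> RunReport:
    """Apply the configured analysis to an external per-trial table."""
    records: TrialTable = read_trial_data(path, convert_ms=convert_ms)
    provenance = {
        "source": "external",
        "path": str(path),
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_trials": len(records),
    }
    report = _analyze(list(records), config, provenance)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_json(out_dir / "reanalysis_report.json")
    return report
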