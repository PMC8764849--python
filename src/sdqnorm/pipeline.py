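"""End-to-end norming pipeline.

One run covers, per SDQ version (self, parent) and per scale, three norm
types: joint norms (age-only model on the gender x ethnic-background
weighted sample) and gender-specific norms for females and males (one model
with gender terms on the ethnic-background weighted sample). Each norm set
yields a fitted model, a percentile norm table, borderline/abnormal
cutoffs, and worm-plot diagnostics; with both versions, all eight scales
and all three types configured the bundle holds 8 x 2 x 3 = 48 norm sets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sdqnorm import __version__
from sdqnorm.instrument import ALL_SCALES, SDQ_INSTRUMENT
from sdqnorm.scoring import filter_complete_demographics, load_cohort, score_scales
from sdqnorm.simulate import SimulationConfig, generate_cohort
from sdqnorm.weights import compute_cell_weights, load_margins
from sdqnorm.fitting import (
    randomized_quantile_residuals,
    render_worm_plot,
    select_model,
    worm_plot,
)
from sdqnorm.tables import CutoffPolicy, build_norm_table, detection_rate, extract_cutoffs
from sdqnorm.reliability import scale_reliability

logger = logging.getLogger(__name__)

MIN_FIT_ROWS = 30  # refuse to fit on fewer records

#: self-report norm group n = 993, parent-report n = 736
DEFAULT_N = {"self": 993, "parent": 736}


def packaged_margins() -> dict:
    path = resources.files("sdqnorm.data") / "dutch_population_margins.yaml"
    return load_margins(str(path))


@dataclass
class PipelineConfig:
    """Configuration of one full norming run."""

    output_dir: str | Path = "sdqnorm_output"
    versions: tuple[str, ...] = ("self", "parent")
    norm_types: tuple[str, ...] = ("female", "male", "joint")
    scales: tuple[str, ...] = ALL_SCALES
    ages: tuple[int, ...] = tuple(range(12, 18))
    cutoff_mode: str = "up_to"
    abnormal_level: float = 90.0
    borderline_level: float = 80.0
    max_degree: int = 6
    seed: int = 0
    input_paths: dict[str, str] = field(default_factory=dict)  # version -> CSV
    margins: dict | None = None
    run_reliability: bool = True
    render_plots: bool = True

    def __post_init__(self):
        unknown = set(self.scales) - set(ALL_SCALES)
        if unknown:
            raise ValueError(f"unknown scales {unknown}")
        bad = set(self.norm_types) - {"female", "male", "joint"}
        if bad:
            raise ValueError(f"unknown norm types {bad}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("versions", "norm_types", "scales", "ages"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class RunManifest:
    """Inventory of one pipeline run: config, seeds, model traces, files."""

    config: dict
    software_version: str
    seeds: dict[str, int] = field(default_factory=dict)
    models: list[dict] = field(default_factory=list)
    norm_sets: list[dict] = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def register(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[path.name] = digest

    def write(self, path: Path) -> None:
        doc = {
            "config": self.config,
            "software_version": self.software_version,
            "seeds": self.seeds,
            "models": self.models,
            "norm_sets": self.norm_sets,
            "files": self.files,
            "stage_seconds": self.stage_seconds,
        }
        path.write_text(json.dumps(doc, indent=2, default=str))


def _family_for(scale: str) -> tuple[str, int]:
    smax = SDQ_INSTRUMENT[scale].score_max
    return ("BCPE", smax) if scale == "total" else ("BB", smax)


def _scale_frame(scored: pd.DataFrame, scale: str) -> pd.DataFrame:
    return scored[["age", "gender", scale]].rename(columns={scale: "score"})


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and write the artifact bundle."""
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    margins = cfg.margins or packaged_margins()
    policy = CutoffPolicy(cfg.abnormal_level, cfg.borderline_level, cfg.cutoff_mode)
    manifest = RunManifest(
        config={k: (str(v) if isinstance(v, Path) else v) for k, v in vars(cfg).items()
                if k != "margins"},
        software_version=__version__,
    )
    rng = np.random.default_rng(cfg.seed)

    all_cutoffs = []
    all_rates = []
    all_reliability = []
    for version in cfg.versions:
        t0 = time.time()
        cohort_seed = int(rng.integers(0, 2**31))
        manifest.seeds[f"cohort_{version}"] = cohort_seed
        if version in cfg.input_paths:
            cohort = load_cohort(cfg.input_paths[version])
        else:
            cohort, _truth = generate_cohort(SimulationConfig(
                n_subjects=DEFAULT_N[version], seed=cohort_seed, version=version))
        cohort, dropped = filter_complete_demographics(cohort)
        logger.info("%s cohort: %d records (%d dropped)", version, len(cohort), dropped)
        if len(cohort) < MIN_FIT_ROWS:
            raise ValueError(f"insufficient data: {len(cohort)} rows < {MIN_FIT_ROWS}")
        scored = score_scales(cohort)
        scored_path = out / f"scores_{version}.csv"
        scored.to_csv(scored_path, index=False)
        manifest.register(scored_path)

        w_joint = compute_cell_weights(scored, margins, ["gender", "ethnic_background"])
        w_gender = compute_cell_weights(scored, margins, ["ethnic_background"])
        wdf = pd.DataFrame({"subject_id": scored["subject_id"],
                            "weight_joint": w_joint, "weight_gender": w_gender})
        wpath = out / f"weights_{version}.csv"
        wdf.to_csv(wpath, index=False)
        manifest.register(wpath)
        manifest.stage_seconds[f"prepare_{version}"] = round(time.time() - t0, 2)

        want_joint = "joint" in cfg.norm_types
        gender_groups = tuple(t for t in cfg.norm_types if t != "joint")
        for scale in cfg.scales:
            t0 = time.time()
            family, smax = _family_for(scale)
            frame = _scale_frame(scored, scale)
            fits = []
            if want_joint:
                m = select_model(frame, w_joint, family, gender_mode="none",
                                 max_degree=cfg.max_degree,
                                 **({"n_trials": smax} if family == "BB"
                                    else {"score_max": smax}))
                fits.append((m, ("joint",), w_joint))
            if gender_groups:
                m = select_model(frame, w_gender, family, gender_mode="auto",
                                 max_degree=cfg.max_degree,
                                 **({"n_trials": smax} if family == "BB"
                                    else {"score_max": smax}))
                fits.append((m, gender_groups, w_gender))

            for model, groups, wts in fits:
                tag = "joint" if groups == ("joint",) else "gender"
                mpath = out / f"model_{version}_{scale}_{tag}.json"
                mpath.write_text(json.dumps(model.to_dict(), indent=2))
                manifest.register(mpath)
                manifest.models.append({
                    "version": version, "scale": scale, "norm_type": tag,
                    "family": family, "degrees": dict(model.spec.degrees),
                    "gender_term": model.spec.gender, "bic": float(model.bic),
                    "n_candidates": len(model.search_trace),
                })
                # diagnostics on the fitting sample
                resid_seed = int(rng.integers(0, 2**31))
                manifest.seeds[f"residuals_{version}_{scale}_{tag}"] = resid_seed
                resid = randomized_quantile_residuals(model, frame, seed=resid_seed)
                wp = worm_plot(resid)
                wp_csv = out / f"worm_{version}_{scale}_{tag}.csv"
                wp.to_frame().to_csv(wp_csv, index=False)
                manifest.register(wp_csv)
                if cfg.render_plots:
                    wp_png = out / f"worm_{version}_{scale}_{tag}.png"
                    render_worm_plot(wp, wp_png)
                    manifest.register(wp_png)

                table = build_norm_table(model, scale, ages=cfg.ages, groups=groups,
                                         version=version)
                cuts = extract_cutoffs(table, policy)
                rates = detection_rate(table, cuts)
                for group in groups:
                    npath = out / f"norms_{version}_{scale}_{group}.csv"
                    sub = table.data[table.data["group"] == group]
                    NormSubset = sub.copy()
                    NormSubset["entry"] = NormSubset["entry"].round(1)
                    NormSubset.to_csv(npath, index=False)
                    manifest.register(npath)
                    manifest.norm_sets.append({
                        "version": version, "scale": scale, "norm_type": group,
                        "norms_file": npath.name,
                    })
                cuts.data.insert(0, "version", version)
                rates.insert(0, "version", version)
                all_cutoffs.append(cuts.data)
                all_rates.append(rates)
            manifest.stage_seconds[f"fit_{version}_{scale}"] = round(time.time() - t0, 2)

        if cfg.run_reliability:
            t0 = time.time()
            rel_seed = int(rng.integers(0, 2**31))
            manifest.seeds[f"reliability_{version}"] = rel_seed
            for scale in cfg.scales:
                est = scale_reliability(cohort, scale, seed=rel_seed)
                all_reliability.append({
                    "version": version, "scale": scale, "alpha": est.alpha,
                    "rho_nl": est.rho_nl, "n_used": est.n_used,
                })
            manifest.stage_seconds[f"reliability_{version}"] = round(time.time() - t0, 2)

    for name, frames in (("cutoffs.csv", all_cutoffs), ("detection_rates.csv", all_rates)):
        if frames:
            path = out / name
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
            manifest.register(path)
    if all_reliability:
        path = out / "reliability.csv"
        pd.DataFrame(all_reliability).to_csv(path, index=False)
        manifest.register(path)

    mpath = out / "manifest.json"
    manifest.write(mpath)
    return manifest
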