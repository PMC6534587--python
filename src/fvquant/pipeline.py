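"""End-to-end runs: simulate → measure → analyze → report.

One :class:`RunConfig` (YAML file or constructed in code) drives the whole
pipeline; all randomness flows from a single root seed.  Outputs are a
report bundle of machine-readable CSV/JSON tables — stage summary, ROC
table, within-sample variation, slope summary, pixel-distribution
histogram — plus optional surface-plot figures and a run manifest.
Identical seed + config produces byte-identical machine-readable outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import compare, inclination, presets, roc, stats, synthetic
from .measure import LineSpec, MeasurementProfile, extract_line_profile, load_gvalue_image, surface_matrix
from .synthetic import StageParams

__all__ = ["RunConfig", "load_run_config", "run_pipeline", "measure_cohort"]

logger = logging.getLogger("fvquant")


@dataclass
class RunConfig:
    out_dir: Path
    preset: str = "rat"  # "rat" | "human"; ignored when stages is given
    stages: dict[str, StageParams] | None = None
    seed: int = 0
    image_format: str = "png"
    image_height: int = synthetic.DEFAULT_HEIGHT
    bin_width: float = 1.0
    fit_method: str = "vertical"
    make_figures: bool = True
    force: bool = False

    def stage_params(self) -> dict[str, StageParams]:
        if self.stages is not None:
            return self.stages
        if self.preset == "rat":
            return dict(presets.RAT_STAGE_PARAMS)
        if self.preset == "human":
            return dict(presets.HUMAN_SITE_PARAMS)
        raise ValueError(f"unknown preset {self.preset!r}")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration.

    Top-level keys mirror :class:`RunConfig`; an optional ``stages``
    mapping (stage label -> StageParams fields) overrides the preset.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    stages = None
    if "stages" in doc:
        stages = {
            label: StageParams(stage_label=label, **fields)
            for label, fields in doc.pop("stages").items()
        }
    if "out_dir" not in doc:
        raise ValueError("config must set out_dir")
    doc["out_dir"] = Path(doc["out_dir"])
    return RunConfig(stages=stages, **doc)


def measure_cohort(cohort_dir: str | Path) -> list[MeasurementProfile]:
    """Load a generated cohort and extract one A→R profile per animal.

    The measurement line runs along the middle image row over the full
    line length recorded in the cohort's truth metadata.
    """
    cohort_dir = Path(cohort_dir)
    truth = synthetic.load_truth(cohort_dir)
    profiles = []
    for rec in truth["animals"]:
        img = load_gvalue_image(cohort_dir / rec["file"])
        h, w = img.shape
        line_px = truth["stages"][rec["stage_label"]]["line_px"]
        line = LineSpec(start=(0, h // 2), end=(line_px - 1, h // 2), n_points=line_px)
        profiles.append(
            extract_line_profile(
                img, line, stage_label=rec["stage_label"], sample_id=rec["animal_id"]
            )
        )
    return profiles


def _group_profiles(profiles: Sequence[MeasurementProfile]) -> dict[str, list[MeasurementProfile]]:
    by_stage: dict[str, list[MeasurementProfile]] = {}
    for p in profiles:
        by_stage.setdefault(p.stage_label, []).append(p)
    return by_stage


def _default_comparisons(stage_labels: Sequence[str]):
    if set(stage_labels) == {"Control", "LGD", "HGD/CIS", "Cancer"}:
        return presets.RAT_COMPARISONS
    labels = list(stage_labels)
    return [
        (f"{labels[i]} vs {labels[j]}", [labels[j]], [labels[i]])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    ]


def _stage(name):
    """Decorator-free stage wrapper: log duration, fail fast with stage name."""

    class _Ctx:
        def __init__(self, label):
            self.label = label

        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", self.label)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                logger.info("stage %s: done in %.2fs", self.label, dt)
            else:
                logger.error("stage %s: FAILED after %.2fs (%s)", self.label, dt, exc)
            return False

    return _Ctx(name)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    Returns a mapping from artifact name to path.  Raises on the first
    failing stage (fail-fast) with the stage name in the log.
    """
    cfg = config
    stages_cfg = cfg.stage_params()
    if not stages_cfg:
        raise ValueError("no stages configured")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    with _stage("simulate"):
        cohort_dir = out / "cohort"
        synthetic.generate_cohort(
            stages_cfg,
            cfg.seed,
            cohort_dir,
            image_format=cfg.image_format,
            height=cfg.image_height,
            force=cfg.force,
        )
        paths["cohort"] = cohort_dir

    with _stage("measure"):
        profiles = measure_cohort(cohort_dir)
        rows = []
        for p in profiles:
            for pos, val in zip(p.positions, p.values):
                rows.append((p.sample_id, p.stage_label, pos, val))
        prof_df = pd.DataFrame(rows, columns=["sample_id", "stage", "position", "g_value"])
        paths["profiles"] = out / "profiles.csv"
        prof_df.to_csv(paths["profiles"], index=False)

    by_stage = _group_profiles(profiles)

    with _stage("sample_statistics"):
        samp_rows = []
        fits_by_stage: dict[str, list[inclination.InclinationFit]] = {}
        for stage_label, plist in by_stage.items():
            for p in plist:
                s = stats.summarize_sample(p)
                f = inclination.fit_inclination(p, method=cfg.fit_method)
                fits_by_stage.setdefault(stage_label, []).append(f)
                samp_rows.append(
                    {
                        "sample_id": s.sample_id,
                        "stage": stage_label,
                        "n_pixels": s.n_pixels,
                        "mean": s.mean,
                        "sd": s.sd,
                        "median": s.median,
                        "min": s.min,
                        "max": s.max,
                        "range": s.range,
                        "detrended_sd": stats.detrended_sample_sd(p),
                        "slope": f.slope_a,
                        "intercept": f.intercept_b,
                        "sign": f.sign,
                        "residual_rms": f.residual_rms,
                    }
                )
        samples_df = pd.DataFrame(samp_rows)
        paths["samples"] = out / "samples.csv"
        samples_df.to_csv(paths["samples"], index=False)

    with _stage("group_statistics"):
        grp_rows = []
        for stage_label, plist in by_stage.items():
            g = stats.summarize_group(plist, stage_label)
            grp_rows.append(asdict(g))
        group_df = pd.DataFrame(grp_rows)
        paths["group_summary"] = out / "group_summary.csv"
        group_df.to_csv(paths["group_summary"], index=False)

        var_rows = []
        for stage_label in by_stage:
            sub = samples_df[samples_df["stage"] == stage_label]
            var_rows.append(
                {
                    "stage": stage_label,
                    "mean_sample_sd": sub["sd"].mean(),
                    "mean_detrended_sd": sub["detrended_sd"].mean(),
                }
            )
        paths["variation"] = out / "variation.csv"
        pd.DataFrame(var_rows).to_csv(paths["variation"], index=False)

    with _stage("inclination"):
        slope_rows = [
            asdict(inclination.slope_group_summary(fits, stage_label))
            for stage_label, fits in fits_by_stage.items()
        ]
        paths["slopes"] = out / "slopes.csv"
        pd.DataFrame(slope_rows).to_csv(paths["slopes"], index=False)

    with _stage("distribution"):
        dist = stats.scatter_distribution(by_stage, bin_width=cfg.bin_width)
        paths["distribution"] = out / "distribution.json"
        with open(paths["distribution"], "w") as fh:
            json.dump(
                {
                    "bin_edges": dist.bin_edges.tolist(),
                    "counts": {k: v.tolist() for k, v in dist.counts.items()},
                },
                fh,
                indent=2,
                sort_keys=True,
            )

    with _stage("roc"):
        pixel_groups = {
            stage_label: np.concatenate([p.finite_values() for p in plist])
            for stage_label, plist in by_stage.items()
        }
        comps = roc.stage_comparison(pixel_groups, _default_comparisons(list(by_stage)))
        paths["roc"] = out / "roc.csv"
        pd.DataFrame([asdict(c) for c in comps]).to_csv(paths["roc"], index=False)

    with _stage("group_tests"):
        labels = list(by_stage)
        means = [[p.finite_values().mean() for p in by_stage[s]] for s in labels]
        if all(len(m) >= 2 for m in means):
            f, p = compare.anova_oneway(means)
            dun = compare.dunnett_many_to_one(
                means,
                reference_index=0,
                seed=cfg.seed + 1,
                labels=[f"{s} vs {labels[0]}" for s in labels],
            )
            test_rows = [{"test": "anova", "label": "omnibus", "statistic": f,
                          "p_adjusted": p, "p_unadjusted": p, "significant": p < 0.05}]
            test_rows += [dict(test="dunnett", **asdict(d)) for d in dun]
            paths["group_tests"] = out / "group_tests.csv"
            pd.DataFrame(test_rows).to_csv(paths["group_tests"], index=False)
        else:
            logger.warning("group_tests skipped: a stage has fewer than 2 samples")

    if cfg.make_figures:
        with _stage("figures"):
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig_dir = out / "figures"
            fig_dir.mkdir(exist_ok=True)
            truth = synthetic.load_truth(cohort_dir)
            first_by_stage: dict[str, str] = {}
            for rec in truth["animals"]:
                first_by_stage.setdefault(rec["stage_label"], rec["file"])
            for stage_label, fname in first_by_stage.items():
                img = load_gvalue_image(cohort_dir / fname)
                m = surface_matrix(img)
                fig = plt.figure(figsize=(5, 3.5))
                ax = fig.add_subplot(111, projection="3d")
                yy, xx = np.mgrid[0 : m.shape[0], 0 : m.shape[1]]
                ax.plot_surface(xx, yy, m, cmap="viridis", rstride=4, cstride=4)
                ax.set_zlim(0, 255)
                ax.set_title(f"{stage_label} intensity surface")
                safe = stage_label.replace("/", "_")
                fig.savefig(fig_dir / f"surface_{safe}.png", dpi=100)
                plt.close(fig)
            paths["figures"] = fig_dir

    with _stage("manifest"):
        cfg_doc = asdict(cfg)
        cfg_doc["out_dir"] = str(cfg_doc["out_dir"])
        if cfg_doc["stages"]:
            cfg_doc["stages"] = {k: v for k, v in cfg_doc["stages"].items()}
        cfg_json = json.dumps(cfg_doc, sort_keys=True, default=str)
        from . import __version__

        manifest = {
            "seed": cfg.seed,
            "config": json.loads(cfg_json),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "fvquant_version": __version__,
        }
        paths["manifest"] = out / "manifest.json"
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return paths
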