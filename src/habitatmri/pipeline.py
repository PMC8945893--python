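"""End-to-end orchestration: synth -> validate -> extract -> volumetrics ->
classify -> cluster, with a reproducible JSON manifest.

The manifest records the config hash, all seeds, SHA-256 checksums of every
written artifact and per-stage timings.  Re-running the same config and seed
reproduces identical outputs (timings and timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as clf
from . import synthetic, volumetrics
from .clustering import FeatureHeatmapCluster, save_heatmap_png
from .features import RegionFeatureExtractor
from .io import read_subject, validate_subject

STAGES = ("synth", "validate", "extract", "volumetrics", "classify", "cluster")


@dataclass
class RunConfig:
    preset: str = "local"  # local | tcia | directory source
    cohort_dir: str | None = None  # read subjects from here instead of synthesizing
    n_subjects: int | None = None
    seed: int = 0
    channel: str = "t1ce"
    grid: str = "small"  # small | default
    n_words: int = 256
    sift_stride: int = 4
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    out_dir: str = "habitat_run"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        cfg = cls(**{k: v for k, v in raw.items() if k != "stages"})
        if "stages" in raw:
            cfg.stages.update(raw["stages"])
        return cfg

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _preset(name: str) -> synthetic.CohortPreset:
    if name == "local":
        return synthetic.local_cohort_preset()
    if name == "tcia":
        return synthetic.tcia_cohort_preset()
    raise ValueError(f"unknown preset {name!r}")


def run(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": {},
        "status": "ok",
    }

    def record(stage: str, t0: float, **info):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}

    subjects = None
    try:
        if config.stages.get("synth", True) and config.cohort_dir is None:
            t0 = time.time()
            preset = _preset(config.preset)
            subjects, log = synthetic.generate_cohort(
                preset, seed=config.seed, n_subjects=config.n_subjects
            )
            cohort_dir = out / "cohort"
            synthetic.write_cohort(cohort_dir, subjects, log)
            manifest["outputs"]["generation_log"] = _sha256(cohort_dir / "generation_log.json")
            record("synth", t0, n_subjects=len(subjects))
            src_dir = cohort_dir
        else:
            src_dir = Path(config.cohort_dir)

        subject_dirs = sorted(d for d in src_dir.iterdir() if d.is_dir())

        if config.stages.get("validate", True):
            t0 = time.time()
            for d in subject_dirs:
                validate_subject(d)
            record("validate", t0, n_subjects=len(subject_dirs))

        if subjects is None:
            subjects = [read_subject(d) for d in subject_dirs]
        else:
            subjects = [read_subject(d) for d in subject_dirs]  # round-trip from disk

        features = None
        if config.stages.get("extract", True):
            t0 = time.time()
            extractor = RegionFeatureExtractor(
                channel=config.channel,
                n_words=config.n_words,
                sift_stride=config.sift_stride,
                random_state=config.seed,
            ).fit(subjects)
            features = extractor.transform(subjects)
            fpath = out / "features.csv"
            features.to_csv(fpath)
            manifest["outputs"]["features_csv"] = _sha256(fpath)
            record("extract", t0, n_rows=len(features))

        if config.stages.get("volumetrics", True):
            t0 = time.time()
            summaries = [volumetrics.compute_volumes(lm) for _, lm in subjects]
            stats = volumetrics.cohort_ratio_stats(summaries)
            table = volumetrics.ratio_table(summaries)
            spath = out / "ratio_stats.csv"
            volumetrics.stats_dataframe(stats).to_csv(spath)
            anova = volumetrics.rm_anova_bonferroni(
                table, family=[f"{h}/abv" for h in ("necrosis", "solid", "peritumoral_tissue", "edema")]
            )
            apath = out / "anova.json"
            apath.write_text(
                json.dumps(
                    {
                        "F": anova.f_statistic,
                        "p": anova.p_value,
                        "pairwise_corrected_p": {
                            f"{a} vs {b}": p for (a, b), p in anova.pairwise_corrected_p.items()
                        },
                        "stars": {f"{a} vs {b}": s for (a, b), s in anova.stars.items()},
                    },
                    indent=2,
                )
            )
            manifest["outputs"]["ratio_stats_csv"] = _sha256(spath)
            manifest["outputs"]["anova_json"] = _sha256(apath)
            record("volumetrics", t0, n_subjects=len(summaries))

        if config.stages.get("classify", True):
            if features is None:
                raise RuntimeError("classify stage requires extract stage")
            t0 = time.time()
            grid = clf.default_grid() if config.grid == "default" else clf.small_grid()
            labels = features.index.get_level_values("habitat").to_numpy()
            report = clf.loocv_evaluate(
                features.to_numpy(), labels, grid=grid, seed=config.seed
            )
            rpath = out / "classifier_report.json"
            rpath.write_text(json.dumps(report.to_dict(), indent=2))
            report.fold_predictions.to_csv(out / "fold_predictions.csv", index=False)
            manifest["outputs"]["classifier_report_json"] = _sha256(rpath)
            record("classify", t0, accuracy=report.accuracy)

        if config.stages.get("cluster", True):
            if features is None:
                raise RuntimeError("cluster stage requires extract stage")
            t0 = time.time()
            model = FeatureHeatmapCluster(n_clusters=5).fit(features)
            cpath = out / "clusters.json"
            cpath.write_text(
                json.dumps(
                    {
                        "labels": model.labels_.tolist(),
                        "row_order": model.row_order_.tolist(),
                        "n_clusters": int(model.n_clusters),
                    },
                    indent=2,
                )
            )
            save_heatmap_png(model, out / "heatmap.png")
            manifest["outputs"]["clusters_json"] = _sha256(cpath)
            record("cluster", t0)
    except Exception as exc:  # record the failure point, skip downstream stages
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
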