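"""End-to-end pipeline orchestration.

Runs simulate -> (render/segment/extract demo field) -> normalize ->
classify -> stats -> treat from a single configuration, writing every
artifact (tables, model JSONs, reports) into a run directory with
provenance (config hash, seed) and JSON-line logs.  Reruns with the same
configuration are bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import segmentation
from .classify import fit_cell_classifier, probability_histogram, score_cells
from .features import MARKERS, extract_cell_features
from .normalization import apply_normalizer, fit_control_normalizer
from .rescue import rescue_analysis
from .stats import marker_set_report
from .synthetic import CohortConfig, SceneSpec, render_field, simulate_feature_table

logger = logging.getLogger(__name__)

ALL_MARKER_SETS = MARKERS + ("combined",)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    scene: SceneSpec | None = None
    marker_sets: tuple = ALL_MARKER_SETS
    alpha: float = 0.05
    normalize: bool = True
    include_treated: bool = False
    histogram_bins: int = 50
    stages: tuple = ("simulate", "normalize", "classify", "stats")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        scene = raw.pop("scene", None)
        if scene is not None:
            scene = SceneSpec(**scene)
        for key in ("marker_sets", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, scene=scene, **raw)

    def digest(self) -> str:
        payload = {
            "cohort": dataclasses.asdict(self.cohort),
            "scene": dataclasses.asdict(self.scene) if self.scene else None,
            "marker_sets": list(self.marker_sets), "alpha": self.alpha,
            "normalize": self.normalize,
            "include_treated": self.include_treated,
            "stages": list(self.stages),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in order; return the summary report.

    Artifacts land in ``outdir``: feature tables (CSV), scoring models
    (JSON), per-marker-set reports and, when treatment is enabled, the
    rescue report.  A stage failure aborts with the stage named; partial
    outputs are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.digest(), "seed": config.cohort.seed}
    log_path = outdir / "pipeline_log.jsonl"
    report: dict = {"provenance": provenance, "marker_sets": {}}

    def _log(stage: str, **info) -> None:
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"stage": stage, "time": time.time(), **info})
                     + "\n")

    table = None
    stage = "start"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            t0 = time.perf_counter()
            table = simulate_feature_table(config.cohort,
                                           include_treated=config.include_treated)
            table.to_csv(outdir / "feature_table.csv", index=False)
            _log(stage, rows=len(table), seconds=time.perf_counter() - t0)

        if "segment" in config.stages or "extract" in config.stages:
            stage = "segment/extract"
            t0 = time.perf_counter()
            spec = config.scene or SceneSpec(seed=config.cohort.seed)
            rendered = render_field(spec)
            nuclei = segmentation.find_nuclei(rendered.field.channels["nucleus"])
            cells = segmentation.find_cytoplasm(
                rendered.field.channels["cellmask"], nuclei)
            cells, nuclei = segmentation.filter_cells(cells, nuclei,
                                                      exclude_border=True)
            image_table = extract_cell_features(rendered.field, nuclei, cells)
            image_table.to_csv(outdir / "image_feature_table.csv", index=False)
            rendered.field.to_tiff(outdir / "demo_field.tiff")
            nuclei.to_tiff(outdir / "nuclei_labels.tiff")
            cells.to_tiff(outdir / "cell_labels.tiff")
            _log(stage, cells=len(image_table),
                 seconds=time.perf_counter() - t0)

        if table is None:
            raise RuntimeError("no feature table: enable the simulate stage "
                               "or provide one")

        untreated = table[table["treatment"] == "untreated"]
        treated = table[table["treatment"] != "untreated"]

        if "normalize" in config.stages and config.normalize:
            stage = "normalize"
            t0 = time.perf_counter()
            params = fit_control_normalizer(table)
            params.to_json(outdir / "normalizer.json")
            untreated = apply_normalizer(untreated, params)
            if len(treated):
                treated = apply_normalizer(treated, params)
            _log(stage, runs=len(params.runs),
                 seconds=time.perf_counter() - t0)

        models, scores = {}, {}
        if "classify" in config.stages:
            stage = "classify"
            for marker_set in config.marker_sets:
                t0 = time.perf_counter()
                model = fit_cell_classifier(untreated, marker_set=marker_set)
                model.to_json(outdir / f"model_{marker_set}.json")
                models[marker_set] = model
                scores[marker_set] = score_cells(model, untreated)
                hist = probability_histogram(scores[marker_set],
                                             config.histogram_bins)
                pd.DataFrame(
                    {"bin_left": hist["edges"][:-1],
                     **{f"count_group{g}": c for g, c in hist["counts"].items()}}
                ).to_csv(outdir / f"histogram_{marker_set}.csv", index=False)
                _log(stage, marker_set=marker_set,
                     seconds=time.perf_counter() - t0)

        if "stats" in config.stages:
            stage = "stats"
            for marker_set, sc in scores.items():
                report["marker_sets"][marker_set] = marker_set_report(sc)
            _log(stage, marker_sets=list(scores))

        if "treat" in config.stages:
            stage = "treat"
            if not len(treated):
                raise RuntimeError("treat stage enabled but the table has no "
                                   "treated cells (set include_treated)")
            rescue = {}
            for marker_set, model in models.items():
                entry = rescue_analysis(model, untreated, treated,
                                        alpha=config.alpha)
                rescue[marker_set] = {
                    "F": entry.f, "p": entry.p,
                    "group_means": entry.group_means,
                    "tukey_p": entry.tukey_p,
                    "rescue_status": entry.rescue_status,
                }
            report["rescue"] = rescue
            _log(stage, marker_sets=list(rescue))
    except Exception as exc:
        _log(stage, error=str(exc))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
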