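"""End-to-end orchestration: simulate (or load) -> normalize -> dosage ->
X status -> profiling, with a machine-readable summary and a run log.

A run is reproducible from its configuration and seed; the summary JSON is
byte-identical across repeated runs of the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import sklearn
import yaml

from . import __version__
from .dosage import ChromosomeDosageModel
from .io import (CountMatrix, GeneAnnotation, read_annotation, read_counts,
                 write_annotation, write_counts, write_sample_meta)
from .normalize import ValidationError
from .profile import (correlation_clustering, differential_expression, log_normalized,
                      marker_panel, pca_profile)
from .simulate import SCENARIOS, simulate_scenario, write_truth
from .xstatus import XStatusModel, XThresholds


class StageError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full study-reconstruction run.

    Either a simulation ``scenario`` (with ``seed``) or explicit input paths
    (``counts_path``, ``annotation_path``, optional ``sample_meta_path``).
    """

    scenario: str | None = "study_design"
    include_fibroblast: bool = True
    counts_path: str | None = None
    annotation_path: str | None = None
    sample_meta_path: str | None = None
    annotation_format: str = "tsv"
    seed: int = 0
    outdir: str = "karyoexpr_run"
    ratio_threshold: float = 1.3
    fdr_threshold: float = 0.01
    xist_high: float = 100.0
    xist_low: float = 10.0
    x_fold_threshold: float = 1.3
    y_rpm_threshold: float = 1.0
    reference_line: str | None = None  # marker-panel reference; default: last ES line

    def __post_init__(self):
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.scenario is None and not (self.counts_path and self.annotation_path):
            raise ValidationError("either a scenario or counts_path+annotation_path is required")
        if not 1.0 < self.ratio_threshold:
            raise ValidationError("ratio_threshold must exceed 1")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValidationError("fdr_threshold must lie in (0, 1]")
        if self.xist_low >= self.xist_high:
            raise ValidationError("xist_low must be strictly below xist_high")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_study_reconstruction(config: RunConfig, log_stream=None) -> dict:
    """Run the full pipeline and write the report bundle to ``config.outdir``.

    Outputs: count/annotation/truth tables (when simulating), the dosage and
    X-status reports, profiling tables, ``summary.json`` (per line: gain
    calls and X class), a MANIFEST of completed stages and ``run.log``.
    Returns the summary dictionary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)
        if log_stream is not None:
            print(msg, file=log_stream)

    def done(stage: str) -> None:
        manifest.append(stage)
        (outdir / "MANIFEST.txt").write_text("\n".join(manifest) + "\n")

    log(f"karyoexpr {__version__} (numpy {np.__version__}, scipy {scipy.__version__}, "
        f"pandas {pd.__version__}, scikit-learn {sklearn.__version__})")
    log(f"seed: {config.seed}")
    log(f"thresholds: ratio>={config.ratio_threshold}, FDR<={config.fdr_threshold}, "
        f"XIST high/low {config.xist_high}/{config.xist_low} rpm, "
        f"X fold>={config.x_fold_threshold}")

    try:
        # ------------------------------------------------------------ inputs
        stage = "input"
        truth = None
        if config.scenario is not None:
            counts, annotation, truth, _ = simulate_scenario(
                config.scenario, seed=config.seed,
                include_fibroblast=config.include_fibroblast,
            )
            write_counts(counts, outdir / "counts.tsv")
            write_sample_meta(counts.sample_meta, outdir / "sample_meta.tsv")
            write_annotation(annotation, outdir / "annotation.tsv")
            write_truth(truth, outdir / "truth.tsv")
            log(f"simulated scenario {config.scenario!r}: "
                f"{len(counts.genes)} genes x {len(counts.samples)} samples")
        else:
            counts = read_counts(config.counts_path, sample_meta_path=config.sample_meta_path)
            annotation = read_annotation(
                config.annotation_path, format=config.annotation_format, counts=counts
            )
            log(f"loaded {config.counts_path}: "
                f"{len(counts.genes)} genes x {len(counts.samples)} samples")
        unassigned = annotation.unassigned(counts.genes)
        if len(unassigned):
            log(f"{len(unassigned)} genes lack a chromosome assignment and are "
                "excluded from chromosome-level statistics")
        meta = counts.sample_meta
        if "cell_type" in meta.columns:
            es_lines = list(dict.fromkeys(
                meta.loc[meta["cell_type"] == "es", "line"]
            )) or counts.lines
        else:
            es_lines = counts.lines
        done(stage)

        # ------------------------------------------------------------ dosage
        stage = "dosage"
        dosage_model = ChromosomeDosageModel(counts, annotation, lines=es_lines)
        dosage_results = dosage_model.fit(
            ratio_threshold=config.ratio_threshold, fdr_threshold=config.fdr_threshold
        )
        dosage_results.to_tsv(outdir / "dosage_report.tsv")
        log(dosage_results.summary())
        done(stage)

        # ------------------------------------------------------------ X status
        stage = "x_status"
        x_model = XStatusModel(counts, annotation, lines=es_lines)
        x_results = x_model.fit(XThresholds(
            xist_high=config.xist_high, xist_low=config.xist_low,
            x_fold_threshold=config.x_fold_threshold,
            y_rpm_threshold=config.y_rpm_threshold,
        ))
        x_results.to_tsv(outdir / "xstatus_report.tsv")
        log(x_results.summary())
        done(stage)

        # ------------------------------------------------------------ profile
        stage = "profile"
        log_norm = log_normalized(counts)
        coords, explained = pca_profile(log_norm)
        pca_out = coords.copy()
        pca_out.loc["explained_variance_fraction"] = list(explained) + [np.nan] * (
            coords.shape[1] - len(explained)
        )
        pca_out.to_csv(outdir / "pca_coordinates.tsv", sep="\t", index_label="sample",
                       float_format="%.6g")
        corr, linkage = correlation_clustering(log_norm)
        corr.to_csv(outdir / "sample_correlation.tsv", sep="\t", index_label="sample",
                    float_format="%.6g")
        ref_line = config.reference_line or es_lines[-1]
        for panel, genes in annotation.marker_panels.items():
            marker_panel(counts, genes, ref_line).to_tsv(outdir / f"markers_{panel}.tsv")
        de_summary = None
        if "cell_type" in meta.columns and (meta["cell_type"] != "es").any():
            es_samples = meta.index[meta["cell_type"] == "es"].tolist()
            other = meta.index[meta["cell_type"] != "es"].tolist()
            if len(es_samples) >= 2 and len(other) >= 2:
                de = differential_expression(counts, es_samples, other)
                de.to_tsv(outdir / "de_es_vs_outgroup.tsv")
                de_summary = int(de.frame["candidate"].sum())
                log(f"differential expression ES vs outgroup: {de_summary} candidates "
                    "(>= 2-fold, FDR < 0.05)")
        done(stage)

        # ------------------------------------------------------------ summary
        stage = "summary"
        summary = {
            "seed": config.seed,
            "scenario": config.scenario,
            "thresholds": {
                "ratio_threshold": config.ratio_threshold,
                "fdr_threshold": config.fdr_threshold,
                "xist_high": config.xist_high,
                "xist_low": config.xist_low,
                "x_fold_threshold": config.x_fold_threshold,
                "y_rpm_threshold": config.y_rpm_threshold,
            },
            "lines": {
                line: {
                    "gain_calls": sorted(
                        c for ln, c in dosage_results.gain_calls if ln == line
                    ),
                    "x_class": x_results.x_class_of(line),
                    "sex_call": x_results.frame.loc[line, "sex_call"],
                }
                for line in es_lines
            },
            "n_de_candidates_es_vs_outgroup": de_summary,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
            fh.write("\n")
        done(stage)
    except Exception as exc:
        log(f"FAILED at stage {stage!r}: {exc}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise StageError(stage, exc) from exc

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
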