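"""Readers/writers for the RR text format and experiment orchestration.

A subject file is plain text: `#`-prefixed header lines carry the subject
id and cohort label, then one `<seconds> <annotation-char>` pair per line.
A cohort is a directory of such files listed by a `manifest.txt`.  The
writer and reader round-trip byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import NetworkConfig
from .preprocessing import BeatAnnotatedRR, CohortLabel, build_dataset
from .training import EvalReport, TrainConfig, run_cross_validation


class RRFormatError(ValueError):
    """Malformed RR text file; the message names the offending line."""


def write_rr_text(series: BeatAnnotatedRR, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# subject_id={series.subject_id} label={series.cohort_label.value}"]
    for v, a in zip(series.intervals, series.annotations):
        lines.append(f"{v:.6f} {a}")
    path.write_text("\n".join(lines) + "\n")


def read_rr_text(path: str | Path) -> BeatAnnotatedRR:
    path = Path(path)
    subject_id: str | None = None
    label: CohortLabel | None = None
    intervals: list[float] = []
    annotations: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line[1:].split():
                if token.startswith("subject_id="):
                    subject_id = token.removeprefix("subject_id=")
                elif token.startswith("label="):
                    value = token.removeprefix("label=")
                    try:
                        label = CohortLabel(value)
                    except ValueError as exc:
                        raise RRFormatError(
                            f"{path}:{lineno}: unknown label {value!r}"
                        ) from exc
            continue
        if subject_id is None or label is None:
            raise RRFormatError(
                f"{path}:{lineno}: data before the subject_id/label header"
            )
        fields = line.split()
        if len(fields) != 2:
            raise RRFormatError(
                f"{path}:{lineno}: expected '<seconds> <annotation>', got {raw!r}"
            )
        try:
            intervals.append(float(fields[0]))
        except ValueError as exc:
            raise RRFormatError(
                f"{path}:{lineno}: non-numeric interval {fields[0]!r}"
            ) from exc
        annotations.append(fields[1])
    if subject_id is None or label is None:
        raise RRFormatError(f"{path}: missing subject_id/label header")
    if not intervals:
        raise RRFormatError(f"{path}: no data lines")
    return BeatAnnotatedRR(
        subject_id=subject_id,
        cohort_label=label,
        intervals=tuple(intervals),
        annotations=tuple(annotations),
    )


def write_cohort(cohort: list[BeatAnnotatedRR], directory: str | Path) -> None:
    """One file per subject plus a manifest listing the members."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for series in cohort:
        name = f"{series.subject_id}.rr"
        write_rr_text(series, directory / name)
        names.append(name)
    (directory / "manifest.txt").write_text("\n".join(names) + "\n")


def read_cohort(directory: str | Path) -> list[BeatAnnotatedRR]:
    directory = Path(directory)
    manifest = directory / "manifest.txt"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.txt in {directory}")
    names = [n for n in manifest.read_text().splitlines() if n.strip()]
    return [read_rr_text(directory / n) for n in names]


@dataclass
class RunConfig:
    """Everything one cross-validation experiment needs."""

    cohort_dir: Path
    output_dir: Path
    segment_length: int = 500
    k: int = 10
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)

    def validate(self) -> None:
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.k < 2:
            raise ValueError("k must be ≥ 2")
        if not Path(self.cohort_dir).exists():
            raise ValueError(f"cohort directory {self.cohort_dir} does not exist")

    def to_dict(self) -> dict:
        return {
            "cohort_dir": str(self.cohort_dir),
            "output_dir": str(self.output_dir),
            "segment_length": self.segment_length,
            "k": self.k,
            "network": self.network.to_dict(),
            "training": self.training.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            cohort_dir=Path(d["cohort_dir"]),
            output_dir=Path(d["output_dir"]),
            segment_length=int(d.get("segment_length", 500)),
            k=int(d.get("k", 10)),
            network=NetworkConfig.from_dict(d.get("network", {})),
            training=TrainConfig(**d.get("training", {})),
        )


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON — a YAML subset) file."""
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def write_report(report: EvalReport, out_dir: Path) -> None:
    """Metrics and ROC points as CSV, per-epoch curves included."""
    rows = []
    for f in report.folds:
        rows.append(
            {
                "fold": f.fold_index,
                **f.metrics,
                "auc": f.auc,
                "tp": f.confusion.tp,
                "fp": f.confusion.fp,
                "tn": f.confusion.tn,
                "fn": f.confusion.fn,
            }
        )
    rows.append(
        {
            "fold": "pooled",
            **report.pooled_metrics,
            "auc": report.pooled_auc,
            "tp": report.pooled_confusion.tp,
            "fp": report.pooled_confusion.fp,
            "tn": report.pooled_confusion.tn,
            "fn": report.pooled_confusion.fn,
        }
    )
    pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)
    fpr, tpr = report.pooled_roc
    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
        out_dir / "roc_pooled.csv", index=False
    )
    for f in report.folds:
        pd.DataFrame({"fpr": f.roc[0], "tpr": f.roc[1]}).to_csv(
            out_dir / f"roc_fold{f.fold_index}.csv", index=False
        )
        pd.DataFrame(f.curves).to_csv(
            out_dir / f"curves_fold{f.fold_index}.csv", index=False
        )


def run_experiment(cfg: RunConfig) -> EvalReport:
    """Cohort → preprocessing → subject-wise k-fold CV → artifacts on disk.

    Deterministic given the config seed.  Writes metrics.csv, ROC CSVs,
    per-epoch curves and a machine-readable copy of the resolved config to
    the output directory; a `RUNNING` marker is left behind if the run dies
    mid-way.
    """
    cfg.validate()
    cohort = read_cohort(cfg.cohort_dir)
    subjects = {s.subject_id for s in cohort}
    if len(subjects) < cfg.k:
        raise ValueError(
            f"{len(subjects)} subjects cannot fill {cfg.k} folds"
        )
    if len({s.cohort_label.binary for s in cohort}) < 2:
        raise ValueError("cohort must contain both CHF and non-CHF subjects")
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "RUNNING"
    marker.write_text("incomplete run\n")
    (out_dir / "config.json").write_text(
        json.dumps(cfg.to_dict(), indent=2) + "\n"
    )
    segments, counts = build_dataset(
        cohort, cfg.segment_length, cfg.network.depth
    )
    (out_dir / "segment_counts.json").write_text(
        json.dumps(counts.as_dict(), indent=2) + "\n"
    )
    report = run_cross_validation(
        segments, cfg.network, cfg.training, k=cfg.k
    )
    write_report(report, out_dir)
    for f in report.folds:
        if f.model is not None:
            f.model.save(out_dir / f"model_fold{f.fold_index}.npz")
    marker.unlink()
    return report
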