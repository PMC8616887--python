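"""End-to-end pipeline: contours -> shape model -> descriptors -> estimates.

The two operating modes differ only in the contour source: the
*semiautomatic* mode resamples expert annotations, the *automatic* mode
predicts contours from the images with a trained localizer. Everything
downstream (GPA, PDM, descriptor tables, ridge estimation) is identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .contour import read_annotation, resample_contour, write_contour
from .descriptors import (
    DESCRIPTOR_KINDS,
    build_descriptors,
    descriptor_columns,
    descriptor_matrix,
)
from .estimation import train_test_evaluate
from .localizer import LocalizerModel, predict_contour
from .morphometrics import fit_pdm, gpa_align
from .synthetic import read_cohort_table

logger = logging.getLogger("mandiblo")


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or malformed input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    data_dir: str
    output_dir: str
    mode: str = "semiautomatic"          # or "automatic"
    model_dir: str | None = None         # required in automatic mode
    variance_threshold: float = 0.95
    descriptor_kinds: tuple = tuple(DESCRIPTOR_KINDS)
    tasks: tuple = ("sex", "age")
    estimation_kind: str = "shape_params_plus_size"
    split_seed: int = 0
    test_size: float = 0.2
    px_per_mm: float | None = None
    sex_age_range: tuple | None = None   # e.g. (18, 70)
    age_age_range: tuple | None = None   # e.g. (5, 17)

    def validate(self) -> None:
        if self.mode not in ("semiautomatic", "automatic"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "automatic" and not self.model_dir:
            raise ConfigError(
                "automatic mode needs a trained localizer: set model_dir "
                "(train one with `mandiblo train`)"
            )
        if not 0 < self.variance_threshold <= 1:
            raise ConfigError("variance_threshold must be in (0, 1]")
        bad = set(self.descriptor_kinds) - set(DESCRIPTOR_KINDS)
        if bad:
            raise ConfigError(f"unknown descriptor kind(s): {sorted(bad)}")
        if not Path(self.data_dir).exists():
            raise ConfigError(f"data_dir does not exist: {self.data_dir}")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_contours(cfg: PipelineConfig, ids: list) -> list:
    data = Path(cfg.data_dir)
    contours = []
    if cfg.mode == "semiautomatic":
        for sid in ids:
            path = data / "annotations" / f"{sid}.json"
            if not path.exists():
                raise DataError(f"missing annotation {path}")
            contours.append(resample_contour(read_annotation(path)))
    else:
        model = LocalizerModel.load(cfg.model_dir)
        for sid in ids:
            path = data / "images" / f"{sid}.png"
            if not path.exists():
                raise DataError(f"missing image {path}")
            img = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
            contours.append(predict_contour(model, img))
    if cfg.px_per_mm:
        for c in contours:
            c.px_per_mm = cfg.px_per_mm
    return contours


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full description + estimation pipeline; write artifacts.

    Returns a summary dict (also written to ``summary.json``) with the
    shape-model diagnostics and one report per estimation task.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.hash()
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("pipeline start: mode=%s config_hash=%s", cfg.mode, cfg_hash)
        table_path = Path(cfg.data_dir) / "cohort.csv"
        if not table_path.exists():
            raise DataError(f"missing cohort table {table_path}")
        table = read_cohort_table(table_path)
        ids = [r["id"] for r in table]
        ages = np.array([float(r["age"]) for r in table])
        sexes = np.array([r["sex"] for r in table])

        contours = load_contours(cfg, ids)
        cdir = out / "contours"
        cdir.mkdir(exist_ok=True)
        for sid, c in zip(ids, contours):
            write_contour(c, cdir / f"{sid}.csv")

        aligned = gpa_align(contours)
        model = fit_pdm(aligned, l=cfg.variance_threshold)
        model.save(out / "shape_model")
        logger.info("PDM: k=%d modes for l=%.3f", model.k, cfg.variance_threshold)

        for kind in cfg.descriptor_kinds:
            descs = build_descriptors(contours, kind, model=model, ids=ids)
            mat = descriptor_matrix(descs)
            cols = descriptor_columns(kind, k=model.k)
            lines = ["id," + ",".join(cols) + f",#config={cfg_hash}"]
            for sid, row in zip(ids, mat):
                lines.append(sid + "," + ",".join(f"{float(v)!r}" for v in row))
            (out / f"descriptors_{kind}.csv").write_text("\n".join(lines) + "\n")

        summary = {
            "config_hash": cfg_hash,
            "mode": cfg.mode,
            "n_subjects": len(ids),
            "pdm_k": model.k,
            "pdm_proportions": model.proportions[:5].tolist(),
            "reports": {},
        }
        descs = build_descriptors(contours, cfg.estimation_kind, model=model)
        X = descriptor_matrix(descs)
        for task in cfg.tasks:
            y = sexes if task == "sex" else ages
            age_filter = cfg.sex_age_range if task == "sex" else cfg.age_age_range
            sel = np.ones(len(ids), dtype=bool)
            if age_filter is not None:
                sel = (ages >= age_filter[0]) & (ages <= age_filter[1])
            _, report = train_test_evaluate(
                X[sel], y[sel], task, seed=cfg.split_seed,
                test_size=cfg.test_size, descriptor_kind=cfg.estimation_kind,
            )
            summary["reports"][task] = report.to_dict()
            logger.info("%s report: %s", task, report.to_dict())
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        logger.info("pipeline done")
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
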