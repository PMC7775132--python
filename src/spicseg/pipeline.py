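"""End-to-end spiculation recognition pipeline and its configuration.

One case flows through: maximum-intensity projection → external force
field → snake segmentation → boundary extraction → 5×7 pulse encoding →
SN P network score.  Training fits the network's trainable synapse
weights and decision threshold on the training split; evaluation reports
per-case AOM against the projected ground truth and the test-split ROC.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .edge_forces import FieldParams
from .evaluation import aom, roc
from .imaging_io import Mask2D
from .phantoms import PhantomCase
from .projection import compute_mip
from .snake import ContourCollapseError, SnakeParams, segment_slice
from .snp import (
    BoundaryGrid,
    TrainedWeights,
    boundary_pixels,
    network_score,
    normalize_boundary,
    train,
)

__all__ = ["PipelineConfig", "run_pipeline", "case_to_grid", "ConfigError"]

logger = logging.getLogger("spicseg")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Flat key-value configuration covering every pipeline tunable."""

    schema_version: int = 1
    seed: int = 0
    # edge map / force field
    sigma: float = 0.8
    field_mode: str = "improved"  # "improved" | "gvf"
    field_w: float = 0.2
    field_dt: float = 0.15
    field_max_iter: int = 2000
    field_tol: float = 1e-5
    field_corner_weight: float = 0.3
    field_kappa: float = 0.1
    # snake
    snake_alpha: float = 0.02
    snake_beta: float = 0.005
    snake_dt: float = 1.0
    snake_move_tol: float = 0.003
    snake_max_iter: int = 1200
    snake_ext_weight: float = 2.0
    seed_radius: float = 26.0
    # projection window (inclusive; -1 = last slice)
    mip_first: int = 0
    mip_last: int = -1
    # network training
    train_epochs: int = 50
    learning_rate: float = 0.1
    # phantom generation defaults
    phantom_radius: float = 10.0
    phantom_n_spikes: int = 8
    phantom_spike_length: float = 8.0
    phantom_spike_width: float = 5.0
    phantom_noise_sigma: float = 0.02
    phantom_nodule_intensity: float = 0.9
    phantom_background_intensity: float = 0.15

    def field_params(self) -> FieldParams:
        return FieldParams(
            w=self.field_w, dt=self.field_dt, max_iter=self.field_max_iter,
            tol=self.field_tol, corner_weight=self.field_corner_weight,
            kappa=self.field_kappa,
        )

    def snake_params(self) -> SnakeParams:
        return SnakeParams(
            alpha=self.snake_alpha, beta=self.snake_beta, dt=self.snake_dt,
            move_tol=self.snake_move_tol, max_iter=self.snake_max_iter,
            ext_weight=self.snake_ext_weight,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if doc is None:
            return cls()
        if not isinstance(doc, dict):
            raise ConfigError("config file must hold a flat mapping")
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(doc) - set(known)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        defaults = cls()
        for key, value in doc.items():
            want = type(getattr(defaults, key))
            if want is float and isinstance(value, int):
                value = float(value)
            if not isinstance(value, want):
                raise ConfigError(
                    f"config key {key!r} must be {want.__name__}, got {type(value).__name__}"
                )
            doc[key] = value
        return cls(**doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _auto_seed_circle(image, max_radius: float) -> tuple[float, float, float]:
    """Seed the snake around the brightest (smoothed) spot.

    The circle radius adapts to the apparent extent of the bright blob
    (1.5x its equivalent radius plus a 5 px margin) so the contour starts
    outside the nodule and its spicules but within the force field's
    capture range; ``max_radius`` caps it, and the circle is shifted to
    fit inside the image.
    """
    h, w = image.pixels.shape
    smoothed = gaussian_filter(image.pixels, 2.0)
    half = (smoothed.max() + np.median(smoothed)) / 2.0
    blob = smoothed > half
    rows, cols = np.nonzero(blob)
    r, c = float(rows.mean()), float(cols.mean())  # centroid of the bright blob
    blob_r = np.sqrt(np.count_nonzero(blob) / np.pi)
    radius = min(1.5 * blob_r + 5.0, max_radius, (min(h, w) - 1) / 2.0 - 1.0)
    r = float(np.clip(r, radius, h - 1 - radius))
    c = float(np.clip(c, radius, w - 1 - radius))
    return r, c, radius


def case_to_grid(
    stack, config: PipelineConfig
) -> tuple[BoundaryGrid | None, Mask2D, "Mask2D"]:
    """MIP → field → snake → boundary encoding for one slice stack.

    Returns (grid, predicted MIP mask, MIP image wrapper); the grid is
    None when segmentation produced an empty mask.
    """
    last = config.mip_last if config.mip_last >= 0 else stack.n_slices - 1
    mip = compute_mip(stack, config.mip_first, last)
    r, c, radius = _auto_seed_circle(mip.image, config.seed_radius)
    try:
        mask, _contour = segment_slice(
            mip.image, (r, c), radius, config.field_params(), config.snake_params(),
            mode=config.field_mode, sigma=config.sigma,
        )
    except ContourCollapseError:
        mask = Mask2D(np.zeros(mip.image.pixels.shape, dtype=np.uint8))
    if mask.area() == 0:
        return None, mask, mip
    boundary = boundary_pixels(mask)
    if boundary.area() == 0:
        return None, mask, mip
    return normalize_boundary(boundary), mask, mip


def _mip_truth(case: PhantomCase) -> Mask2D:
    stacked = np.stack([m.pixels for m in case.truth], axis=0)
    return Mask2D(stacked.max(axis=0))


def run_pipeline(
    cases: Sequence[PhantomCase],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, TrainedWeights, dict]:
    """Run the full recognition pipeline over a labeled case set.

    Segments and encodes every case, trains the SN P classifier on the
    train split, scores everything, and returns (report, trained
    weights, metrics).  With ``out_dir`` the report CSV, config and
    trained weights are written there.
    """
    rows = []
    grids: dict[str, BoundaryGrid | None] = {}
    for case in cases:
        t0 = time.perf_counter()
        grid, mask, _mip = case_to_grid(case.stack, config)
        grids[case.case_id] = grid
        truth = _mip_truth(case)
        overlap = (
            aom(truth, mask).value if (truth.area() or mask.area()) else float("nan")
        )
        logger.info(
            "stage=encode case=%s label=%d split=%s cells=%s aom=%.1f elapsed=%.2fs",
            case.case_id, case.label, case.split,
            grid.total_pulses() if grid else 0, overlap, time.perf_counter() - t0,
        )
        rows.append({
            "case": case.case_id, "split": case.split, "label": case.label,
            "boundary_cells": grid.total_pulses() if grid else 0,
            "aom_percent": overlap,
        })

    empty_grid = BoundaryGrid(np.zeros((5, 7), dtype=np.uint8))
    train_cases = [c for c in cases if c.split == "train"]
    trained = train(
        [grids[c.case_id] or empty_grid for c in train_cases],
        [c.label for c in train_cases],
        epochs=config.train_epochs,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    logger.info("stage=train epochs=%d final_errors=%s threshold=%.1f",
                len(trained.history),
                trained.history[-1] if trained.history else "n/a", trained.threshold)

    for row, case in zip(rows, cases):
        grid = grids[case.case_id]
        if grid is None:
            score = 0.0
        else:
            score, _counts = network_score(grid, trained.weights)
        row["score"] = score
        row["pred"] = int(score >= trained.threshold)

    report = pd.DataFrame(rows)
    metrics: dict = {}
    for split in ("train", "test"):
        sub = report[report["split"] == split]
        if sub["label"].nunique() == 2:
            metrics[f"{split}_auc"] = roc(sub["score"], sub["label"]).auc
        metrics[f"{split}_accuracy"] = float((sub["pred"] == sub["label"]).mean())
    logger.info("stage=metrics %s", metrics)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "report.csv", index=False)
        (out_dir / "weights.json").write_text(trained.to_json())
        config.to_yaml(out_dir / "config.yaml")
    return report, trained, metrics
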