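"""End-to-end pipeline: configuration, sample loading, splitting, the GA
sweep over grid sizes, merit reporting and interval refinement.

This module is the library behind the command-line interface: every
command is a thin wrapper over a ``run_*`` function here, so scripted use
and the CLI produce byte-identical outputs for identical configuration and
master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ArtifactStateError, DomainError
from .ga import FitnessEvaluator, GAConfig, run_restarts
from .histograms import DEFAULT_CHANNELS, build_feature_matrix
from .image_grid import RasterImage, ROIGrid, load_image, partition_image
from .intervals import ipls, ispa_pls, make_intervals
from .pls import (
    MeritReport,
    bias_t_test,
    figures_of_merit,
    fit_pls,
    loocv_curve,
    pick_lv,
    predict,
)
from .spxy import spxy

logger = logging.getLogger("chromaroi")

__all__ = [
    "RunConfig",
    "load_samples",
    "split_samples",
    "model_merits",
    "run_simulate",
    "run_select_roi",
    "run_intervals",
]


@dataclass
class RunConfig:
    """Pipeline configuration; all defaults mirror the reported study run
    (100-individual, 100-generation GA at 5% mutation / 65% crossover, RGB
    histograms, 10 restarts, 28-sample calibration)."""

    sample_table: str = "samples.csv"
    image_dir: str = "."
    output_dir: str = "results"
    grids: tuple[tuple[int, int], ...] = ((5, 5), (10, 10))  # (roi1, roi2)
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    ga: GAConfig = field(default_factory=GAConfig)
    use_table_labels: bool = True
    n_cal: int = 28
    confidence: float = 0.95
    n_intervals: int | None = None   # default: 16 per 256-bin channel
    max_intervals: int = 3
    seed: int = 0
    # optional retention axes for ROI annotation: (start, stop) of the
    # first dimension (minutes, along width) and second (seconds, height)
    axis1_range: tuple[float, float] | None = None
    axis2_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.grids = tuple(tuple(int(v) for v in g) for g in self.grids)
        self.channels = tuple(self.channels)
        if isinstance(self.ga, dict):
            self.ga = GAConfig(**self.ga)
        # the master seed and channel choice flow into the GA config
        self.ga = dataclasses.replace(self.ga, seed=self.seed, channels=self.channels)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Short digest of the analytical configuration (filesystem paths
        excluded: the same analysis written elsewhere is the same analysis)."""
        d = self.to_dict()
        for key in ("sample_table", "image_dir", "output_dir"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_samples(
    config: RunConfig,
) -> tuple[list[tuple[str, RasterImage, float]], list[str] | None]:
    """Read the sample table and its images.

    The table needs ``sample_id``, ``image_path`` and ``y`` columns; an
    optional ``set_label`` column (C = calibration, P = prediction) is
    returned alongside when present.
    """
    table = pd.read_csv(Path(config.sample_table))
    for col in ("sample_id", "image_path", "y"):
        if col not in table.columns:
            raise DomainError(f"sample table lacks required column {col!r}")
    image_dir = Path(config.image_dir)
    samples = []
    for _, row in table.iterrows():
        path = image_dir / str(row["image_path"])
        if not path.exists():
            raise FileNotFoundError(
                f"sample {row['sample_id']!r}: image {path} not found"
            )
        samples.append((str(row["sample_id"]), load_image(path), float(row["y"])))
    labels = (
        [str(v) for v in table["set_label"]] if "set_label" in table.columns else None
    )
    return samples, labels


def split_samples(
    samples: Sequence[tuple[str, RasterImage, float]],
    labels: Sequence[str] | None,
    config: RunConfig,
) -> tuple[list[int], list[int]]:
    """Calibration/prediction split: honour C/P table labels when present
    and requested, otherwise run SPXY on full-image histogram features."""
    if labels is not None and config.use_table_labels:
        cal = [i for i, lab in enumerate(labels) if lab.upper() == "C"]
        pred = [i for i, lab in enumerate(labels) if lab.upper() == "P"]
        if len(cal) + len(pred) != len(samples):
            raise DomainError("set_label column must contain only C and P")
        return cal, pred
    img0 = samples[0][1]
    grid = partition_image(img0, 1, 1)
    fm = build_feature_matrix(samples, grid, [1], config.channels)
    split = spxy(fm.X, fm.y, config.n_cal)
    return sorted(split.calibration), list(split.prediction)


def model_merits(
    name: str,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray | None,
    y_pred_true: np.ndarray | None,
    ga: GAConfig,
    confidence: float = 0.95,
) -> MeritReport:
    """Cross-validation and (optionally) prediction figures of merit of one
    feature matrix, with the latent-variable count chosen by the
    parsimonious LOOCV rule unless the GA config pins it."""
    keep = np.ptp(X_cal, axis=0) > 0
    Xc = X_cal[:, keep]
    lv_hi = min(
        ga.n_lv if ga.n_lv is not None else ga.lv_max,
        X_cal.shape[0] - 2,
        Xc.shape[1],
    )
    curve, cv_preds = loocv_curve(Xc, y_cal, lv_hi)
    n_lv = lv_hi if ga.n_lv is not None else pick_lv(curve, tol=ga.lv_tol)
    cv = figures_of_merit(y_cal, cv_preds[:, n_lv - 1])
    kwargs: dict = {}
    if X_pred is not None and y_pred_true is not None:
        model = fit_pls(Xc, y_cal, n_lv)
        y_hat = predict(model, X_pred[:, keep])
        pm = figures_of_merit(y_pred_true, y_hat)
        bt = bias_t_test(y_pred_true, y_hat, confidence)
        kwargs = {
            "rmsep": pm["rmse"],
            "rep": pm["rep"],
            "r2": pm["r2"],
            "bias": bt["bias"],
            "t_cal": bt["t_cal"],
            "t_crit": bt["t_crit"],
            "bias_significant": bt["significant"],
        }
    return MeritReport(
        model_name=name,
        n_lv=n_lv,
        rmsecv=float(curve[n_lv - 1]),
        rep_cv=cv["rep"],
        r2_cv=cv["r2"],
        **kwargs,
    )


def run_simulate(spec, out_dir: str | Path, image_format: str = "png") -> Path:
    """Generate a synthetic dataset on disk (images + table + spec)."""
    from .synthetic import generate

    dataset = generate(spec)
    return dataset.write_to_dir(out_dir, image_format=image_format)


def _roi_frames(
    grid: ROIGrid, config: RunConfig, row: int, col: int
) -> dict:
    out: dict = {}
    if config.axis1_range is not None:
        a, b = config.axis1_range
        x0 = grid.col_bounds[col - 1] / grid.width
        x1 = grid.col_bounds[col] / grid.width
        out["t1_start"] = a + (b - a) * x0
        out["t1_stop"] = a + (b - a) * x1
    if config.axis2_range is not None:
        a, b = config.axis2_range
        y0 = grid.row_bounds[row - 1] / grid.height
        y1 = grid.row_bounds[row] / grid.height
        out["t2_start"] = a + (b - a) * y0
        out["t2_stop"] = a + (b - a) * y1
    return out


def run_select_roi(config: RunConfig) -> dict:
    """The main pipeline: split, GA per grid size, merit reports.

    For every grid in the sweep the GA (best of ``n_restarts``) selects a
    subimage subset on the calibration samples; the selected model and the
    full-image baseline are then evaluated on the prediction set.  Writes
    ``merits.csv`` (one row per model, shaped like the study's statistical
    summary), per-grid selected-ROI and per-generation RMSECV CSVs, and
    returns everything in memory as well.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples, labels = load_samples(config)
    cal_idx, pred_idx = split_samples(samples, labels, config)
    cal = [samples[i] for i in cal_idx]
    pred = [samples[i] for i in pred_idx]
    y_cal = np.array([s[2] for s in cal])
    y_pred = np.array([s[2] for s in pred])
    cfg_hash = config.config_hash()
    provenance = {"seed": config.seed, "channels": "+".join(config.channels),
                  "config_hash": cfg_hash}

    merit_rows: list[dict] = []
    results: dict = {"config": config, "cal_ids": [s[0] for s in cal],
                     "pred_ids": [s[0] for s in pred], "grids": {}}
    baseline_done = False
    for roi1, roi2 in config.grids:
        grid = partition_image(samples[0][1], roi1, roi2)
        gname = f"{roi1}x{roi2}"
        logger.info("grid %s: building per-cell histograms", gname)
        evaluator = FitnessEvaluator(
            cal, grid, config.channels,
            n_lv=config.ga.n_lv, lv_max=config.ga.lv_max, lv_tol=config.ga.lv_tol,
        )
        ev_pred = FitnessEvaluator(
            pred, grid, config.channels,
            n_lv=config.ga.n_lv, lv_max=config.ga.lv_max, lv_tol=config.ga.lv_tol,
        ) if pred else None

        if not baseline_done:
            # the all-ones chromosome over any grid pools the full image
            all_ones = np.ones(grid.n, dtype=bool)
            Xb_cal = evaluator.feature_matrix(all_ones)
            Xb_pred = ev_pred.feature_matrix(all_ones) if ev_pred else None
            report = model_merits(
                "full_image", Xb_cal, y_cal, Xb_pred, y_pred if pred else None,
                config.ga, config.confidence,
            )
            merit_rows.append({**report.to_row(), "grid": "full", **provenance})
            results["baseline"] = report
            baseline_done = True

        best, runs = run_restarts(config.ga, evaluator)
        logger.info(
            "grid %s: best RMSECV %.4f with %d cells (%d evaluations, %d cache hits)",
            gname, best.best_rmsecv, best.best.n_selected,
            evaluator.n_evaluations, evaluator.n_cache_hits,
        )
        Xg_cal = evaluator.feature_matrix(best.best.genes)
        Xg_pred = ev_pred.feature_matrix(best.best.genes) if ev_pred else None
        report = model_merits(
            f"GA ({gname})", Xg_cal, y_cal, Xg_pred, y_pred if pred else None,
            config.ga, config.confidence,
        )
        merit_rows.append({**report.to_row(), "grid": gname, **provenance})
        results["grids"][gname] = {
            "grid": grid, "best": best, "runs": runs, "report": report,
        }

        roi_rows = []
        for idx in best.best.selected_indices():
            row, col = grid.fold_index(idx)
            roi_rows.append({
                "row": row, "col": col, "linear_index": idx,
                **_roi_frames(grid, config, row, col), **provenance,
            })
        pd.DataFrame(roi_rows).to_csv(
            out_dir / f"selected_roi_{gname}.csv", index=False
        )
        gen_rows = [
            {"run_seed": r.seed, "generation": gi + 1, "best_rmsecv": v}
            for r in runs for gi, v in enumerate(r.best_per_generation)
        ]
        pd.DataFrame(gen_rows).to_csv(
            out_dir / f"generations_{gname}.csv", index=False
        )

    merits = pd.DataFrame(merit_rows, columns=[
        "model", "grid", "n_lv", "rmsecv", "rep_cv", "r2_cv",
        "rmsep", "rep", "r2", "bias", "t_cal", "t_crit", "bias_significant",
        "seed", "channels", "config_hash",
    ])
    merits.to_csv(out_dir / "merits.csv", index=False)
    results["merits"] = merits
    return results


def run_intervals(config: RunConfig, grid_name: str | None = None) -> dict:
    """Interval selection (iPLS and iSPA-PLS) on a prior ROI-selection run.

    Reads the selected-ROI CSV written by :func:`run_select_roi`, rebuilds
    the winning pooled-histogram features on the calibration samples and
    writes the interval table plus the iSPA-PLS choice.
    """
    out_dir = Path(config.output_dir)
    candidates = sorted(out_dir.glob("selected_roi_*.csv"))
    if not candidates:
        raise ArtifactStateError(
            f"no selected_roi_*.csv under {out_dir}; run ROI selection first"
        )
    if grid_name is None:
        grid_name = candidates[0].stem.replace("selected_roi_", "")
    roi_path = out_dir / f"selected_roi_{grid_name}.csv"
    if not roi_path.exists():
        raise ArtifactStateError(f"{roi_path} not found")
    roi = pd.read_csv(roi_path)
    roi1, roi2 = (int(v) for v in grid_name.split("x"))

    samples, labels = load_samples(config)
    cal_idx, _ = split_samples(samples, labels, config)
    cal = [samples[i] for i in cal_idx]
    grid = partition_image(samples[0][1], roi1, roi2)
    fm = build_feature_matrix(
        cal, grid, [int(i) for i in roi["linear_index"]], config.channels
    )
    n_intervals = (
        config.n_intervals
        if config.n_intervals is not None
        else 16 * len(config.channels)
    )
    partition = make_intervals(fm.n_features, n_intervals)
    lv_max = config.ga.lv_max
    lv_tol = config.ga.lv_tol
    table = ipls(fm.X, fm.y, partition, lv_max=lv_max, lv_tol=lv_tol)
    spa = ispa_pls(
        fm.X, fm.y, partition, max_intervals=config.max_intervals,
        lv_max=lv_max, lv_tol=lv_tol,
    )
    provenance = {"seed": config.seed, "config_hash": config.config_hash(),
                  "grid": grid_name}
    bins_per_ch = 256
    ip = table.table.copy()
    ip["channel"] = [
        config.channels[min(s // bins_per_ch, len(config.channels) - 1)]
        for s in ip["start"]
    ]
    for k, v in provenance.items():
        ip[k] = v
    ip.to_csv(out_dir / f"ipls_{grid_name}.csv", index=False)
    spa_df = spa.candidates.copy()
    spa_df["selected"] = [
        tuple(c) == spa.intervals for c in spa_df["intervals"]
    ]
    for k, v in provenance.items():
        spa_df[k] = v
    spa_df.to_csv(out_dir / f"ispa_{grid_name}.csv", index=False)
    return {
        "ipls": table, "ispa": spa, "partition": partition,
        "features": fm, "grid_name": grid_name,
    }
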