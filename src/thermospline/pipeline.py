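"""End-to-end orchestration: simulate -> compress -> train -> evaluate.

Each stage reads and writes plain-text artifacts (CSV tables, JSON models),
so any stage can resume from files produced earlier, and one master seed
deterministically governs the whole run: per-sweep noise seeds and
per-restart initialisation seeds are fanned out from it through
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ann_quant, evaluation, io, sensor_model, spline_compress
from .ann_quant import GridSearchReport, MLPModel, TrainConfig
from .sensor_model import AnalyteMix, CircuitParams, GasResponseParams, HeaterRamp

__all__ = [
    "RunConfig",
    "cmd_simulate",
    "cmd_compress",
    "cmd_train",
    "cmd_evaluate",
    "cmd_run_all",
]

log = logging.getLogger("thermospline")

#: Peak output voltages (V) the amplitude calibration reproduces for
#: noise-free single-gas sweeps at the 0.5 % reference concentration.
DEFAULT_PEAK_TARGETS = {"acetone": 4.65, "ethanol": 4.13}


@dataclass(frozen=True)
class RunConfig:
    """Flat, serialisable configuration of a full pipeline run."""

    # ramp / simulation
    ramp_start: float = 0.0
    ramp_end: float = 5.0
    ramp_step: float = 0.01
    noise_sd: float = 0.02
    replicates: int = 1
    n_levels: int = 13
    peak_v_acetone: float = DEFAULT_PEAK_TARGETS["acetone"]
    peak_v_ethanol: float = DEFAULT_PEAK_TARGETS["ethanol"]
    # spline compression
    degree: int = 3
    initial_spacing: float = 0.1
    target_knots: int = 6
    shared_knots: bool = False
    # training grid
    hidden_sizes: tuple[int, ...] = tuple(range(2, 10))
    activations: tuple[str, ...] = ("Lin", "Log", "Exp", "Tanh")
    restarts: int = 20
    max_iter: int = 200
    prefer_smallest_within: float | None = None
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        self.ramp()  # validates ramp fields
        if self.n_levels < 1 or self.n_levels > 13:
            raise ValueError("n_levels must be in 1..13")
        self.train_config()  # validates grid fields

    def ramp(self) -> HeaterRamp:
        return HeaterRamp(self.ramp_start, self.ramp_end, self.ramp_step)

    def levels(self) -> np.ndarray:
        # top slice of the serial-dilution ladder keeps the 0.5 % anchor
        return sensor_model.concentration_levels()[-self.n_levels :]

    def calibrated_params(self) -> GasResponseParams:
        return sensor_model.calibrate_amplitudes(
            {"acetone": self.peak_v_acetone, "ethanol": self.peak_v_ethanol},
            ramp=self.ramp(),
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            hidden_sizes=tuple(self.hidden_sizes),
            activations=tuple(self.activations),
            restarts=self.restarts,
            max_iter=self.max_iter,
            seed=self.seed,
            prefer_smallest_within=self.prefer_smallest_within,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["activations"] = list(self.activations)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "hidden_sizes" in d:
            d["hidden_sizes"] = tuple(d["hidden_sizes"])
        if "activations" in d:
            d["activations"] = tuple(d["activations"])
        return cls(**d)


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("stage=%s elapsed=%.2fs", stage, time.perf_counter() - self.t0)

    return _Timer()


def cmd_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate the factorial sweep dataset as CSV files plus a manifest.

    Returns the manifest path.  The file set is deterministic for a fixed
    config: rerunning with the same seed rewrites byte-identical artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.calibrated_params()
    levels = config.levels()
    with _timed("simulate"):
        sweeps = sensor_model.generate_dataset(
            levels_eth=levels,
            levels_ace=levels,
            replicates=config.replicates,
            noise_sd=config.noise_sd,
            seed=config.seed,
            ramp=config.ramp(),
            params=params,
        )
        rows = []
        for k, sweep in enumerate(sweeps):
            name = f"sweep_{k:04d}.csv"
            io.write_sweep(sweep, out / name)
            rows.append(
                {
                    "file": name,
                    "c_ethanol_pct": sweep.mix.c_ethanol,
                    "c_acetone_pct": sweep.mix.c_acetone,
                    "replicate": sweep.replicate,
                    "seed": sweep.seed,
                }
            )
        manifest = out / "manifest.csv"
        io.write_manifest(rows, manifest)
    log.info("stage=simulate sweeps=%d manifest=%s", len(rows), manifest)
    return manifest


def compress_sweeps(
    sweeps: list[sensor_model.SensorSweep],
    degree: int = 3,
    initial_spacing: float = 0.1,
    target_knots: int = 6,
    shared: bool = False,
) -> pd.DataFrame:
    """Compress in-memory sweeps to the feature table (no file round-trip)."""
    if not sweeps:
        raise ValueError("no sweeps to compress")
    v_min = float(sweeps[0].heater_v.min())
    v_max = float(sweeps[0].heater_v.max())
    start = spline_compress.initial_knot_vector(v_min, v_max, initial_spacing)
    shared_kv = (
        spline_compress.consensus_knots(sweeps, start, target_knots, degree)
        if shared
        else None
    )
    rows = []
    for k, sweep in enumerate(sweeps):
        if shared_kv is not None:
            fit = spline_compress.fit_lsq_spline(sweep, shared_kv, degree)
        else:
            fit = spline_compress.eliminate_knots(sweep, start, target_knots, degree)
        feats = spline_compress.features(fit)
        row = {
            "file": f"sweep_{k:04d}",
            "c_ethanol_pct": sweep.mix.c_ethanol,
            "c_acetone_pct": sweep.mix.c_acetone,
            "replicate": sweep.replicate,
        }
        row.update({f"f{i+1}": feats[i] for i in range(feats.size)})
        row["sse"] = fit.sse
        row.update(
            {f"knot{i+1}": kv for i, kv in enumerate(fit.model.knots.breakpoints)}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def cmd_compress(
    manifest_path: str | Path,
    out_path: str | Path,
    degree: int = 3,
    initial_spacing: float = 0.1,
    target_knots: int = 6,
    shared: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Compress every sweep in a manifest to its 8-coefficient feature row.

    Malformed sweep files are logged and excluded; the return value carries
    the failure count so callers can exit non-zero while keeping the
    successful rows.
    """
    manifest_path = Path(manifest_path)
    manifest = io.read_manifest(manifest_path)
    base = manifest_path.parent
    sweeps, keep_rows = [], []
    n_failed = 0
    with _timed("compress"):
        for _, rec in manifest.iterrows():
            try:
                sweep = io.read_sweep(
                    base / rec["file"],
                    mix=AnalyteMix(rec["c_ethanol_pct"], rec["c_acetone_pct"]),
                    replicate=int(rec["replicate"]),
                )
            except (ValueError, OSError) as exc:
                log.error("stage=compress file=%s error=%s", rec["file"], exc)
                n_failed += 1
                continue
            sweeps.append(sweep)
            keep_rows.append(rec)
        if sweeps:
            table = compress_sweeps(sweeps, degree, initial_spacing, target_knots, shared)
            table["file"] = [r["file"] for r in keep_rows]
        else:
            table = pd.DataFrame(columns=io.MANIFEST_COLUMNS[:4] + io.feature_columns())
            log.warning("stage=compress empty manifest, empty feature table")
        io.write_feature_table(table, out_path)
    log.info("stage=compress rows=%d failed=%d out=%s", len(table), n_failed, out_path)
    return table, n_failed


def _features_targets(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = table[io.feature_columns()].to_numpy(float)
    c = table[["c_ethanol_pct", "c_acetone_pct"]].to_numpy(float)
    if np.any(c <= 0):
        raise ValueError("training requires strictly positive concentrations (log2 targets)")
    return x, np.log2(c), c


def cmd_train(
    table: pd.DataFrame | str | Path,
    config: RunConfig,
    out_dir: str | Path,
) -> tuple[MLPModel, GridSearchReport]:
    """Run the topology grid search on a feature table; write model + report."""
    if not isinstance(table, pd.DataFrame):
        table = io.read_feature_table(table)
    if len(table) < 3:
        raise ValueError(f"need at least 3 samples to train, got {len(table)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    x, y, _ = _features_targets(table)
    split = ann_quant.split_dataset(len(table), seed=config.seed)
    with _timed("train"):
        report, model = ann_quant.grid_search(x, y, split, config.train_config())
    report.table.to_csv(out / "grid_report.csv", index=False)
    io.save_model(
        model,
        out / "model.json",
        extra={
            "selected_hidden_size": report.selected_hidden_size,
            "selected_activation": report.selected_activation,
            "selected_restart": report.selected_restart,
            "selected_validation_error": report.selected_validation_error,
            "split_seed": config.seed,
            "split": {k: v.tolist() for k, v in split.subsets().items()},
        },
    )
    log.info(
        "stage=train candidates=%d selected=%d-%s val_err=%.3g",
        config.train_config().n_candidates,
        report.selected_hidden_size,
        report.selected_activation,
        report.selected_validation_error,
    )
    return model, report


def cmd_evaluate(
    model: MLPModel | str | Path,
    table: pd.DataFrame | str | Path,
    split: ann_quant.DatasetSplit | None = None,
    out_dir: str | Path | None = None,
) -> evaluation.EvalReport:
    """Score a trained model on a feature table; optionally write CSV/JSON."""
    meta: dict = {}
    if not isinstance(model, MLPModel):
        model, meta = io.load_model(model)
    if not isinstance(table, pd.DataFrame):
        table = io.read_feature_table(table)
    missing = {"c_ethanol_pct", "c_acetone_pct"} - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing analyte columns {sorted(missing)}")
    if split is None:
        if "split" in meta:
            split = ann_quant.DatasetSplit(**meta["split"])
        else:
            split = ann_quant.split_dataset(len(table), seed=meta.get("split_seed", 0))
    x, _, c = _features_targets(table)
    with _timed("evaluate"):
        report = evaluation.evaluate(model, x, c, split)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.table.to_csv(out / "eval_report.csv", index=False)
        report.table.to_json(out / "eval_report.json", orient="records", indent=1)
    log.info("stage=evaluate cells=%d", len(report.table))
    return report


def cmd_run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Full pipeline under a single master seed; returns the stage artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest = cmd_simulate(config, out / "sweeps")
    table, n_failed = cmd_compress(
        manifest,
        out / "features.csv",
        degree=config.degree,
        initial_spacing=config.initial_spacing,
        target_knots=config.target_knots,
        shared=config.shared_knots,
    )
    model, grid = cmd_train(table, config, out)
    split = ann_quant.split_dataset(len(table), seed=config.seed)
    report = cmd_evaluate(model, table, split, out)
    return {
        "manifest": manifest,
        "features": table,
        "n_failed": n_failed,
        "model": model,
        "grid": grid,
        "report": report,
    }
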