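"""Feed-forward network mapping spline features to log2 analyte concentrations.

The quantifier is a multilayer perceptron with 8 inputs (the spline
control-point ordinates), a single hidden layer of 2–9 units with a
selectable activation (Lin, Log, Exp or Tanh), and 2 linear outputs: the
base-2 logarithms of the ethanol and acetone mass fractions.  Working on
log2 targets makes the serial-dilution design linear in target space
(0.5 % -> -1, ..., 0.0078125 % -> -7).

Training minimises the sum of squared errors over the learning set with the
BFGS quasi-Newton algorithm (analytic gradients).  The data are split
70/15/15 into learning/test/validation subsets; the test subset monitors
training (the weight snapshot with the lowest test error seen along the
BFGS trajectory is kept), while the validation subset — untouched during
fitting and snapshotting — drives model selection in the topology grid
search.  The full-scale grid (8 hidden sizes x 4 activations x 1000 random
restarts) enumerates 32,000 candidate networks; the desk-scale default uses
20 restarts per cell.

Inputs are standardised with learning-set statistics and targets are mapped
to [-1, 1] per output, so saturating activations operate in their useful
range.  Reported errors are mean squared error per sample per output on the
scaled-target scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .sensor_model import PCT_TO_PPM, AnalyteMix

__all__ = [
    "ACTIVATIONS",
    "DatasetSplit",
    "MLPModel",
    "TrainConfig",
    "GridSearchReport",
    "TrainingFailure",
    "ConcentrationEstimate",
    "activation",
    "target_transform",
    "inverse_target_transform",
    "split_dataset",
    "train_mlp",
    "grid_search",
    "predict",
]


class TrainingFailure(RuntimeError):
    """Raised when a training restart produces a non-finite loss."""


# name -> (f, f') pairs; "Exp" is the decaying exponential e^(-x)
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "Lin": (lambda x: x, lambda x: np.ones_like(x)),
    "Log": (expit, lambda x: expit(x) * (1.0 - expit(x))),
    "Exp": (lambda x: np.exp(-x), lambda x: -np.exp(-x)),
    "Tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
}


def activation(name: str, x: float | np.ndarray) -> np.ndarray:
    """Evaluate a hidden-layer activation by name (Lin, Log, Exp or Tanh)."""
    if name not in ACTIVATIONS:
        raise KeyError(f"unknown activation {name!r}; expected one of {sorted(ACTIVATIONS)}")
    return ACTIVATIONS[name][0](np.asarray(x, dtype=float))


def target_transform(mix: AnalyteMix) -> tuple[float, float]:
    """Map a mixture to network targets: (log2 ethanol %, log2 acetone %)."""
    if mix.c_ethanol <= 0 or mix.c_acetone <= 0:
        raise ValueError(
            "log2 targets require strictly positive concentrations, "
            f"got ({mix.c_ethanol}, {mix.c_acetone})"
        )
    return float(np.log2(mix.c_ethanol)), float(np.log2(mix.c_acetone))


def inverse_target_transform(log2_eth: float, log2_ace: float) -> AnalyteMix:
    """Invert :func:`target_transform` back to mass fractions in %."""
    return AnalyteMix(c_ethanol=float(2.0**log2_eth), c_acetone=float(2.0**log2_ace))


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint learning/test/validation index sets covering all samples."""

    learning: np.ndarray
    test: np.ndarray
    validation: np.ndarray

    def __post_init__(self) -> None:
        for name in ("learning", "test", "validation"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        all_idx = np.concatenate([self.learning, self.test, self.validation])
        if len(np.unique(all_idx)) != all_idx.size:
            raise ValueError("split subsets overlap")

    @property
    def n(self) -> int:
        return self.learning.size + self.test.size + self.validation.size

    def subsets(self) -> dict[str, np.ndarray]:
        return {"learning": self.learning, "test": self.test, "validation": self.validation}


def split_dataset(
    n: int, ratios: tuple[float, float, float] = (0.70, 0.15, 0.15), seed: int | None = 0
) -> DatasetSplit:
    """Random 70/15/15 partition into learning/test/validation.

    Test and validation sizes are ``floor(ratio * n)`` each; the learning set
    takes the remainder, so n = 169 yields the 119/25/25 split of the
    reference design.
    """
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n_test = int(np.floor(ratios[1] * n))
    n_val = int(np.floor(ratios[2] * n))
    perm = np.random.default_rng(seed).permutation(n)
    return DatasetSplit(
        learning=np.sort(perm[n_test + n_val :]),
        test=np.sort(perm[:n_test]),
        validation=np.sort(perm[n_test : n_test + n_val]),
    )


@dataclass
class MLPModel:
    """8-h-2 perceptron with input/target scalers and training metadata.

    ``w1`` is (8, hidden), ``w2`` is (hidden, 2); outputs are linear.
    ``x_mean``/``x_std`` standardise features; ``y_lo``/``y_hi`` map each
    log2 target to [-1, 1].
    """

    hidden_size: int
    hidden_activation: str
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_lo: np.ndarray
    y_hi: np.ndarray
    seed: int | None = None
    errors: dict = field(default_factory=dict)

    input_dim = 8
    output_dim = 2

    def __post_init__(self) -> None:
        if self.hidden_activation not in ACTIVATIONS:
            raise KeyError(f"unknown activation {self.hidden_activation!r}")
        if self.w1.shape != (self.input_dim, self.hidden_size) or self.w2.shape != (
            self.hidden_size,
            self.output_dim,
        ):
            raise ValueError("weight shapes inconsistent with layer sizes")
        for w in (self.w1, self.b1, self.w2, self.b2):
            if not np.all(np.isfinite(w)):
                raise ValueError("non-finite weights")

    # -- scaling -----------------------------------------------------------
    def scale_x(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.x_mean) / self.x_std

    def unscale_x(self, xs: np.ndarray) -> np.ndarray:
        return np.asarray(xs, float) * self.x_std + self.x_mean

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(y, float) - self.y_lo) / (self.y_hi - self.y_lo) - 1.0

    def unscale_y(self, ys: np.ndarray) -> np.ndarray:
        return (np.asarray(ys, float) + 1.0) / 2.0 * (self.y_hi - self.y_lo) + self.y_lo

    # -- inference ---------------------------------------------------------
    def forward_scaled(self, xs: np.ndarray) -> np.ndarray:
        """Forward pass on already standardised inputs, scaled-target output."""
        f = ACTIVATIONS[self.hidden_activation][0]
        return f(xs @ self.w1 + self.b1) @ self.w2 + self.b2

    def predict_log2(self, features: np.ndarray) -> np.ndarray:
        """Map raw feature rows to (log2 ethanol %, log2 acetone %)."""
        x = np.atleast_2d(np.asarray(features, float))
        if x.shape[1] != self.input_dim:
            raise ValueError(f"expected {self.input_dim} features, got {x.shape[1]}")
        out = self.unscale_y(self.forward_scaled(self.scale_x(x)))
        return out[0] if np.ndim(features) == 1 else out

    # -- serialisation -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "hidden_size": self.hidden_size,
            "hidden_activation": self.hidden_activation,
            "seed": self.seed,
            "errors": self.errors,
            **{
                k: getattr(self, k).tolist()
                for k in ("w1", "b1", "w2", "b2", "x_mean", "x_std", "y_lo", "y_hi")
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        arrays = {
            k: np.asarray(d[k], float)
            for k in ("w1", "b1", "w2", "b2", "x_mean", "x_std", "y_lo", "y_hi")
        }
        return cls(
            hidden_size=d["hidden_size"],
            hidden_activation=d["hidden_activation"],
            seed=d.get("seed"),
            errors=d.get("errors", {}),
            **arrays,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Topology-grid and optimiser settings.

    ``restarts=1000`` reproduces the full 32,000-network enumeration;
    the default 20 keeps a desk-scale search of 640 candidates.
    """

    hidden_sizes: tuple[int, ...] = tuple(range(2, 10))
    activations: tuple[str, ...] = ("Lin", "Log", "Exp", "Tanh")
    restarts: int = 20
    max_iter: int = 200
    gtol: float = 1e-8
    seed: int = 0
    prefer_smallest_within: float | None = None

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        unknown = set(self.activations) - set(ACTIVATIONS)
        if unknown:
            raise ValueError(f"unknown activations {sorted(unknown)}")

    @property
    def n_candidates(self) -> int:
        return len(self.hidden_sizes) * len(self.activations) * self.restarts


@dataclass
class GridSearchReport:
    """Per-cell error summary of the topology grid plus the selection."""

    table: pd.DataFrame
    selected_hidden_size: int
    selected_activation: str
    selected_restart: int
    selected_validation_error: float


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(theta: np.ndarray, d_in: int, h: int, d_out: int):
    i = 0
    w1 = theta[i : i + d_in * h].reshape(d_in, h)
    i += d_in * h
    b1 = theta[i : i + h]
    i += h
    w2 = theta[i : i + h * d_out].reshape(h, d_out)
    i += h * d_out
    b2 = theta[i : i + d_out]
    return w1, b1, w2, b2


def _init_weights(rng: np.random.Generator, d_in: int, h: int, d_out: int) -> np.ndarray:
    w1 = rng.uniform(-0.5, 0.5, (d_in, h)) / np.sqrt(d_in)
    b1 = rng.uniform(-0.5, 0.5, h) / np.sqrt(d_in)
    w2 = rng.uniform(-0.5, 0.5, (h, d_out)) / np.sqrt(h)
    b2 = rng.uniform(-0.5, 0.5, d_out) / np.sqrt(h)
    return _pack(w1, b1, w2, b2)


def _loss_and_grad(theta, xs, ys, act_name, d_in, h, d_out):
    f, df = ACTIVATIONS[act_name]
    w1, b1, w2, b2 = _unpack(theta, d_in, h, d_out)
    z = xs @ w1 + b1
    a = f(z)
    pred = a @ w2 + b2
    r = pred - ys
    loss = float(np.sum(r * r))
    g_pred = 2.0 * r
    g_w2 = a.T @ g_pred
    g_b2 = g_pred.sum(axis=0)
    g_a = g_pred @ w2.T
    g_z = g_a * df(z)
    g_w1 = xs.T @ g_z
    g_b1 = g_z.sum(axis=0)
    return loss, _pack(g_w1, g_b1, g_w2, g_b2)


def train_mlp(
    features: np.ndarray,
    targets: np.ndarray,
    split: DatasetSplit,
    hidden_size: int,
    hidden_activation: str = "Tanh",
    seed: int | None = 0,
    bfgs_opts: dict | None = None,
) -> tuple[MLPModel, tuple[float, float, float]]:
    """Train one network with BFGS on the sum-of-squares learning loss.

    The test subset plays its monitoring role here: at every BFGS iteration
    the test-set error is evaluated and the best-so-far weight snapshot is
    the one returned (an early-stopping variant that never looks at the
    validation subset).  Returns the model and the (learning, test,
    validation) mean-squared errors per sample per output, on the scaled
    target scale.  Deterministic for a fixed seed.
    """
    x = np.asarray(features, float)
    y = np.asarray(targets, float)
    if x.ndim != 2 or x.shape[1] != MLPModel.input_dim:
        raise ValueError(f"features must be (n, {MLPModel.input_dim}), got {x.shape}")
    if y.shape != (x.shape[0], MLPModel.output_dim):
        raise ValueError(f"targets must be (n, {MLPModel.output_dim}), got {y.shape}")
    opts = {"maxiter": 200, "gtol": 1e-8}
    if bfgs_opts:
        opts.update(bfgs_opts)

    learn, test = split.learning, split.test
    x_mean = x[learn].mean(axis=0)
    x_std = x[learn].std(axis=0)
    x_std = np.where(x_std > 0, x_std, 1.0)
    y_lo = y[learn].min(axis=0)
    y_hi = y[learn].max(axis=0)
    y_hi = np.where(y_hi > y_lo, y_hi, y_lo + 1.0)

    xs = (x - x_mean) / x_std
    ys = 2.0 * (y - y_lo) / (y_hi - y_lo) - 1.0

    d_in, h, d_out = MLPModel.input_dim, hidden_size, MLPModel.output_dim
    n_weights = d_in * h + h + h * d_out + d_out
    if learn.size <= n_weights:
        warnings.warn(
            f"learning set ({learn.size}) not larger than free weights ({n_weights}); "
            "the fit is under-determined",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    theta0 = _init_weights(rng, d_in, h, d_out)
    args = (xs[learn], ys[learn], hidden_activation, d_in, h, d_out)
    loss0, _ = _loss_and_grad(theta0, *args)
    if not np.isfinite(loss0):
        raise TrainingFailure("non-finite loss at initialisation")

    def subset_mse(theta: np.ndarray, idx: np.ndarray) -> float:
        w1, b1, w2, b2 = _unpack(theta, d_in, h, d_out)
        f = ACTIVATIONS[hidden_activation][0]
        r = f(xs[idx] @ w1 + b1) @ w2 + b2 - ys[idx]
        return float(np.mean(r * r))

    best = {"theta": theta0.copy(), "test_err": subset_mse(theta0, test)}

    def keep_best(theta: np.ndarray) -> None:
        err = subset_mse(theta, test)
        if np.isfinite(err) and err < best["test_err"]:
            best["test_err"] = err
            best["theta"] = theta.copy()

    res = minimize(
        _loss_and_grad,
        theta0,
        args=args,
        method="BFGS",
        jac=True,
        callback=keep_best,
        options=opts,
    )
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise TrainingFailure("BFGS diverged to non-finite parameters")
    keep_best(res.x)

    theta = best["theta"]
    w1, b1, w2, b2 = _unpack(theta, d_in, h, d_out)
    errs = (
        subset_mse(theta, learn),
        subset_mse(theta, test),
        subset_mse(theta, split.validation),
    )
    model = MLPModel(
        hidden_size=h,
        hidden_activation=hidden_activation,
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        x_mean=x_mean,
        x_std=x_std,
        y_lo=y_lo,
        y_hi=y_hi,
        seed=seed,
        errors={"learning": errs[0], "test": errs[1], "validation": errs[2]},
    )
    return model, errs


def _restart_seed(master: int, hidden: int, act_idx: int, restart: int) -> int:
    ss = np.random.SeedSequence([int(master), hidden, act_idx, restart])
    return int(ss.generate_state(1)[0] % 2**31)


def grid_search(
    features: np.ndarray,
    targets: np.ndarray,
    split: DatasetSplit,
    config: TrainConfig = TrainConfig(),
) -> tuple[GridSearchReport, MLPModel]:
    """Topology grid search: hidden sizes x activations x random restarts.

    Every cell trains ``config.restarts`` networks from distinct seeded
    initialisations and records mean and minimum errors per subset.  The
    selected model is the candidate with the lowest validation error; with
    ``prefer_smallest_within`` set, selection restricts to the smallest
    hidden size whose best validation error is within that relative margin
    of the global optimum (a parsimony rule).  Restarts that diverge are
    counted as failed and excluded; a cell with no surviving restart is
    marked failed and excluded from selection.
    """
    rows = []
    candidates: list[tuple[float, int, str, int, MLPModel]] = []
    bfgs_opts = {"maxiter": config.max_iter, "gtol": config.gtol}
    for hidden in config.hidden_sizes:
        for act_idx, act in enumerate(config.activations):
            errs_cell = []
            n_failed = 0
            for r in range(config.restarts):
                seed = _restart_seed(config.seed, hidden, act_idx, r)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        model, errs = train_mlp(
                            features, targets, split, hidden, act, seed, bfgs_opts
                        )
                except TrainingFailure:
                    n_failed += 1
                    continue
                errs_cell.append(errs)
                candidates.append((errs[2], hidden, act, r, model))
            errs_arr = np.asarray(errs_cell) if errs_cell else np.full((1, 3), np.nan)
            rows.append(
                {
                    "hidden_size": hidden,
                    "activation": act,
                    "mean_learning_err": errs_arr[:, 0].mean(),
                    "mean_test_err": errs_arr[:, 1].mean(),
                    "mean_validation_err": errs_arr[:, 2].mean(),
                    "min_validation_err": errs_arr[:, 2].min(),
                    "n_restarts": config.restarts,
                    "n_failed": n_failed,
                }
            )
    if not candidates:
        raise TrainingFailure("every restart in every grid cell failed")

    best_val = min(c[0] for c in candidates)
    if config.prefer_smallest_within is not None:
        tol = 1.0 + config.prefer_smallest_within
        admissible = [c for c in candidates if c[0] <= best_val * tol]
        smallest = min(c[1] for c in admissible)
        pool = [c for c in admissible if c[1] == smallest]
    else:
        pool = candidates
    sel = min(pool, key=lambda c: c[0])

    report = GridSearchReport(
        table=pd.DataFrame(rows),
        selected_hidden_size=sel[1],
        selected_activation=sel[2],
        selected_restart=sel[3],
        selected_validation_error=sel[0],
    )
    return report, sel[4]


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Predicted analyte concentrations on both reporting scales."""

    c_ethanol_pct: float
    c_acetone_pct: float

    @property
    def c_ethanol_ppm(self) -> float:
        return self.c_ethanol_pct * PCT_TO_PPM

    @property
    def c_acetone_ppm(self) -> float:
        return self.c_acetone_pct * PCT_TO_PPM


def predict(model: MLPModel, feature_vector: np.ndarray) -> ConcentrationEstimate:
    """Forward pass, unscale, and invert the log2 target transform."""
    log2_out = model.predict_log2(np.asarray(feature_vector, float))
    if not np.all(np.isfinite(log2_out)):
        raise ValueError("non-finite network output")
    mix = inverse_target_transform(log2_out[0], log2_out[1])
    return ConcentrationEstimate(c_ethanol_pct=mix.c_ethanol, c_acetone_pct=mix.c_acetone)
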