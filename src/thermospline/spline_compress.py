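"""Least-squares B-spline fitting and greedy knot elimination.

A 501-point sweep is compressed to 8 numbers in two steps.  First the sweep
is fitted with a cubic least-squares B-spline on a dense knot vector (51
knots: the two data endpoints plus 49 interior knots every 0.1 V).  Then
interior knots are removed greedily: at each step every interior knot is
tentatively deleted, the spline is refitted without it, and the knot whose
removal increases the residual sum of squares the least is dropped for good.
The loop stops at 6 knots total, which for a clamped cubic spline means
4 interior knots and hence 4 + 3 + 1 = 8 basis coefficients (control-point
ordinates).  Those 8 coefficients are the feature vector handed to the
regression network.

Because removing a knot restricts the spline space to a subspace, each
removal can only increase (never decrease) the best attainable residual —
the greedy path's error sequence is non-decreasing by construction.

Fitting uses the standard clamped (open-uniform) knot convention: each data
endpoint is repeated degree+1 times in the full knot vector, so the spline
domain is exactly the data range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

from .sensor_model import SensorSweep

__all__ = [
    "KnotVector",
    "BsplineModel",
    "FitResult",
    "FitError",
    "bspline_basis",
    "fit_lsq_spline",
    "initial_knot_vector",
    "eliminate_knots",
    "consensus_knots",
    "features",
    "N_FEATURES",
]

#: Feature-vector length: 6 total knots, cubic -> 4 interior + 3 + 1 = 8.
N_FEATURES = 8

#: Total knot count the greedy elimination targets by default.
DEFAULT_TARGET_KNOTS = 6

DEFAULT_DEGREE = 3


class FitError(RuntimeError):
    """Raised when the least-squares design is rank deficient (empty knot span)."""


@dataclass(frozen=True)
class KnotVector:
    """Strictly increasing breakpoints, first/last pinned to the data endpoints."""

    breakpoints: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.breakpoints, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least the two endpoint knots")
        if not np.all(np.diff(b) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", b)

    def __len__(self) -> int:
        return self.breakpoints.size

    @property
    def interior(self) -> np.ndarray:
        return self.breakpoints[1:-1]

    def without(self, interior_index: int) -> "KnotVector":
        """A copy with interior knot ``interior_index`` (0-based) removed."""
        n_int = len(self) - 2
        if not 0 <= interior_index < n_int:
            raise IndexError(f"interior index {interior_index} out of range [0, {n_int})")
        return KnotVector(np.delete(self.breakpoints, interior_index + 1))

    def full_knots(self, degree: int) -> np.ndarray:
        """Clamped full knot vector: endpoints repeated degree+1 times."""
        b = self.breakpoints
        return np.concatenate(
            [np.full(degree + 1, b[0]), b[1:-1], np.full(degree + 1, b[-1])]
        )


@dataclass(frozen=True)
class BsplineModel:
    """Degree, breakpoints and control-point ordinates of one fitted spline."""

    degree: int
    knots: KnotVector
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        expected = len(self.knots) - 2 + self.degree + 1
        if c.size != expected:
            raise ValueError(
                f"coefficient count law violated: got {c.size}, "
                f"expected interior + degree + 1 = {expected}"
            )
        object.__setattr__(self, "coefficients", c)

    def spline(self) -> BSpline:
        return BSpline(self.knots.full_knots(self.degree), self.coefficients, self.degree)

    def __call__(self, v: float | np.ndarray) -> np.ndarray:
        return self.spline()(v)

    def greville_abscissae(self) -> np.ndarray:
        """Knot-average x-locations paired with each coefficient (control point)."""
        t = self.knots.full_knots(self.degree)
        k = self.degree
        return np.array(
            [t[j + 1 : j + k + 1].mean() for j in range(self.coefficients.size)]
        )


@dataclass(frozen=True)
class FitResult:
    model: BsplineModel
    sse: float

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError(f"sse must be >= 0, got {self.sse}")


def bspline_basis(
    v: float | np.ndarray, knots: KnotVector, degree: int = DEFAULT_DEGREE
) -> np.ndarray:
    """All B-spline basis functions evaluated at ``v`` (scalar -> 1-D vector).

    The basis is non-negative and sums to one at every point of the knot
    span (partition of unity).  Points outside the span raise ``ValueError``.
    """
    v_arr = np.atleast_1d(np.asarray(v, dtype=float))
    lo, hi = knots.breakpoints[0], knots.breakpoints[-1]
    if np.any(v_arr < lo) or np.any(v_arr > hi):
        raise ValueError(f"evaluation point outside knot span [{lo}, {hi}]")
    design = BSpline.design_matrix(v_arr, knots.full_knots(degree), degree).toarray()
    return design[0] if np.isscalar(v) or np.ndim(v) == 0 else design


def _design_matrix(x: np.ndarray, knots: KnotVector, degree: int):
    return BSpline.design_matrix(x, knots.full_knots(degree), degree)


def _empty_spans(x: np.ndarray, knots: KnotVector) -> list[tuple[float, float]]:
    b = knots.breakpoints
    out = []
    for lo, hi in zip(b[:-1], b[1:]):
        inside = np.count_nonzero((x >= lo) & (x < hi))
        if inside == 0:
            out.append((float(lo), float(hi)))
    return out

def _lsq_coefficients(x: np.ndarray, y: np.ndarray, knots: KnotVector, degree: int):
    """Normal-equations LSQ solve with one iterative-refinement step."""
    a = _design_matrix(x, knots, degree)
    ata = (a.T @ a).toarray()
    atb = a.T @ y
    try:
        chol = cho_factor(ata)
    except np.linalg.LinAlgError as exc:
        spans = _empty_spans(x, knots)
        raise FitError(
            f"rank-deficient spline design; data-free knot spans: {spans}"
        ) from exc
    coef = cho_solve(chol, atb)
    # one refinement step recovers the accuracy lost to squaring the condition number
    resid = y - a @ coef
    coef = coef + cho_solve(chol, a.T @ resid)
    resid = y - a @ coef
    return coef, float(resid @ resid)


def fit_lsq_spline(
    sweep: SensorSweep, knots: KnotVector, degree: int = DEFAULT_DEGREE
) -> FitResult:
    """Least-squares B-spline fit of one sweep on a fixed knot vector.

    Coefficients minimise the residual sum of squares over all sweep samples;
    an LSQ spline is an approximant, not an interpolant — it need not pass
    through any data point.  Raises :class:`FitError` when some knot span
    contains no data (rank-deficient design), reporting the offending spans.
    """
    x = np.asarray(sweep.heater_v, dtype=float)
    y = np.asarray(sweep.out_v, dtype=float)
    n_coef = len(knots) - 2 + degree + 1
    if x.size < n_coef:
        raise FitError(f"need at least {n_coef} samples, got {x.size}")
    coef, sse = _lsq_coefficients(x, y, knots, degree)
    return FitResult(model=BsplineModel(degree=degree, knots=knots, coefficients=coef), sse=sse)


def initial_knot_vector(v_min: float, v_max: float, spacing: float = 0.1) -> KnotVector:
    """Endpoints plus evenly spaced interior knots every ``spacing`` volts.

    The default (0, 5, 0.1) gives the 51-knot starting vector: endpoints and
    49 interior knots.  A spacing at or beyond the domain width degenerates
    to the endpoints alone.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    if v_max - v_min < spacing:
        raise ValueError(f"domain width {v_max - v_min} smaller than spacing {spacing}")
    n_interior = int(np.floor((v_max - v_min) / spacing - 1e-9))
    interior = v_min + spacing * np.arange(1, n_interior + 1)
    return KnotVector(np.concatenate([[v_min], interior, [v_max]]))


def _greedy_eliminate(
    xy_sets: Sequence[tuple[np.ndarray, np.ndarray]],
    start: KnotVector,
    target_total: int,
    degree: int,
) -> tuple[KnotVector, list[float]]:
    """Shared greedy loop: drop the interior knot whose removal least increases
    the summed sse over all (x, y) sets.  Ties break to the leftmost knot."""
    knots = start
    path: list[float] = []

    def total_sse(kv: KnotVector) -> float:
        return sum(_lsq_coefficients(x, y, kv, degree)[1] for x, y in xy_sets)

    path.append(total_sse(knots))
    while len(knots) > target_total:
        best_sse = np.inf
        best_idx = -1
        for i in range(len(knots) - 2):
            candidate = knots.without(i)
            sse = total_sse(candidate)
            if sse < best_sse:  # strict: ties keep the leftmost candidate
                best_sse = sse
                best_idx = i
        knots = knots.without(best_idx)
        path.append(best_sse)
    return knots, path


def eliminate_knots(
    sweep: SensorSweep,
    start: KnotVector,
    target_total: int = DEFAULT_TARGET_KNOTS,
    degree: int = DEFAULT_DEGREE,
    return_path: bool = False,
):
    """Greedy backward knot elimination down to ``target_total`` knots.

    Each step refits the spline once per interior-knot candidate and
    permanently removes the knot whose deletion gives the smallest refit
    residual; ties break to the leftmost knot.  Returns the final
    :class:`FitResult` (and, with ``return_path=True``, the non-decreasing
    sse sequence along the elimination path, starting at the full fit).
    """
    if target_total < 2:
        raise ValueError(f"target_total must be >= 2 (the endpoints), got {target_total}")
    if target_total > len(start):
        raise ValueError(
            f"target_total {target_total} exceeds starting knot count {len(start)}"
        )
    x = np.asarray(sweep.heater_v, dtype=float)
    y = np.asarray(sweep.out_v, dtype=float)
    knots, path = _greedy_eliminate([(x, y)], start, target_total, degree)
    fit = fit_lsq_spline(sweep, knots, degree)
    return (fit, path) if return_path else fit


def consensus_knots(
    sweeps: Iterable[SensorSweep],
    start: KnotVector,
    target_total: int = DEFAULT_TARGET_KNOTS,
    degree: int = DEFAULT_DEGREE,
) -> KnotVector:
    """One shared knot vector minimising the summed sse over a calibration set.

    Greedy elimination as in :func:`eliminate_knots`, but each candidate
    removal is scored by the total residual over all sweeps.  Fitting every
    sweep on the shared knots keeps the feature space consistent across
    recordings (the per-sweep default instead mirrors independent per-curve
    compression).
    """
    if target_total < 2:
        raise ValueError(f"target_total must be >= 2, got {target_total}")
    xy = [(np.asarray(s.heater_v, float), np.asarray(s.out_v, float)) for s in sweeps]
    if not xy:
        raise ValueError("need at least one sweep")
    knots, _ = _greedy_eliminate(xy, start, target_total, degree)
    return knots


def features(fit: FitResult) -> np.ndarray:
    """The 8 control-point ordinates of a 6-knot cubic fit, in basis order."""
    coef = fit.model.coefficients
    if coef.size != N_FEATURES:
        raise ValueError(
            f"feature extraction requires exactly {N_FEATURES} coefficients, got {coef.size}"
        )
    return coef.copy()
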