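"""Zero-anchored thermal performance curve.

Sprint velocity as a function of body temperature is fitted with a
penalized cubic regression spline: a modest B-spline basis with the
integrated-squared-second-derivative wiggliness penalty.
The observed (temperature, max velocity) points are augmented with two
zero-velocity pseudo-observations at the tolerance limits — CTmin below
and CTgape above — so the curve is anchored at zero where the animal
cannot move. Predicted performance is reported as a percentage of the
curve's maximum over a fine evaluation grid, which is the scale on
which landscape projections are expressed.

The smoother defaults (5 basis functions, penalty weight 0.1) match the
trait-study convention for this kind of sparse five-temperature design;
exact equivalence with any particular GAM package is not a goal — the
curve is validated against closed-form oracles and its anchor/peak
properties instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.interpolate import BSpline

from .errors import AnchorError, UnderdeterminedFitError

EVAL_STEP_C = 0.1
"""Evaluation-grid step (°C) for locating the curve maximum."""


def _curvature_penalty(knots: np.ndarray, degree: int) -> np.ndarray:
    """Gram matrix of basis second derivatives, P_jk = ∫ B_j'' B_k'' dt.

    For cubic splines the second derivatives are piecewise linear, so
    2-point Gauss–Legendre per knot interval integrates the products
    exactly.
    """
    n_basis = len(knots) - degree - 1
    uniq = np.unique(knots)
    gx, gw = np.polynomial.legendre.leggauss(2)
    xs, ws = [], []
    for a, b in zip(uniq[:-1], uniq[1:]):
        xs.append((b - a) / 2 * gx + (a + b) / 2)
        ws.append((b - a) / 2 * gw)
    xs = np.concatenate(xs)
    ws = np.concatenate(ws)
    d2 = np.empty((len(xs), n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        d2[:, j] = BSpline(knots, coef, degree)(xs, nu=2)
    return (d2 * ws[:, None]).T @ d2


def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix of cubic B-spline basis functions evaluated at x."""
    n_basis = len(knots) - degree - 1
    cols = []
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        cols.append(BSpline(knots, coef, degree, extrapolate=False)(x))
    return np.nan_to_num(np.column_stack(cols))


@dataclass(frozen=True)
class PerformanceCurve:
    """Fitted thermal performance curve.

    Predictions are clipped to be non-negative and are zero outside the
    anchor interval; ``p_max`` and ``argmax_T`` are taken on a 0.1 °C
    grid over [anchor_low, anchor_high].
    """

    anchor_low: float
    anchor_high: float
    basis_dimension: int
    smoothing: float
    knots: tuple[float, ...]
    coefficients: tuple[float, ...]
    p_max: float
    argmax_T: float

    def predict(self, t) -> np.ndarray:
        """Predicted velocity (m/s) at temperature(s) ``t``, clipped ≥ 0.

        Temperatures outside [anchor_low, anchor_high] predict 0.
        """
        t = np.asarray(t, dtype=float)
        spline = BSpline(
            np.asarray(self.knots), np.asarray(self.coefficients), 3,
            extrapolate=False,
        )
        v = np.nan_to_num(spline(t))
        v = np.clip(v, 0.0, None)
        # the anchors are zero-velocity by definition, so the closed
        # boundary (and anything beyond it) predicts exactly 0
        v = np.where((t <= self.anchor_low) | (t >= self.anchor_high), 0.0, v)
        return v

    def performance_percent(self, t) -> np.ndarray:
        """Predicted performance as a percentage of the curve maximum.

        Values lie in [0, 100]; the argmax temperature maps to 100 and
        the anchors (and anything beyond them) to 0.
        """
        return 100.0 * np.minimum(self.predict(t) / self.p_max, 1.0)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "anchor_low": self.anchor_low,
            "anchor_high": self.anchor_high,
            "basis_dimension": self.basis_dimension,
            "smoothing": self.smoothing,
            "knots": list(self.knots),
            "coefficients": list(self.coefficients),
            "p_max": self.p_max,
            "argmax_T": self.argmax_T,
        }

    def save(self, path: str | Path) -> None:
        """Write the curve to a small JSON file so projection can run
        without refitting."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "PerformanceCurve":
        return cls(
            anchor_low=float(d["anchor_low"]),
            anchor_high=float(d["anchor_high"]),
            basis_dimension=int(d["basis_dimension"]),
            smoothing=float(d["smoothing"]),
            knots=tuple(float(k) for k in d["knots"]),
            coefficients=tuple(float(c) for c in d["coefficients"]),
            p_max=float(d["p_max"]),
            argmax_T=float(d["argmax_T"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PerformanceCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_performance_curve(
    points: Iterable[tuple[float, float]],
    anchor_low: float,
    anchor_high: float,
    basis_dimension: int = 5,
    smoothing: float = 0.1,
) -> PerformanceCurve:
    """Fit the zero-anchored penalized-spline performance curve.

    Parameters
    ----------
    points
        (temperature °C, velocity m/s) observations — each individual's
        maximal segment velocity at each test temperature, pooled.
    anchor_low, anchor_high
        Temperatures at which velocity is pinned to zero (population
        mean CTmin and CTgape by convention); they must bracket every
        observed temperature.
    basis_dimension
        Number of cubic B-spline basis functions (default 5).
    smoothing
        Weight of the integrated-squared-second-derivative penalty
        (default 0.1). Larger values give a smoother curve.
    """
    pts = [(float(t), float(v)) for t, v in points]
    if len({t for t, _ in pts}) < 3:
        raise UnderdeterminedFitError("need at least 3 distinct temperatures")
    temps = np.array([t for t, _ in pts])
    if anchor_low >= temps.min() or anchor_high <= temps.max():
        raise AnchorError(
            f"anchors ({anchor_low}, {anchor_high}) must strictly bracket the "
            f"data range ({temps.min()}, {temps.max()})"
        )

    # anchor pseudo-observations weighted heavily so the curve is pinned
    # near zero at the tolerance limits
    x = np.concatenate([temps, [anchor_low, anchor_high]])
    y = np.concatenate([[v for _, v in pts], [0.0, 0.0]])
    w = np.concatenate([np.ones(len(pts)), [len(pts), len(pts)]])

    degree = 3
    n_interior = basis_dimension - degree - 1
    interior = np.linspace(anchor_low, anchor_high, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [[anchor_low] * (degree + 1), interior, [anchor_high] * (degree + 1)]
    )
    B = _bspline_design(x, knots, degree)

    # integrated squared second derivative — the cubic regression spline
    # wiggliness penalty, so larger smoothing always yields a curve with
    # no more curvature
    P = _curvature_penalty(knots, degree)
    lhs = (B * w[:, None]).T @ B + smoothing * P
    rhs = (B * w[:, None]).T @ y
    coef = np.linalg.solve(lhs, rhs)

    grid = np.arange(anchor_low, anchor_high + EVAL_STEP_C / 2, EVAL_STEP_C)
    spline = BSpline(knots, coef, degree, extrapolate=False)
    pred = np.clip(np.nan_to_num(spline(grid)), 0.0, None)
    i_max = int(pred.argmax())
    if pred[i_max] <= 0:
        raise UnderdeterminedFitError("fitted curve has no positive maximum")

    return PerformanceCurve(
        anchor_low=float(anchor_low),
        anchor_high=float(anchor_high),
        basis_dimension=int(basis_dimension),
        smoothing=float(smoothing),
        knots=tuple(float(k) for k in knots),
        coefficients=tuple(float(c) for c in coef),
        p_max=float(pred[i_max]),
        argmax_T=float(grid[i_max]),
    )


def performance_percent(curve: PerformanceCurve, t) -> np.ndarray:
    """Functional alias for :meth:`PerformanceCurve.performance_percent`."""
    return curve.performance_percent(t)


def pooled_points(
    max_velocities: dict[str, dict[float, float]]
) -> list[tuple[float, float]]:
    """Flatten per-individual max velocities into pooled (T, v) points."""
    pts: list[tuple[float, float]] = []
    for per in max_velocities.values():
        pts.extend(sorted(per.items()))
    return pts
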