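"""Gravimetric tie-line determination for ABS phase diagrams.

A biphasic mixture (Xm, Ym) with a known phase-mass fraction alpha (mass of
the IL-rich phase over total mixture mass) splits into two coexisting
phases whose compositions both lie on the binodal and obey the lever rule:

    Y_IL  = f(X_IL)                     (IL-rich endpoint on the curve)
    Y_non = f(X_non)                    (non-IL-rich endpoint on the curve)
    Ym    = alpha*Y_IL + (1-alpha)*Y_non
    Xm    = alpha*X_IL + (1-alpha)*X_non

Substituting the mass balance X_IL = (Xm - (1-alpha)*X_non)/alpha reduces
the system to a single equation in X_non, solved here with a bracketed
Brent root search over the physically admissible interval; this is
deterministic and globally convergent where a solution exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .binodal import BinodalModel, classify_mixture, evaluate_binodal
from .chemistry import TernaryComposition, validate_composition

__all__ = [
    "TieLineProblem",
    "TieLine",
    "TieLineError",
    "solve_tieline",
    "tieline_metrics",
    "lever_rule_alpha",
]

#: Max absolute residual accepted when substituting endpoints back into the
#: four tie-line equations.
RESIDUAL_TOL = 1e-8


class TieLineError(RuntimeError):
    """Tie-line system has no admissible solution (monophasic mixture,
    degenerate lever rule or no root in the physical box)."""


@dataclass(frozen=True)
class TieLineProblem:
    """A tie-line determination: fitted binodal + mixture point + alpha."""

    model: BinodalModel
    x_m: float
    y_m: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        comp = self.mixture_composition()
        if classify_mixture(self.model, comp) != "biphasic":
            raise TieLineError(
                f"mixture ({self.x_m}, {self.y_m}) is not strictly inside the biphasic region"
            )

    def mixture_composition(self) -> TernaryComposition:
        return validate_composition(self.y_m, self.x_m, 100.0 - self.x_m - self.y_m)


@dataclass(frozen=True)
class TieLine:
    """Solved coexisting-phase compositions and derived metrics."""

    il_rich: tuple[float, float]      # (X_IL, Y_IL), the high-Y endpoint
    non_il_rich: tuple[float, float]  # (X_non, Y_non)
    length: float
    slope: float
    vertical: bool
    residual: float


def _max_residual(model: BinodalModel, problem: TieLineProblem, x_il, y_il, x_non, y_non) -> float:
    a = problem.alpha
    res = (
        y_il - evaluate_binodal(model, x_il),
        y_non - evaluate_binodal(model, x_non),
        y_il - (problem.y_m / a - (1 - a) / a * y_non),
        x_il - (problem.x_m / a - (1 - a) / a * x_non),
    )
    return max(abs(r) for r in res)


def solve_tieline(problem: TieLineProblem, coincidence_tol: float = 1e-6) -> TieLine:
    """Solve the four-equation tie-line system for both phase endpoints.

    The IL-rich endpoint is the one with the larger IL content Y (the
    denser, IL-rich phase).  Raises :class:`TieLineError` when no root
    exists in the physical box [0, 100]^2 or the endpoints coincide
    (mixture effectively on the binodal).
    """
    model, a = problem.model, problem.alpha
    x_m, y_m = problem.x_m, problem.y_m

    def x_il_of(x_non: float) -> float:
        # clamp the float roundoff at the X_IL = 0 edge of the bracket
        return max((x_m - (1 - a) * x_non) / a, 0.0)

    def h(x_non: float) -> float:
        # lever-rule Y closure along the binodal
        return a * evaluate_binodal(model, x_il_of(x_non)) + (1 - a) * evaluate_binodal(model, x_non) - y_m

    # Admissible X_non: at least the mixture's X (the non-IL-rich phase is
    # richer in the second phase former) and small enough that X_IL >= 0.
    upper = min(x_m / (1 - a), 100.0)
    if upper <= x_m:
        raise TieLineError("no admissible interval for the non-IL-rich endpoint")

    # Scan a geometric refinement of [x_m, upper] for a sign change; h < 0 at
    # the mixture itself (biphasic mixtures lie above the curve).
    grid = np.linspace(x_m, upper, 257)
    h_vals = [h(x) for x in grid]
    bracket = None
    for lo, hi, h_lo, h_hi in zip(grid[:-1], grid[1:], h_vals[:-1], h_vals[1:]):
        if h_lo == 0.0:
            bracket = (lo, lo)
            break
        if h_lo * h_hi < 0:
            bracket = (lo, hi)
            break
    if bracket is None:
        raise TieLineError(
            "no root in the admissible box: mixture may be outside the region "
            "where the fitted binodal closes the lever rule"
        )
    if bracket[0] == bracket[1]:
        x_non = bracket[0]
    else:
        x_non = brentq(h, *bracket, xtol=1e-13, rtol=8.9e-16)

    x_il = x_il_of(x_non)
    y_il = evaluate_binodal(model, x_il)
    y_non = evaluate_binodal(model, x_non)

    if math.hypot(x_il - x_non, y_il - y_non) < coincidence_tol:
        raise TieLineError("endpoints coincide: mixture lies on the binodal (degenerate lever rule)")
    for coord in (x_il, y_il, x_non, y_non):
        if not -1e-9 <= coord <= 100.0 + 1e-9:
            raise TieLineError(f"solution coordinate {coord} outside the physical box [0, 100]")
    if y_il <= y_non:
        raise TieLineError("solved IL-rich endpoint does not have the larger IL content")

    residual = _max_residual(model, problem, x_il, y_il, x_non, y_non)
    if residual > RESIDUAL_TOL:
        raise TieLineError(f"solver residual {residual:.2e} exceeds {RESIDUAL_TOL:.0e}")

    length, slope, vertical = _metrics(x_il, y_il, x_non, y_non)
    return TieLine(
        il_rich=(x_il, y_il),
        non_il_rich=(x_non, y_non),
        length=length,
        slope=slope,
        vertical=vertical,
        residual=residual,
    )


def _metrics(x_il, y_il, x_non, y_non):
    dx = x_il - x_non
    dy = y_il - y_non
    length = math.hypot(dx, dy)
    if dx == 0.0:
        return length, math.inf, True
    return length, dy / dx, False


def tieline_metrics(tl: TieLine) -> tuple[float, float]:
    """Tie-line length (TLL, wt% units) and slope (STL, dimensionless).

    A vertical tie-line reports ``math.inf`` slope with ``tl.vertical`` set.
    """
    (x_il, y_il), (x_non, y_non) = tl.il_rich, tl.non_il_rich
    length, slope, _ = _metrics(x_il, y_il, x_non, y_non)
    return length, slope


def lever_rule_alpha(mixture, il_rich, non_il_rich) -> dict:
    """Per-axis lever-rule alpha and a closure diagnostic.

    alpha_Y = (Ym - Y_non) / (Y_IL - Y_non) and analogously on X.  An axis on
    which the endpoints coincide is skipped (reported as None).  The
    consistency entry is |alpha_Y - alpha_X| when both are defined.
    """
    xm, ym = mixture
    x_il, y_il = il_rich
    x_non, y_non = non_il_rich
    if il_rich == non_il_rich:
        raise ValueError("endpoints coincide; lever rule undefined")
    alpha_y = (ym - y_non) / (y_il - y_non) if y_il != y_non else None
    alpha_x = (xm - x_non) / (x_il - x_non) if x_il != x_non else None
    consistency = abs(alpha_y - alpha_x) if alpha_y is not None and alpha_x is not None else None
    return {"alpha_y": alpha_y, "alpha_x": alpha_x, "consistency": consistency}
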