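"""Merchuck binodal-curve model for ABS phase diagrams.

The binodal (solubility curve) separates monophasic from biphasic mixtures
in the (non-IL wt%, IL wt%) plane.  The canonical empirical form is the
three-parameter Merchuck curve

    Y = A * exp(B * X**0.5 - C * X**3)

with Y the IL weight percentage and X the second phase former's.  A literal
polynomial variant ``Y = A * (B * X**0.5 - C * X**3)`` is retained behind
``form="literal"`` for comparison with sources that typeset the equation
without the exponential; it cannot reproduce sigmoidal binodals and is not
the default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import lmfit
import numpy as np

from .chemistry import TernaryComposition

__all__ = [
    "BinodalPoint",
    "BinodalModel",
    "BinodalFitError",
    "evaluate_binodal",
    "fit_binodal",
    "classify_mixture",
]

#: wt% tolerance inside which a mixture is classified as lying on the curve.
ON_CURVE_TOL = 1e-6


@dataclass(frozen=True)
class BinodalPoint:
    """One (X, Y) titration point: X = non-IL wt%, Y = IL wt%."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"binodal point ({self.x}, {self.y}) has a negative coordinate")
        if self.x + self.y > 100.0:
            raise ValueError(f"binodal point ({self.x}, {self.y}) exceeds 100 wt% total")


@dataclass(frozen=True)
class BinodalModel:
    """Fitted Merchuck parameters plus fit diagnostics."""

    a: float
    b: float
    c: float
    form: str = "exponential"
    fit_rss: float = 0.0
    n_points: int = 0
    stderr: tuple[float, float, float] | None = None
    max_abs_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "literal"):
            raise ValueError(f"unknown binodal form {self.form!r}")
        if self.fit_rss < 0:
            raise ValueError("fit_rss must be >= 0")

    def __call__(self, x):
        return evaluate_binodal(self, x)


class BinodalFitError(RuntimeError):
    """Raised when the multi-start least-squares fit fails; carries the best
    candidate found so far in ``best_candidate`` (may be None)."""

    def __init__(self, message: str, best_candidate: BinodalModel | None = None):
        super().__init__(message)
        self.best_candidate = best_candidate


def _merchuck(x, a, b, c, form):
    x = np.asarray(x, dtype=float)
    inner = b * np.sqrt(x) - c * x**3
    if form == "exponential":
        return a * np.exp(inner)
    return a * inner


def evaluate_binodal(model: BinodalModel, x):
    """Evaluate the binodal curve at non-IL wt% ``x`` (scalar or array).

    Raises on negative ``x`` (the square root is undefined there).
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("binodal evaluation requires x >= 0")
    y = _merchuck(x_arr, model.a, model.b, model.c, model.form)
    return float(y) if np.isscalar(x) or x_arr.ndim == 0 else y


# Deterministic multi-start grid: magnitudes and sign patterns for (B, C).
# Typical salting-out binodals have B < 0 (initial decay) and small C > 0
# (sharp drop at high X), but all sign patterns are tried.
_B_STARTS = (-1.0, -0.3, -0.05, 0.05, 0.3)
_C_STARTS = (1e-6, 1e-4, 1e-2)


def fit_binodal(points, form: str = "exponential") -> BinodalModel:
    """Least-squares Merchuck fit over a deterministic multi-start grid.

    Parameters
    ----------
    points:
        Sequence of :class:`BinodalPoint` (or (x, y) pairs); at least three
        distinct x values are required.
    form:
        ``"exponential"`` (default) or ``"literal"``.

    Returns
    -------
    BinodalModel with parameter estimates, standard errors (when the
    Jacobian is well conditioned), RSS and the largest absolute residual.
    """
    pts = [p if isinstance(p, BinodalPoint) else BinodalPoint(*p) for p in points]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 points to fit a 3-parameter binodal, got {len(pts)}")
    x = np.array([p.x for p in pts], dtype=float)
    y = np.array([p.y for p in pts], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct x values; degenerate design")
    if form == "exponential" and np.any(y <= 0):
        raise ValueError("exponential form requires all y > 0")

    def residual(params):
        return _merchuck(x, params["a"], params["b"], params["c"], form) - y

    a0 = float(np.max(y)) if form == "exponential" else 1.0
    best = None
    for b0, c0 in itertools.product(_B_STARTS, _C_STARTS):
        for c_sign in (1.0, -1.0):
            params = lmfit.Parameters()
            params.add("a", value=a0)
            params.add("b", value=b0)
            params.add("c", value=c_sign * c0)
            try:
                res = lmfit.minimize(
                    residual, params, method="leastsq", nan_policy="raise",
                    xtol=1e-14, ftol=1e-14,
                )
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr - 1e-12:
                best = res
    if best is None:
        raise BinodalFitError("no multi-start candidate converged")

    p = best.params
    stderr = None
    if all(p[k].stderr is not None for k in ("a", "b", "c")):
        stderr = (p["a"].stderr, p["b"].stderr, p["c"].stderr)
    resid = _merchuck(x, p["a"].value, p["b"].value, p["c"].value, form) - y
    model = BinodalModel(
        a=p["a"].value,
        b=p["b"].value,
        c=p["c"].value,
        form=form,
        fit_rss=float(np.sum(resid**2)),
        n_points=len(pts),
        stderr=stderr,
        max_abs_residual=float(np.max(np.abs(resid))),
    )
    if not best.success:
        raise BinodalFitError("least-squares fit did not converge", best_candidate=model)
    return model


def classify_mixture(model: BinodalModel, comp: TernaryComposition, tol: float = ON_CURVE_TOL) -> str:
    """Classify a mixture as ``"monophasic"``, ``"biphasic"`` or ``"on_curve"``.

    Phase separation occurs for mixtures whose IL content lies above the
    binodal at their non-IL content.
    """
    y_curve = evaluate_binodal(model, comp.w_non)
    delta = comp.w_il - y_curve
    if delta > tol:
        return "biphasic"
    if delta < -tol:
        return "monophasic"
    return "on_curve"
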