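"""MST binding analysis: serial-dilution designs and 1:1 mass-action Kd fits.

Microscale thermophoresis reports a normalized fluorescence (Fnorm) of a
labeled target protein across a serial dilution of ligand.  For a 1:1
equilibrium with total ligand L, total target T and dissociation constant
Kd, the bound fraction is the exact quadratic mass-action solution

    fb = ((L + T + Kd) - sqrt((L + T + Kd)^2 - 4*L*T)) / (2*T)

which reduces to the hyperbola L/(L + Kd) as T -> 0.  The fit estimates
(Kd, f_unbound, f_bound) from Fnorm = f_unbound + (f_bound - f_unbound)*fb.

All concentrations are mM; the labeled-target concentration is typically
given in uM and converted by the caller (0.41 uM = 4.1e-4 mM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "TitrationSeries",
    "TitrationFit",
    "serial_dilution",
    "fraction_bound_model",
    "fit_kd",
    "capillary_quality_filter",
]

#: Default labeled-protein concentration in mM (0.41 uM).
DEFAULT_TARGET_MM = 4.1e-4
#: Default capillary-rejection threshold: ligand concentrations above this
#: suffer fluorescence inhomogeneity and are excluded from fitting.
DEFAULT_MAX_CONC_MM = 50.0
#: Minimum usable points for a Kd fit.
MIN_POINTS = 8
#: Amplitude must exceed this many residual SDs for binding to be declared.
DETECTION_SIGMA = 3.0


@dataclass(frozen=True)
class TitrationSeries:
    """A dose-response series: ligand concentrations (mM) and Fnorm values."""

    ligand_conc: tuple[float, ...]
    fnorm: tuple[float, ...]
    target_conc: float = DEFAULT_TARGET_MM  # mM
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if len(self.ligand_conc) != len(self.fnorm):
            raise ValueError("ligand_conc and fnorm lengths differ")
        if any(c < 0 for c in self.ligand_conc):
            raise ValueError("ligand concentrations must be non-negative")
        if self.target_conc <= 0:
            raise ValueError("target concentration must be positive")

    def __len__(self) -> int:
        return len(self.ligand_conc)


@dataclass(frozen=True)
class TitrationFit:
    kd: float | None            # mM; None when no binding detected
    kd_se: float | None
    f_unbound: float
    f_bound: float
    fraction_bound: tuple[float, ...]
    converged: bool
    binding_detected: bool
    residual_sd: float


def serial_dilution(start_conc: float, n: int = 16, ratio: float = 2.0) -> np.ndarray:
    """Concentrations of an n-point serial dilution: start / ratio**i.

    A 16-point 1:1 (ratio 2) series from 100 mM ends at 100/2**15 =
    3.0518e-3 mM.
    """
    if start_conc <= 0:
        raise ValueError("start_conc must be positive")
    if n < 2:
        raise ValueError("need at least 2 dilution points")
    if ratio <= 1:
        raise ValueError("dilution ratio must exceed 1")
    return start_conc / ratio ** np.arange(n, dtype=float)


def fraction_bound_model(ligand, target: float, kd: float):
    """Exact 1:1 mass-action bound fraction of the target.

    Vectorizes over ``ligand``; all concentrations share one unit (mM here).
    """
    if target <= 0 or kd <= 0:
        raise ValueError("target and kd must be positive")
    L = np.asarray(ligand, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentrations must be non-negative")
    s = L + target + kd
    disc = s * s - 4.0 * L * target
    fb = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * target)
    return float(fb) if np.isscalar(ligand) else fb


def capillary_quality_filter(
    series: TitrationSeries, max_conc: float = DEFAULT_MAX_CONC_MM
) -> tuple[TitrationSeries, dict]:
    """Drop capillaries with ligand concentration above ``max_conc`` (mM).

    Returns the filtered series and an exclusion log.  Warns when fewer than
    :data:`MIN_POINTS` points remain (the downstream fit will refuse them).
    """
    keep = [i for i, c in enumerate(series.ligand_conc) if c <= max_conc]
    removed = len(series) - len(keep)
    filtered = TitrationSeries(
        ligand_conc=tuple(series.ligand_conc[i] for i in keep),
        fnorm=tuple(series.fnorm[i] for i in keep),
        target_conc=series.target_conc,
        replicate_id=series.replicate_id,
    )
    log = {"removed": removed, "retained": len(keep), "max_conc_mM": max_conc}
    if len(keep) < MIN_POINTS:
        warnings.warn(
            f"only {len(keep)} capillaries remain after the {max_conc} mM quality "
            f"filter; Kd fitting requires >= {MIN_POINTS}",
            stacklevel=2,
        )
    return filtered, log


def _span_decades(conc) -> float:
    pos = [c for c in conc if c > 0]
    if not pos:
        return 0.0
    return float(np.log10(max(pos) / min(pos)))


def fit_kd(series: TitrationSeries) -> TitrationFit:
    """Fit (Kd, f_unbound, f_bound) to a titration series by nonlinear
    least squares on the quadratic mass-action response.

    Requires >= 8 points spanning >= 2 decades of ligand concentration.
    Binding is declared only when the fitted amplitude |f_bound - f_unbound|
    exceeds 3x the residual SD; otherwise ``binding_detected`` is False and
    Kd is reported as None.
    """
    if len(series) < MIN_POINTS:
        raise ValueError(f"need >= {MIN_POINTS} usable points, got {len(series)}")
    if _span_decades(series.ligand_conc) < 2.0:
        raise ValueError("ligand concentrations must span >= 2 decades")

    L = np.asarray(series.ligand_conc, dtype=float)
    f = np.asarray(series.fnorm, dtype=float)
    T = series.target_conc

    def residual(params):
        fb = fraction_bound_model(L, T, params["kd"].value)
        return params["f_un"].value + (params["f_b"].value - params["f_un"].value) * fb - f

    f_lo, f_hi = float(np.min(f)), float(np.max(f))
    # Kd initial guess: ligand concentration at the half response, searched
    # on the geometric grid of measured concentrations.
    mid = 0.5 * (f_lo + f_hi)
    kd0 = float(L[np.argmin(np.abs(f - mid))]) if L.max() > 0 else 1.0
    kd0 = min(max(kd0, 1e-6), 1e6)

    best = None
    for kd_start in (kd0, kd0 * 10.0, kd0 / 10.0):
        params = lmfit.Parameters()
        params.add("kd", value=kd_start, min=1e-9, max=1e9)
        # try both response orientations
        params.add("f_un", value=f[np.argmin(L)] if len(L) else f_lo)
        params.add("f_b", value=f[np.argmax(L)] if len(L) else f_hi)
        try:
            res = lmfit.minimize(
                residual, params, method="leastsq", nan_policy="raise",
                xtol=1e-14, ftol=1e-14,
            )
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res

    if best is None:
        return TitrationFit(
            kd=None, kd_se=None, f_unbound=float(np.mean(f)), f_bound=float(np.mean(f)),
            fraction_bound=tuple(np.full(len(f), np.nan)),
            converged=False, binding_detected=False,
            residual_sd=float(np.std(f, ddof=1)),
        )

    p = best.params
    kd = p["kd"].value
    f_un, f_b = p["f_un"].value, p["f_b"].value
    resid = residual(p)
    dof = max(len(f) - 3, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    amplitude = abs(f_b - f_un)
    # Amplitude actually expressed over the measured concentration range:
    # guards against degenerate fits where fb is ~constant (Kd pushed far
    # outside the titrated range) and the baseline difference is
    # unidentifiable noise.
    fb_hat = fraction_bound_model(L, T, kd)
    expressed = amplitude * float(np.max(fb_hat) - np.min(fb_hat))
    detected = bool(best.success and expressed >= DETECTION_SIGMA * residual_sd)

    if detected and amplitude > 0:
        fb = (f - f_un) / (f_b - f_un)
    else:
        fb = np.full(len(f), np.nan)

    return TitrationFit(
        kd=kd if detected else None,
        kd_se=(p["kd"].stderr if detected else None),
        f_unbound=f_un,
        f_bound=f_b,
        fraction_bound=tuple(fb),
        converged=bool(best.success),
        binding_detected=detected,
        residual_sd=residual_sd,
    )
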