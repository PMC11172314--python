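"""Two-state DSC thermogram analysis: baseline subtraction, excess heat
capacity modelling and Tm / van't Hoff enthalpy estimation.

A two-state unfolding equilibrium folded <-> unfolded with midpoint Tm and
van't Hoff enthalpy dH has equilibrium constant

    K(T) = exp((dH/R) * (1/Tm - 1/T))        (temperatures in Kelvin)

so the unfolded fraction is fu = K/(1+K) and the excess heat capacity is

    Cp_excess(T) = scale * dH^2 / (R T^2) * K / (1+K)^2

i.e. scale * dH * dfu/dT: the integral of the peak is scale*dH, its maximum
sits at Tm (to first order) and its width shrinks as dH grows.  The single
amplitude factor ``scale`` absorbs instrument normalisation, making the Tm
and dH estimates invariant to the (unstated) units of the raw signal.

Entropy and free energy follow from the two-state relations dS = dH/Tm and
dG(T) = dH - T*dS, which vanishes at Tm by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "GAS_CONSTANT_KJ",
    "Thermogram",
    "TwoStateFit",
    "two_state_excess_cp",
    "subtract_baseline",
    "fit_two_state",
    "multi_transition_fit",
]

#: Gas constant in kJ/(mol*K).
GAS_CONSTANT_KJ = 8.314462618e-3
_T0 = 273.15

#: Default half-width (degrees C) of the window excluded around the peak when
#: fitting the polynomial baseline.
DEFAULT_EXCLUDE_HALFWIDTH = 8.0
#: Peak must exceed this many off-peak noise SDs to count as a transition.
PEAK_SIGMA = 3.0


@dataclass(frozen=True)
class Thermogram:
    """A DSC scan: temperature grid (degrees C) and heat-capacity signal."""

    temperature: tuple[float, ...]
    cp: tuple[float, ...]
    scan_rate: float = 1.0       # degrees C / min
    protein_conc: float = 1.0    # mg/mL

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature)
        if len(t) != len(self.cp):
            raise ValueError("temperature and cp lengths differ")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.temperature, dtype=float)

    @property
    def signal(self) -> np.ndarray:
        return np.asarray(self.cp, dtype=float)


@dataclass(frozen=True)
class TwoStateFit:
    """Fitted two-state transition with derived thermodynamic quantities."""

    tm: float                 # degrees C
    dh: float                 # kJ/mol (van't Hoff)
    scale: float              # instrument amplitude factor
    tm_se: float | None
    dh_se: float | None
    fit_rss: float
    baseline_coeffs: tuple[float, ...] | None = None

    @property
    def ds(self) -> float:
        """Unfolding entropy dH/Tm in kJ/(mol*K)."""
        return self.dh / (self.tm + _T0)

    def dg(self, temperature_c) -> float | np.ndarray:
        """Two-state free energy dG(T) = dH - T*dS (kJ/mol); zero at Tm."""
        t_k = np.asarray(temperature_c, dtype=float) + _T0
        out = self.dh - t_k * self.ds
        return float(out) if np.ndim(temperature_c) == 0 else out


def two_state_excess_cp(temperature_c, tm: float, dh: float, scale: float = 1.0):
    """Excess heat capacity of a two-state transition (kJ/(mol*K) at scale=1).

    ``temperature_c`` and ``tm`` in degrees C; ``dh`` in kJ/mol (must be
    positive for unfolding).
    """
    if dh <= 0:
        raise ValueError("van't Hoff enthalpy must be positive for unfolding")
    t_k = np.asarray(temperature_c, dtype=float) + _T0
    tm_k = tm + _T0
    # log-space guard against overflow far from the transition
    ln_k = (dh / GAS_CONSTANT_KJ) * (1.0 / tm_k - 1.0 / t_k)
    ln_k = np.clip(ln_k, -500.0, 500.0)
    k = np.exp(ln_k)
    cp = scale * dh**2 / (GAS_CONSTANT_KJ * t_k**2) * k / (1.0 + k) ** 2
    return float(cp) if np.ndim(temperature_c) == 0 else cp


def subtract_baseline(
    tg: Thermogram,
    exclude_window: tuple[float, float] | None = None,
    degree: int = 3,
) -> tuple[Thermogram, np.ndarray]:
    """Fit a polynomial baseline outside the transition window and subtract it.

    When ``exclude_window`` is None the window defaults to the signal argmax
    +/- 8 degrees C.  Returns the corrected thermogram and the polynomial
    coefficients (numpy order, highest degree first).
    """
    t, y = tg.t, tg.signal
    if exclude_window is None:
        peak_t = t[int(np.argmax(y))]
        exclude_window = (peak_t - DEFAULT_EXCLUDE_HALFWIDTH, peak_t + DEFAULT_EXCLUDE_HALFWIDTH)
    lo, hi = exclude_window
    outside = (t < lo) | (t > hi)
    if not np.any(outside):
        raise ValueError("exclusion window covers the whole scan; no baseline points left")
    if np.count_nonzero(outside) <= degree:
        raise ValueError("too few points outside the exclusion window for the baseline degree")
    coeffs = np.polyfit(t[outside], y[outside], degree)
    corrected = y - np.polyval(coeffs, t)
    return (
        Thermogram(tuple(t), tuple(corrected), tg.scan_rate, tg.protein_conc),
        coeffs,
    )


def _require_peak(t: np.ndarray, y: np.ndarray) -> float:
    """Return the peak temperature; raise when no discernible peak exists.

    The comparison runs on a ~1-degree boxcar smoothing of the signal so
    that single noise spikes in a flat trace do not count as transitions.
    """
    dt = float(np.median(np.diff(t)))
    width = max(int(round(1.0 / dt)), 1)
    if width > 1:
        kernel = np.ones(width) / width
        y = np.convolve(y, kernel, mode="same")
    i_max = int(np.argmax(y))
    peak_t, peak_val = t[i_max], y[i_max]
    off = np.abs(t - peak_t) > DEFAULT_EXCLUDE_HALFWIDTH
    if np.count_nonzero(off) < 10:
        off = np.ones_like(t, dtype=bool)
    off_sd = float(np.std(y[off], ddof=1))
    if off_sd == 0.0:
        off_sd = 1e-12
    if peak_val < PEAK_SIGMA * off_sd:
        raise ValueError(
            f"no discernible transition: peak {peak_val:.3g} below "
            f"{PEAK_SIGMA}x off-peak SD {off_sd:.3g}"
        )
    return float(peak_t)


def _initial_dh(t: np.ndarray, y: np.ndarray, tm0: float) -> float:
    """dH guess from peak height and area: height = s*dH^2/(4RT^2), area = s*dH."""
    area = float(np.trapezoid(np.maximum(y, 0.0), t))
    height = float(np.max(y))
    if area <= 0:
        return 400.0
    dh = 4.0 * GAS_CONSTANT_KJ * (tm0 + _T0) ** 2 * height / area
    return float(np.clip(dh, 50.0, 5000.0))


def _fit_components(tg: Thermogram, k: int) -> tuple[list[TwoStateFit], lmfit.minimizer.MinimizerResult]:
    t, y = tg.t, tg.signal
    if len(t) < 50:
        raise ValueError("need >= 50 grid points to fit a thermogram")
    peak_t = _require_peak(t, y)

    # Initial Tm placement: detected local maxima, topped up with an even
    # spread across the region holding most of the peak area.
    prominence = 0.1 * float(np.max(y))
    idx, _ = find_peaks(y, prominence=prominence)
    tm_inits = sorted(t[i] for i in idx[np.argsort(y[idx])[::-1][:k]]) if len(idx) else []
    if len(tm_inits) < k:
        lo = peak_t - DEFAULT_EXCLUDE_HALFWIDTH / 2
        hi = peak_t + DEFAULT_EXCLUDE_HALFWIDTH / 2
        fill = list(np.linspace(lo, hi, k))
        tm_inits = sorted((tm_inits + fill))[:k]
    dh0 = _initial_dh(t, y, peak_t) * (k if k > 1 else 1)
    height = float(np.max(y))

    params = lmfit.Parameters()
    for i, tm_i in enumerate(tm_inits[:k]):
        cp0 = two_state_excess_cp(tm_i, tm_i, dh0, 1.0)
        params.add(f"tm{i}", value=float(tm_i), min=float(t[0]), max=float(t[-1]))
        params.add(f"dh{i}", value=dh0, min=10.0)
        params.add(f"s{i}", value=max(height / (k * cp0), 1e-12), min=0.0)

    def model(p):
        out = np.zeros_like(t)
        for i in range(k):
            out = out + two_state_excess_cp(t, p[f"tm{i}"].value, p[f"dh{i}"].value, p[f"s{i}"].value)
        return out

    res = lmfit.minimize(
        lambda p: model(p) - y, params, method="leastsq", nan_policy="raise",
        xtol=1e-14, ftol=1e-14,
    )
    if not res.success:
        raise RuntimeError(f"two-state fit did not converge ({res.message})")
    rss = float(res.chisqr)
    fits = []
    for i in range(k):
        p = res.params
        fits.append(
            TwoStateFit(
                tm=p[f"tm{i}"].value,
                dh=p[f"dh{i}"].value,
                scale=p[f"s{i}"].value,
                tm_se=p[f"tm{i}"].stderr,
                dh_se=p[f"dh{i}"].stderr,
                fit_rss=rss,
            )
        )
    fits.sort(key=lambda f: f.tm)
    return fits, res


def _aicc(rss: float, n: int, n_params: int) -> float:
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * n_params
    denom = n - n_params - 1
    return float(aic + (2 * n_params * (n_params + 1)) / denom) if denom > 0 else float("inf")


def fit_two_state(tg: Thermogram) -> TwoStateFit:
    """Fit a single two-state transition to a baseline-corrected thermogram.

    Raises when the scan shows no peak above 3x the off-peak noise SD.
    """
    fits, _ = _fit_components(tg, 1)
    return fits[0]


def multi_transition_fit(tg: Thermogram, k: int) -> tuple[list[TwoStateFit], dict]:
    """Jointly fit a sum of ``k`` two-state components (k in 1..4).

    Returns the components sorted by Tm plus a diagnostics dict with the
    AICc of the k-component model and, for k > 1, of the (k-1)-component
    alternative (``delta_aicc`` < 0 favours the k-component model).
    """
    if not 1 <= k <= 4:
        raise ValueError("k must be between 1 and 4")
    fits, res = _fit_components(tg, k)
    n = len(tg.temperature)
    diag = {"aicc": _aicc(float(res.chisqr), n, 3 * k), "k": k}
    if k > 1:
        try:
            _, res_m1 = _fit_components(tg, k - 1)
            diag["aicc_km1"] = _aicc(float(res_m1.chisqr), n, 3 * (k - 1))
            diag["delta_aicc"] = diag["aicc"] - diag["aicc_km1"]
        except (ValueError, RuntimeError):
            diag["aicc_km1"] = None
            diag["delta_aicc"] = None
    return fits, diag
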