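"""Synthetic-data generators for every instrument stream the analysis
modules consume.

Each generator draws from a single seeded numpy Generator and, at zero
noise, returns data lying exactly on the generating model, so every
analysis stage has a forward-construction oracle.  Defaults mirror the
study conditions: 16-point 1:1 serial dilutions with the labeled protein
at 0.41 uM, DSC scans from 20 to 90 degrees C on a 0.1-degree grid,
turbidity traces sampled every 30 s for 5 minutes in triplicate, and
gravimetric binodal point clouds with sub-wt% scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import ActivityTrace
from .binding import TitrationSeries, serial_dilution, fraction_bound_model, DEFAULT_TARGET_MM
from .binodal import BinodalModel, BinodalPoint, evaluate_binodal
from .dsc import Thermogram, two_state_excess_cp
from .partition import PartitionSystem

__all__ = [
    "SimulationConfig",
    "gen_binodal",
    "gen_partition",
    "gen_titration",
    "gen_thermogram",
    "gen_activity",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Seed plus per-instrument noise levels and design parameters."""

    seed: int = 0
    binodal_noise_wtpct: float = 0.5
    fnorm_noise: float = 0.02
    cp_noise: float = 0.01
    a450_noise: float = 0.005
    n_binodal_points: int = 20
    dilution_start_mM: float = 100.0
    dilution_ratio: float = 2.0
    n_dilutions: int = 16
    temp_grid: tuple[float, float, float] = (20.0, 90.0, 0.1)

    def __post_init__(self) -> None:
        for name in ("binodal_noise_wtpct", "fnorm_noise", "cp_noise", "a450_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def gen_binodal(
    model: BinodalModel,
    n: int = 20,
    noise_sd: float = 0.5,
    x_range: tuple[float, float] = (0.1, 25.0),
    rng=0,
) -> list[BinodalPoint]:
    """Cloud-point titration data: x log-uniform over ``x_range``, y on the
    curve plus Gaussian wt% noise.  Negative noisy y values truncate to 0
    (with a warning); the exponential-form fitter refuses such points.
    """
    if n < 3:
        raise ValueError("need n >= 3 binodal points")
    rng = _rng(rng)
    lo, hi = x_range
    if lo <= 0 or hi <= lo:
        raise ValueError("x_range must be positive and increasing")
    x = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    x.sort()
    y = evaluate_binodal(model, x) + rng.normal(0.0, noise_sd, size=n)
    if np.any(y < 0):
        import warnings

        warnings.warn(f"{int(np.sum(y < 0))} noisy binodal points truncated at y=0", stacklevel=2)
    y = np.maximum(y, 0.0)
    return [BinodalPoint(float(xi), float(yi)) for xi, yi in zip(x, y)]


def gen_partition(
    system: PartitionSystem,
    true_ee: float,
    total_protein_mg: float = 2.0,
    conc_noise_cv: float = 0.02,
    n_reps: int = 3,
    rng=0,
) -> list[dict]:
    """Replicate partition records (concentration per phase) for a system
    with a known true extraction efficiency.

    The protein mass splits by ``true_ee``, converts to per-phase
    concentrations through the phase volumes and picks up multiplicative
    lognormal noise of coefficient of variation ``conc_noise_cv``.
    Returns rows matching the partition CSV schema.
    """
    if not 0.0 <= true_ee <= 100.0:
        raise ValueError("true_ee must be a percentage in [0, 100]")
    rng = _rng(rng)
    m_il = total_protein_mg * true_ee / 100.0
    m_non = total_protein_mg - m_il
    v_il = system.il_rich_phase.volume
    v_non = system.non_il_rich_phase.volume
    sigma = np.sqrt(np.log1p(conc_noise_cv**2))
    rows = []
    for rep in range(1, n_reps + 1):
        for phase, m, v in (("il_rich", m_il, v_il), ("non_il_rich", m_non, v_non)):
            noise = float(rng.lognormal(-0.5 * sigma**2, sigma)) if conc_noise_cv > 0 else 1.0
            rows.append(
                {
                    "system_id": system.system_id,
                    "replicate": rep,
                    "phase": phase,
                    "conc_mg_ml": (m / v) * noise,
                    "volume_ml": v,
                }
            )
    return rows


def gen_titration(
    kd: float,
    target: float = DEFAULT_TARGET_MM,
    start: float = 100.0,
    n: int = 16,
    ratio: float = 2.0,
    f_unbound: float = 1.0,
    f_bound: float = 1.5,
    noise_sd: float = 0.02,
    no_binding: bool = False,
    replicate_id: int = 0,
    rng=0,
) -> TitrationSeries:
    """A serial-dilution MST titration from the 1:1 mass-action model.

    Concentrations in mM (``target`` defaults to 0.41 uM = 4.1e-4 mM).
    ``no_binding=True`` collapses the response amplitude to zero, emulating
    a ligand that does not interact below its aggregation threshold.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    rng = _rng(rng)
    conc = serial_dilution(start, n=n, ratio=ratio)
    if no_binding:
        fnorm = np.full(n, f_unbound)
    else:
        fb = fraction_bound_model(conc, target, kd)
        fnorm = f_unbound + (f_bound - f_unbound) * fb
    if noise_sd > 0:
        fnorm = fnorm + rng.normal(0.0, noise_sd, size=n)
    return TitrationSeries(
        ligand_conc=tuple(float(c) for c in conc),
        fnorm=tuple(float(f) for f in fnorm),
        target_conc=target,
        replicate_id=replicate_id,
    )


def gen_thermogram(
    tms,
    dhs,
    scales=None,
    baseline_coeffs=(0.0,),
    noise_sd: float = 0.0,
    temp_grid: tuple[float, float, float] = (20.0, 90.0, 0.1),
    rng=0,
) -> Thermogram:
    """A DSC scan: sum of two-state excess-Cp components on a polynomial
    baseline plus Gaussian noise, on the 20-90 degrees C grid by default.

    ``baseline_coeffs`` are numpy polynomial coefficients (highest degree
    first) evaluated on the temperature axis.
    """
    tms = list(tms)
    dhs = list(dhs)
    scales = [1.0] * len(tms) if scales is None else list(scales)
    if not (len(tms) == len(dhs) == len(scales)):
        raise ValueError("tms, dhs and scales must have equal lengths")
    lo, hi, step = temp_grid
    t = np.arange(lo, hi + 0.5 * step, step)
    for tm in tms:
        if not (t[0] <= tm <= t[-1]):
            raise ValueError(f"Tm {tm} outside the temperature grid [{t[0]}, {t[-1]}]")
    rng = _rng(rng)
    cp = np.polyval(np.asarray(baseline_coeffs, dtype=float), t)
    for tm, dh, s in zip(tms, dhs, scales):
        cp = cp + two_state_excess_cp(t, tm, dh, s)
    if noise_sd > 0:
        cp = cp + rng.normal(0.0, noise_sd, size=len(t))
    return Thermogram(tuple(float(x) for x in t), tuple(float(x) for x in cp))


def gen_activity(
    true_relative_pct: float,
    reference_slope: float = -1.0e-3,
    a450_start: float = 0.7,
    duration: float = 300.0,
    interval: float = 30.0,
    noise_sd: float = 0.005,
    n_reps: int = 3,
    condition: str = "sample",
    rng=0,
) -> list[ActivityTrace]:
    """Linear turbidity-decay traces with slope scaled to a reference.

    The sample slope is ``reference_slope * true_relative_pct / 100``; the
    reference must be an active enzyme (negative slope).
    """
    if reference_slope >= 0:
        raise ValueError("reference slope must be negative (active enzyme)")
    rng = _rng(rng)
    t = np.arange(0.0, duration + 0.5 * interval, interval)
    slope = reference_slope * true_relative_pct / 100.0
    traces = []
    for rep in range(1, n_reps + 1):
        a = a450_start + slope * t
        if noise_sd > 0:
            a = a + rng.normal(0.0, noise_sd, size=len(t))
        traces.append(
            ActivityTrace(
                time=tuple(float(x) for x in t),
                a450=tuple(float(x) for x in a),
                condition=condition,
                replicate_id=rep,
            )
        )
    return traces
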