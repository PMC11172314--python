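"""Protein partition bookkeeping: extraction efficiency, per-phase masses
and linear calibration for concentration quantification.

Extraction efficiency is always expressed relative to the IL/FIL-rich
phase:

    %EE = 100 * m_IL-rp / (m_IL-rp + m_non-IL-rp)

so the complement identity %EE(a, b) + %EE(b, a) = 100 holds exactly.
Whether the IL-rich phase is the protein-enriched one is a derived label
(%EE >= 50), never a sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev

import numpy as np
from scipy import stats

from .chemistry import TernaryComposition

__all__ = [
    "PartitionSystem",
    "PartitionResult",
    "extraction_efficiency",
    "mass_from_concentration",
    "aggregate_replicates",
    "LinearCalibration",
    "linear_calibration",
]


@dataclass(frozen=True)
class Phase:
    composition: TernaryComposition
    ph: float
    volume: float  # mL

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("phase volume must be positive")


@dataclass(frozen=True)
class PartitionSystem:
    """A characterised biphasic point: two phases plus their volume ratio."""

    system_id: str
    il_rich_phase: Phase
    non_il_rich_phase: Phase

    @property
    def volume_ratio(self) -> float:
        """V(IL-rich) / V(non-IL-rich)."""
        return self.il_rich_phase.volume / self.non_il_rich_phase.volume


@dataclass(frozen=True)
class PartitionResult:
    m_il_rp: float   # mg protein in the IL/FIL-rich phase
    m_non_rp: float  # mg protein in the non-IL-rich phase
    ee_pct: float
    replicate_sd: float | None = None

    @property
    def il_rich_enriched(self) -> bool:
        return self.ee_pct >= 50.0


def extraction_efficiency(m_il_rp: float, m_non_rp: float) -> float:
    """%EE = 100 * m_il_rp / (m_il_rp + m_non_rp).

    Raises on negative masses or when both masses are zero.
    """
    if m_il_rp < 0 or m_non_rp < 0:
        raise ValueError("protein masses must be non-negative")
    total = m_il_rp + m_non_rp
    if total == 0:
        raise ValueError("both phase masses are zero; %EE undefined")
    # evaluate the smaller share directly so the complement identity
    # ee(a, b) + ee(b, a) == 100 holds exactly in floating point
    if m_il_rp <= m_non_rp:
        return 100.0 * m_il_rp / total
    return 100.0 - 100.0 * m_non_rp / total


def mass_from_concentration(conc_mg_ml: float, volume_ml: float) -> float:
    """Protein mass (mg) from concentration (mg/mL) and phase volume (mL)."""
    if conc_mg_ml < 0 or volume_ml < 0:
        raise ValueError("concentration and volume must be non-negative")
    return conc_mg_ml * volume_ml


def aggregate_replicates(replicate_ee: list[float]) -> PartitionResult | dict:
    """Mean and SD of replicate-level %EE values.

    The SD is over per-replicate %EE (replicate experiments), not propagated
    per-phase; it is reported only for >= 2 replicates (None otherwise).
    """
    if len(replicate_ee) < 1:
        raise ValueError("need at least one replicate")
    m = mean(replicate_ee)
    sd = stdev(replicate_ee) if len(replicate_ee) >= 2 else None
    return {"ee_mean": m, "ee_sd": sd, "n": len(replicate_ee)}


@dataclass(frozen=True)
class LinearCalibration:
    """OLS calibration line absorbance = slope*conc + intercept."""

    slope: float
    intercept: float
    r_squared: float
    conc_min: float
    conc_max: float

    def predict_concentration(self, absorbance: float, extrapolation_frac: float = 0.10) -> float:
        """Inverse prediction conc = (A - intercept)/slope.

        Refuses absorbances mapping more than ``extrapolation_frac`` of the
        calibrated concentration range outside it.
        """
        conc = (absorbance - self.intercept) / self.slope
        span = self.conc_max - self.conc_min
        margin = extrapolation_frac * span
        if conc < self.conc_min - margin or conc > self.conc_max + margin:
            raise ValueError(
                f"predicted concentration {conc:.4g} outside calibrated range "
                f"[{self.conc_min}, {self.conc_max}] by more than {extrapolation_frac:.0%}"
            )
        return conc


def linear_calibration(standards) -> LinearCalibration:
    """Fit an OLS line to (concentration, absorbance) standards.

    Requires >= 2 standards with distinct concentrations.
    """
    conc = np.array([s[0] for s in standards], dtype=float)
    absorbance = np.array([s[1] for s in standards], dtype=float)
    if len(conc) < 2 or len(np.unique(conc)) < 2:
        raise ValueError("need >= 2 standards with distinct concentrations")
    res = stats.linregress(conc, absorbance)
    if res.slope == 0:
        raise ValueError("calibration slope is zero; inverse prediction undefined")
    return LinearCalibration(
        slope=res.slope,
        intercept=res.intercept,
        r_squared=res.rvalue**2,
        conc_min=float(conc.min()),
        conc_max=float(conc.max()),
    )
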