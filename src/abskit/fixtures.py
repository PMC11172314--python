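"""Packaged reference tables from the fluorinated-IL ABS protein study.

Three small datasets ship with the package, verbatim to the printed digits:
the phase properties of the twelve biphasic points (volume ratio, pH and
wt% composition of both phases), the MST dissociation constants of
FITC-lysozyme with the four phase-forming ligands, and the printed melting
temperatures of lysozyme in water and in selected ABS phases.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_phase_properties", "load_kd_table", "load_tm_values"]


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("abskit").joinpath("data", name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, **kwargs)


def load_phase_properties() -> pd.DataFrame:
    """Phase properties of biphasic points BP#1-BP#12.

    Columns: system_id, abs_composition, volume_ratio (V_IL-rich /
    V_non-IL-rich), then pH / wt% water / wt% IL / wt% non-IL for the
    IL-rich (bottom) and non-IL-rich (top) phases.
    """
    return _read("table1_phase_properties.csv")


def load_kd_table() -> pd.DataFrame:
    """FITC-lysozyme dissociation constants per ligand and concentration range.

    ``kd_mM`` is NaN for ranges where no binding was detected (monomer
    regimes of all four ligands).
    """
    return _read("table2_kd.csv")


def load_tm_values() -> pd.DataFrame:
    """Printed lysozyme melting temperatures (degrees C) with uncertainties."""
    return _read("tm_values.csv")
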