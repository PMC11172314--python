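"""Phase-forming components and ternary-composition coordinate conversions.

An aqueous biphasic system (ABS) mixture point is specified by the weight
percentages of an ionic-liquid component, a second phase former (salt,
carbohydrate or a second IL) and water.  Phase diagrams are often replotted
with solute molality on the axes, so this module also provides the
wt% <-> molality conversion.  Molality is defined on kilograms of *water*
only, the usual convention for water-rich ABS phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import yaml

__all__ = [
    "Component",
    "ComponentRegistry",
    "TernaryComposition",
    "default_registry",
    "validate_composition",
    "wtpct_to_molality",
    "molality_to_wtpct",
]

#: Roles a phase-forming species can play in these systems.
COMPONENT_ROLES = frozenset(
    {
        "fluorinated_IL",
        "fluoro_containing_IL",
        "conventional_IL",
        "inorganic_salt",
        "carbohydrate",
        "stabilizer",
        "water",
        "protein",
    }
)

#: Composition sums may deviate from 100 wt% by this much (gravimetric
#: rounding of measured phases) before the point is rejected.
SUM_TOLERANCE_WTPCT = 0.5


@dataclass(frozen=True)
class Component:
    """A phase-forming chemical species.

    Parameters
    ----------
    name:
        Identifier, e.g. the bracketed IL shorthand ``[C2C1Im][C4F9SO3]``.
    molar_mass:
        Molar mass in g/mol; must be positive.
    role:
        One of :data:`COMPONENT_ROLES`.
    """

    name: str
    molar_mass: float
    role: str

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be > 0, got {self.molar_mass}")
        if self.role not in COMPONENT_ROLES:
            raise ValueError(f"unknown role {self.role!r}")


class ComponentRegistry:
    """Name-keyed collection of :class:`Component` records."""

    def __init__(self, components: Iterable[Component] = ()) -> None:
        self._by_name: dict[str, Component] = {}
        for comp in components:
            self.add(comp)

    def add(self, comp: Component) -> None:
        if comp.name in self._by_name:
            raise ValueError(f"component {comp.name!r} already registered")
        self._by_name[comp.name] = comp

    def __getitem__(self, name: str) -> Component:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(
                f"component {name!r} not in registry; known: {sorted(self._by_name)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self):
        return iter(self._by_name.values())

    @classmethod
    def from_yaml(cls, path_or_stream) -> "ComponentRegistry":
        """Load a registry from a YAML list of {name, molar_mass_g_mol, role}."""
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream, "r", encoding="utf-8") as fh:
                raw = yaml.safe_load(fh)
        comps = [
            Component(
                name=entry["name"],
                molar_mass=float(entry["molar_mass_g_mol"]),
                role=entry["role"],
            )
            for entry in raw
        ]
        return cls(comps)


def default_registry() -> ComponentRegistry:
    """Registry of the phase formers used in the fluorinated-IL ABS study.

    Molar masses are taken from standard reference data for each salt or
    carbohydrate; the source study does not tabulate them.
    """
    ref = resources.files("abskit").joinpath("data", "components.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return ComponentRegistry.from_yaml(fh)


@dataclass(frozen=True)
class TernaryComposition:
    """One composition point of an (IL, non-IL, water) ternary system in wt%.

    The three fractions must each lie in [0, 100] and sum to 100 within
    1e-6.  Use :func:`validate_composition` to build one from raw,
    possibly unnormalised, gravimetric numbers.
    """

    w_il: float
    w_non: float
    w_water: float
    #: Deviation of the raw (pre-normalisation) sum from 100 wt%, kept as a
    #: closure diagnostic for measured phase compositions.
    closure_deviation: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        for label, w in (("w_il", self.w_il), ("w_non", self.w_non), ("w_water", self.w_water)):
            if not 0.0 <= w <= 100.0:
                raise ValueError(f"{label}={w} outside [0, 100]")
        total = self.w_il + self.w_non + self.w_water
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"composition sums to {total}, not 100 (use validate_composition)")


def validate_composition(w_il: float, w_non: float, w_water: float) -> TernaryComposition:
    """Build a :class:`TernaryComposition` from raw gravimetric wt% values.

    Sums within ``SUM_TOLERANCE_WTPCT`` (0.5 wt%) of 100 are renormalised to
    exactly 100, recording the deviation; larger deviations raise.
    """
    for label, w in (("w_il", w_il), ("w_non", w_non), ("w_water", w_water)):
        if w < 0:
            raise ValueError(f"{label}={w} is negative")
    total = w_il + w_non + w_water
    deviation = total - 100.0
    if abs(deviation) > SUM_TOLERANCE_WTPCT:
        raise ValueError(
            f"composition sum {total:.4f} deviates from 100 by more than "
            f"{SUM_TOLERANCE_WTPCT} wt%"
        )
    scale = 100.0 / total
    return TernaryComposition(
        w_il=w_il * scale,
        w_non=w_non * scale,
        w_water=w_water * scale,
        closure_deviation=deviation,
    )


def wtpct_to_molality(
    comp: TernaryComposition, il: Component, non_il: Component
) -> tuple[float, float]:
    """Convert a ternary composition to (IL, non-IL) molalities.

    Molality is mol of solute per kg of water: ``b_i = (w_i / M_i) / (w_water / 1000)``
    with w in wt% and M in g/mol.

    Raises
    ------
    ValueError
        If the composition contains no water (molality undefined).
    """
    if comp.w_water <= 0:
        raise ValueError("molality undefined at zero water content")
    kg_water_per_100g = comp.w_water / 1000.0
    b_il = (comp.w_il / il.molar_mass) / kg_water_per_100g
    b_non = (comp.w_non / non_il.molar_mass) / kg_water_per_100g
    return b_il, b_non


def molality_to_wtpct(
    b_il: float, b_non: float, il: Component, non_il: Component
) -> TernaryComposition:
    """Inverse of :func:`wtpct_to_molality`.

    Per kg of water the solute masses are ``b_i * M_i`` grams, so the weight
    fractions follow from the total mass ``1000 + b_il*M_il + b_non*M_non``.
    """
    if b_il < 0 or b_non < 0:
        raise ValueError("molalities must be non-negative")
    g_il = b_il * il.molar_mass
    g_non = b_non * non_il.molar_mass
    total = 1000.0 + g_il + g_non
    return TernaryComposition(
        w_il=100.0 * g_il / total,
        w_non=100.0 * g_non / total,
        w_water=100.0 * 1000.0 / total,
    )
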