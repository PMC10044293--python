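"""Extender component definitions.

A cryopreservation extender is assembled from 12 ingredients whose
concentrations are varied over fixed physical ranges: the aqueous base
(water, tris buffer), extracellular protectants (egg yolk, milk), sugars
and osmoregulators (fructose, trehalose), a membrane stabilizer
(cholesterol-loaded cyclodextrin, CLC), antioxidants (glutathione,
melatonin, nerve growth factor), and permeating cryoprotectants
(glycerol, ethylene glycol).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ComponentSpec:
    """One extender ingredient with its physical concentration range.

    Parameters
    ----------
    name : str
        Identifier used as a column name in experiment tables.
    unit : str
        Physical unit of the concentration ("mL", "mg", "uL" or "ng").
    low, high : float
        Lower and upper bounds of the range screened, in `unit`.
    """

    name: str
    unit: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.high):
            raise ValueError(f"{self.name}: low must be < high")
        if self.low < 0:
            raise ValueError(f"{self.name}: bounds must be non-negative")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def range(self) -> float:
        return self.high - self.low


#: Canonical component order used everywhere (tables, design matrices,
#: coefficient vectors).
COMPONENT_ORDER = (
    "water",
    "tris",
    "egg_yolk",
    "milk",
    "fructose",
    "trehalose",
    "clc",
    "glutathione",
    "melatonin",
    "ngf",
    "glycerol",
    "ethylene_glycol",
)

_DEFAULT_SPECS = (
    ComponentSpec("water", "mL", 0.0, 4.0),
    ComponentSpec("tris", "mL", 3.0, 8.0),
    ComponentSpec("egg_yolk", "mL", 1.0, 2.0),
    ComponentSpec("milk", "mL", 0.0, 0.4),
    ComponentSpec("fructose", "mg", 0.0, 125.0),
    ComponentSpec("trehalose", "mg", 0.0, 165.0),
    ComponentSpec("clc", "mg", 2.0, 10.0),
    ComponentSpec("glutathione", "uL", 0.0, 10.0),
    ComponentSpec("melatonin", "uL", 5.0, 12.0),
    ComponentSpec("ngf", "ng", 0.0, 500.0),
    ComponentSpec("glycerol", "mL", 0.0, 0.75),
    ComponentSpec("ethylene_glycol", "mL", 0.0, 0.85),
)


def default_component_specs() -> list[ComponentSpec]:
    """Return the 12 screened components with their concentration ranges.

    Order is fixed (:data:`COMPONENT_ORDER`) and names are unique.
    """
    return list(_DEFAULT_SPECS)
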