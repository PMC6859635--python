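"""Media factor definitions shared across the package.

Six MS-medium components are varied: KNO3, NH4NO3, the mesos salt group
(CaCl2, KH2PO4, MgSO4), the minors group (micronutrients + chelated iron) --
all as multiples of their 1x MS concentration -- plus the hormones BAP
(6-benzylaminopurine, cytokinin) and IBA (indole-3-butyric acid, auxin) in
mg/l.  Expression terminals use the single-letter symbols A..F in this
column order (the order of the experimental data tables).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np

#: factor column names, in canonical order
FACTOR_NAMES: tuple[str, ...] = ("KNO3", "NH4NO3", "mesos", "minors", "BAP", "IBA")

#: expression-tree terminal symbols, aligned with FACTOR_NAMES
FACTOR_SYMBOLS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")

SYMBOL_TO_NAME: dict[str, str] = dict(zip(FACTOR_SYMBOLS, FACTOR_NAMES))
NAME_TO_SYMBOL: dict[str, str] = dict(zip(FACTOR_NAMES, FACTOR_SYMBOLS))

#: experimental ranges of each factor (the optimization box)
FACTOR_BOUNDS: dict[str, tuple[float, float]] = {
    "KNO3": (0.5, 2.0),
    "NH4NO3": (0.5, 2.0),
    "mesos": (0.5, 2.5),
    "minors": (0.5, 4.0),
    "BAP": (0.5, 3.0),
    "IBA": (0.05, 0.2),
}

RESPONSE_NAMES: tuple[str, ...] = ("PR", "SL", "STN", "Vitri", "QI")

#: physically meaningful bounds of each growth response
RESPONSE_BOUNDS: dict[str, tuple[float, float]] = {
    "PR": (0.0, np.inf),
    "SL": (0.0, np.inf),
    "STN": (0.0, 100.0),
    "Vitri": (0.0, 100.0),
    "QI": (1.0, 5.0),
}

ROOTSTOCKS: tuple[str, ...] = ("Pyrodwarf", "OHF")


def canonical_rootstock(name: str) -> str:
    """Resolve a rootstock name case-insensitively, raising on unknown names."""
    for rs in ROOTSTOCKS:
        if name.lower() == rs.lower():
            return rs
    raise KeyError(f"unknown rootstock {name!r}; valid: {list(ROOTSTOCKS)}")


class FactorVector(NamedTuple):
    """One media composition: six factor levels in canonical order."""

    KNO3: float
    NH4NO3: float
    mesos: float
    minors: float
    BAP: float
    IBA: float

    def as_symbols(self) -> dict[str, float]:
        """Map to the expression-terminal symbols A..F."""
        return dict(zip(FACTOR_SYMBOLS, self))

    def in_range(self) -> bool:
        """Whether every level lies inside its experimental range."""
        return all(
            FACTOR_BOUNDS[n][0] <= v <= FACTOR_BOUNDS[n][1]
            for n, v in zip(FACTOR_NAMES, self)
        )

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "FactorVector":
        """Build from a mapping keyed by factor names or by symbols A..F."""
        if all(s in m for s in FACTOR_SYMBOLS):
            return cls(*(float(m[s]) for s in FACTOR_SYMBOLS))
        return cls(*(float(m[n]) for n in FACTOR_NAMES))


def check_factor_vector(x: Iterable[float], warn_out_of_range: bool = True) -> FactorVector:
    """Validate a factor vector: finite everywhere; warn (not reject) off-range."""
    fv = FactorVector(*(float(v) for v in x))
    if not all(np.isfinite(fv)):
        raise ValueError(f"non-finite factor level in {fv}")
    if warn_out_of_range and not fv.in_range():
        warnings.warn(f"factor vector {fv} outside experimental ranges", stacklevel=2)
    return fv


@dataclass(frozen=True)
class FactorSpec:
    """One factor's three design levels (coded -1 / 0 / +1)."""

    name: str
    low: float
    mid: float
    high: float
    units: str = "x MS"

    def __post_init__(self) -> None:
        if not (self.low < self.mid < self.high):
            raise ValueError(f"levels of {self.name} must satisfy low < mid < high")

    @property
    def levels(self) -> tuple[float, float, float]:
        return (self.low, self.mid, self.high)


#: three-level design specification of the six factors.  The IBA mid level is
#: the true midpoint 0.125 (printed tables round it to 0.13).
DESIGN_SPECS: tuple[FactorSpec, ...] = (
    FactorSpec("KNO3", 0.5, 1.25, 2.0),
    FactorSpec("NH4NO3", 0.5, 1.25, 2.0),
    FactorSpec("mesos", 0.5, 1.5, 2.5),
    FactorSpec("minors", 0.5, 2.25, 4.0),
    FactorSpec("BAP", 0.5, 1.75, 3.0, units="mg/l"),
    FactorSpec("IBA", 0.05, 0.125, 0.2, units="mg/l"),
)
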