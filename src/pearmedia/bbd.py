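"""Box–Behnken designs: generation, coding, and the literal experimental design.

A Box–Behnken design (BBD) varies subsets of factors at their low/high
levels (+-1 coded) while holding the rest at the mid level (0).  The
experimental design used here is the 6-factor, 3-level, 48-run edge-run BBD
(six blocks of three factors, each crossed over all eight sign
combinations, no center runs).  The literal printed design ships as a
packaged fixture and is the default anchor for analyses; a generator for
arbitrary k >= 3 is also provided.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations, product
from typing import Sequence

import numpy as np
import pandas as pd

from .factors import DESIGN_SPECS, FACTOR_NAMES, FactorSpec, FactorVector

#: cyclic three-factor blocks of the classical 6-factor BBD: (i, i+1, i+3) mod 6
_BLOCKS_6 = tuple(tuple(sorted((i % 6, (i + 1) % 6, (i + 3) % 6))) for i in range(6))

#: tolerance for matching printed (rounded) actual levels to design levels
LEVEL_MATCH_TOL = 0.01


@dataclass(frozen=True)
class DesignMatrix:
    """Coded BBD runs plus the factor specifications mapping codes to levels."""

    runs: np.ndarray  # (n_runs, k) with entries in {-1, 0, +1}
    factor_specs: tuple[FactorSpec, ...] = field(default=DESIGN_SPECS)

    def __post_init__(self) -> None:
        runs = np.asarray(self.runs, dtype=float)
        if not np.isin(runs, (-1.0, 0.0, 1.0)).all():
            raise ValueError("coded design entries must be in {-1, 0, +1}")
        if runs.shape[1] != len(self.factor_specs):
            raise ValueError("run width does not match number of factor specs")
        object.__setattr__(self, "runs", runs)

    def __len__(self) -> int:
        return len(self.runs)

    def to_actual(self) -> pd.DataFrame:
        """Actual factor levels of every run, as a DataFrame."""
        rows = [code_to_actual(run, self.factor_specs) for run in self.runs]
        return pd.DataFrame(rows, columns=[s.name for s in self.factor_specs])


def bbd_generate(k: int, n_center: int = 0,
                 factor_specs: Sequence[FactorSpec] | None = None) -> DesignMatrix:
    """Generate a k-factor Box–Behnken edge-run design.

    For k = 6 the classical six cyclic three-factor blocks are used, giving
    exactly 48 runs; otherwise all factor pairs are crossed at +-1 (the
    standard two-factor-block BBD).  Runs are deduplicated and ordered
    lexicographically by block then signs; ``n_center`` all-mid runs are
    appended (the experimental design has none).
    """
    if k < 3:
        raise ValueError("a Box–Behnken design needs at least 3 factors")
    blocks = _BLOCKS_6 if k == 6 else list(combinations(range(k), 2))
    seen, runs = set(), []
    for block in sorted(blocks):
        for signs in product((-1.0, 1.0), repeat=len(block)):
            run = np.zeros(k)
            run[list(block)] = signs
            key = tuple(run)
            if key not in seen:
                seen.add(key)
                runs.append(run)
    runs.extend(np.zeros(k) for _ in range(n_center))
    if factor_specs is None:
        factor_specs = DESIGN_SPECS if k == 6 else tuple(
            FactorSpec(f"x{i + 1}", -1.0, 0.0, 1.0, units="coded") for i in range(k)
        )
    return DesignMatrix(np.array(runs), tuple(factor_specs))


def code_to_actual(coded: Sequence[float],
                   specs: Sequence[FactorSpec] = DESIGN_SPECS) -> FactorVector | tuple:
    """Map a coded run (-1/0/+1 entries) to actual factor levels."""
    coded = np.asarray(coded, dtype=float)
    if not np.isin(coded, (-1.0, 0.0, 1.0)).all():
        raise ValueError(f"coded entries must be in {{-1, 0, +1}}, got {coded}")
    levels = tuple(
        spec.levels[int(c) + 1] for c, spec in zip(coded, specs, strict=True)
    )
    if tuple(s.name for s in specs) == FACTOR_NAMES:
        return FactorVector(*levels)
    return levels


def actual_to_code(actual: Sequence[float],
                   specs: Sequence[FactorSpec] = DESIGN_SPECS,
                   tol: float = LEVEL_MATCH_TOL) -> np.ndarray:
    """Map actual levels back to codes by nearest design level within ``tol``."""
    out = np.empty(len(specs))
    for i, (v, spec) in enumerate(zip(actual, specs, strict=True)):
        diffs = [abs(float(v) - lv) for lv in spec.levels]
        j = int(np.argmin(diffs))
        if diffs[j] > tol:
            raise ValueError(
                f"{spec.name}={v} does not match any design level {spec.levels} "
                f"within {tol}"
            )
        out[i] = j - 1
    return out


def load_paper_design() -> pd.DataFrame:
    """The 48 experimental runs in printed order (actual levels, both rootstocks)."""
    ref = resources.files("pearmedia.data").joinpath("bbd_design.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh)
    if list(df.columns) != ["medium_id", *FACTOR_NAMES] or len(df) != 48:
        raise IOError("packaged design fixture is corrupt")
    return df


def design_to_csv(design: DesignMatrix, path, coded: bool = False) -> None:
    """Export a design as CSV; a metadata column records the representation."""
    df = pd.DataFrame(design.runs, columns=[s.name for s in design.factor_specs]) \
        if coded else design.to_actual()
    df.insert(0, "representation", "coded" if coded else "actual")
    df.to_csv(path, index=False)
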