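"""Packaged experimental datasets and the replicate-level train/test split.

Each rootstock's dataset holds 51 media: the 48 Box–Behnken runs plus three
control media (MS, WPM, QL at 1x MS factor levels with BAP 2.50, IBA 0.20),
with the per-medium mean of each growth response.  Fixture integrity is
verified against stored sha256 digests on every load.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .factors import (
    FACTOR_NAMES,
    FactorVector,
    RESPONSE_NAMES,
    canonical_rootstock,
)

_FIXTURES = {"Pyrodwarf": "pyrodwarf_responses.csv", "OHF": "ohf_responses.csv"}

CONTROL_MEDIA = ("MS", "WPM", "QL")

COLUMNS = ["medium_id", *FACTOR_NAMES, *RESPONSE_NAMES]


@dataclass(frozen=True)
class MediaRecord:
    """One medium: its factor levels and five measured response means."""

    medium_id: str
    factors: FactorVector
    PR: float
    SL: float
    STN: float
    Vitri: float
    QI: float

    @classmethod
    def from_row(cls, row: pd.Series) -> "MediaRecord":
        return cls(
            medium_id=str(row["medium_id"]),
            factors=FactorVector(*(float(row[n]) for n in FACTOR_NAMES)),
            **{r: float(row[r]) for r in RESPONSE_NAMES},
        )


def _read_fixture(filename: str) -> pd.DataFrame:
    pkg = resources.files("pearmedia.data")
    raw = pkg.joinpath(filename).read_bytes()
    digests = json.loads(pkg.joinpath("checksums.json").read_text())
    actual = hashlib.sha256(raw).hexdigest()
    if actual != digests[filename]:
        raise IOError(
            f"fixture {filename} failed its integrity check "
            f"(sha256 {actual} != {digests[filename]})"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), dtype={"medium_id": str})


def load_dataset(rootstock: str) -> pd.DataFrame:
    """All 51 media of one rootstock, in printed order, values as printed."""
    rs = canonical_rootstock(rootstock)
    df = _read_fixture(_FIXTURES[rs])
    if list(df.columns) != COLUMNS or len(df) != 51:
        raise IOError(f"fixture for {rs} has unexpected shape")
    _validate_responses(df)
    return df


def load_records(rootstock: str) -> list[MediaRecord]:
    return [MediaRecord.from_row(row) for _, row in load_dataset(rootstock).iterrows()]


def _validate_responses(df: pd.DataFrame) -> None:
    checks = {
        "PR": (0, np.inf),
        "SL": (0, np.inf),
        "STN": (0, 100),
        "Vitri": (0, 100),
        "QI": (1, 5),
    }
    for col, (lo, hi) in checks.items():
        v = df[col].to_numpy(float)
        if np.isnan(v).any() or (v < lo).any() or (v > hi).any():
            raise ValueError(f"response {col} outside [{lo}, {hi}] in fixture")


@dataclass(frozen=True)
class SplitResult:
    """A reproducible train/test partition of observation records."""

    train: pd.DataFrame
    test: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train.index) & set(self.test.index)
        if overlap:
            raise ValueError("train/test overlap")


def split_train_test(records: pd.DataFrame, train_fraction: float = 0.7,
                     seed: int = 0) -> SplitResult:
    """Uniform random split without replacement, sizes round(N*f) / N - that.

    Operates on whatever record table is supplied — the 51 printed means or
    replicate-level data (e.g. 510 synthetic records, split 357/153 at 70%).
    """
    if len(records) == 0:
        raise ValueError("cannot split an empty record table")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(records)
    n_train = int(np.floor(n * train_fraction + 0.5))  # round half up
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return SplitResult(
        train=records.iloc[train_idx],
        test=records.iloc[test_idx],
        seed=seed,
    )
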