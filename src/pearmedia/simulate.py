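"""Replicate-level synthetic observations over smooth response surfaces.

The experimental protocol measured each medium in 10 replicate jars, but
only per-medium means are printed; model fitting, however, operated on the
replicate-level records (510 per rootstock).  This module emulates that
structure: a :class:`SurfaceSpec` holds a smooth bounded ground-truth
surface per response, per-response Gaussian noise, and a replicate count;
:func:`generate_replicates` draws reproducible replicate observations from
it.  :func:`spec_from_published` uses the published media equations as the
ground truth, which gives downstream fitting/evaluation stages data with
the statistical shape the analysis assumes — not a mechanistic simulation
of explant biology.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .datasets import load_dataset
from .factors import (
    FACTOR_NAMES,
    NAME_TO_SYMBOL,
    RESPONSE_BOUNDS,
    RESPONSE_NAMES,
    canonical_rootstock,
)
from .published import predict

#: fraction of each response's observed range used as the default noise SD
DEFAULT_NOISE_FRACTION = 0.1


@dataclass(frozen=True)
class SurfaceSpec:
    """Ground truth + noise model defining a synthetic experiment."""

    ground_truth: Mapping[str, Callable]  # response -> f(env of factor arrays)
    noise_sd: Mapping[str, float]
    replicates: int = 10
    response_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(RESPONSE_BOUNDS)
    )

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for r, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"negative noise SD for {r}")
        for r, (lo, hi) in self.response_bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds of {r} must be ordered")


def default_noise_sd(rootstock: str,
                     fraction: float = DEFAULT_NOISE_FRACTION) -> dict[str, float]:
    """Per-response noise SD as a fraction of the printed response range."""
    df = load_dataset(rootstock)
    return {
        r: fraction * float(df[r].max() - df[r].min()) for r in RESPONSE_NAMES
    }


def spec_from_published(rootstock: str,
                        noise_sd: float | Mapping[str, float] | None = None,
                        replicates: int = 10) -> SurfaceSpec:
    """Surface spec whose ground truth is the five published media models.

    ``noise_sd`` may be a single SD applied to every response, a per-response
    mapping, or None for the default (10% of each response's printed range).
    """
    rs = canonical_rootstock(rootstock)
    if noise_sd is None:
        sd = default_noise_sd(rs)
    elif isinstance(noise_sd, Mapping):
        sd = {r: float(noise_sd[r]) for r in RESPONSE_NAMES}
    else:
        sd = {r: float(noise_sd) for r in RESPONSE_NAMES}

    def make_truth(resp: str) -> Callable:
        def f(env):
            return predict(rs, resp, env)

        return f

    return SurfaceSpec(
        ground_truth={r: make_truth(r) for r in RESPONSE_NAMES},
        noise_sd=sd,
        replicates=replicates,
    )


def generate_replicates(design: pd.DataFrame, spec: SurfaceSpec,
                        seed: int = 0) -> pd.DataFrame:
    """Draw ``len(design) * spec.replicates`` noisy observations.

    ``design`` needs the six factor columns (a ``medium_id`` column is kept
    if present).  Each response is ``clip(truth + N(0, sd), lo, hi)``; PR is
    additionally rounded to quarter-shoot resolution, mimicking the
    averaging of shoot counts over four explants per jar.
    """
    if len(design) == 0:
        raise ValueError("design must be non-empty")
    rng = np.random.default_rng(seed)
    reps = spec.replicates
    base = design.loc[design.index.repeat(reps)].reset_index(drop=True)
    out = pd.DataFrame()
    if "medium_id" in base:
        out["medium_id"] = base["medium_id"].astype(str)
    for name in FACTOR_NAMES:
        out[name] = base[name].to_numpy(float)
    out["replicate_id"] = np.tile(np.arange(1, reps + 1), len(design))
    env = {NAME_TO_SYMBOL[n]: out[n].to_numpy(float) for n in FACTOR_NAMES}
    for resp, truth in spec.ground_truth.items():
        mu = np.asarray(truth(env), dtype=float)
        sd = spec.noise_sd.get(resp, 0.0)
        vals = mu if sd == 0 else mu + rng.normal(0.0, sd, size=len(out))
        lo, hi = spec.response_bounds.get(resp, (-np.inf, np.inf))
        vals = np.clip(vals, lo, hi)
        if resp == "PR" and sd > 0:
            # quarter-shoot resolution from averaging counts over 4 explants;
            # skipped at zero noise so the generator is exactly the identity
            vals = np.round(vals * 4.0) / 4.0
        out[resp] = vals
    return out
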