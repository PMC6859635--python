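"""Model-comparison error statistics.

Four indices are reported for each model/response pair:

* RMSE  = sqrt(mean((O - P)^2))
* MARE  = mean(|O - P| / |O|) over observations with O != 0 (terms with a
  zero observation are undefined and are excluded but counted)
* MBE   = mean(O - P)  (positive = model under-predicts)
* r     = Pearson correlation of O and P; r^2 is also reported, since the
  source literature's "R^2" formula is an unsquared correlation while its
  printed values are consistent with the square.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class MetricsReport:
    rmse: float
    mare: float
    mbe: float
    r: float
    r_squared: float
    n: int
    n_excluded_mare: int

    def as_dict(self) -> dict[str, float]:
        return {
            "rmse": self.rmse,
            "mare": self.mare,
            "mbe": self.mbe,
            "r": self.r,
            "r_squared": self.r_squared,
            "n": self.n,
            "n_excluded_mare": self.n_excluded_mare,
        }


def compute_metrics(observed, predicted) -> MetricsReport:
    """Compute the four indices; r is NaN when either series is constant."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    n = len(o)
    if n < 2:
        raise ValueError("need at least 2 observations")
    err = o - p
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mbe = float(np.mean(err))
    nonzero = o != 0
    n_excl = int(n - nonzero.sum())
    if nonzero.any():
        mare = float(np.mean(np.abs(err[nonzero] / o[nonzero])))
    else:
        mare = math.nan
    # relative guard: identical values can yield std ~1e-17 from rounding
    so, sp = np.std(o), np.std(p)
    if so <= 1e-12 * (1 + abs(o.mean())) or sp <= 1e-12 * (1 + abs(p.mean())):
        r = math.nan
    else:
        r = float(np.corrcoef(o, p)[0, 1])
    return MetricsReport(
        rmse=rmse, mare=mare, mbe=mbe, r=r,
        r_squared=(r * r if not math.isnan(r) else math.nan),
        n=n, n_excluded_mare=n_excl,
    )
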