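"""Median-effect dose-response fitting and Chou-Talalay combination index.

The median-effect model fa/(1 - fa) = (D/Dm)^m is fit as a straight line in
log-log space; Dm (the dose at fa = 0.5) doubles as the IC50 estimate. For a
drug pair, the combination index at an observed combination point is
CI = d1/Dx1 + d2/Dx2 with Dx_i the single-agent dose achieving the same
fraction affected: CI = 1 additive, < 1 synergistic, > 1 antagonistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "MedianEffectFit",
    "median_effect_fit",
    "ic50",
    "combination_index",
]


@dataclass(frozen=True)
class MedianEffectFit:
    m: float  # Hill-type slope (dimensionless)
    dm: float  # median-effect dose, µM
    r2: float  # fit quality of the log-log line
    n_points: int

    def fa(self, dose) -> np.ndarray:
        """Predicted fraction affected at the given dose(s)."""
        dose = np.asarray(dose, dtype=float)
        return 1.0 / (1.0 + (self.dm / dose) ** self.m)

    def dx(self, fa) -> np.ndarray:
        """Single-agent dose achieving the given fraction(s) affected."""
        fa = np.asarray(fa, dtype=float)
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


def median_effect_fit(doses: Sequence[float], fa: Sequence[float],
                      ) -> MedianEffectFit:
    """Least-squares median-effect fit on log10(fa/(1-fa)) vs log10(D).

    Points with fa at 0 or 1 carry no information on the log-odds scale and
    are excluded with a warning; at least two interior points are required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.size != fa.size:
        raise InvalidParameterError("doses and fa must have equal length")
    if np.any(doses <= 0):
        raise InvalidParameterError("doses must be positive")
    interior = (fa > 0.0) & (fa < 1.0)
    if not interior.all():
        warnings.warn(f"excluding {int((~interior).sum())} point(s) with fa "
                      "at 0 or 1 from the median-effect fit")
    doses, fa = doses[interior], fa[interior]
    if doses.size < 2:
        raise InvalidParameterError("need >= 2 points with 0 < fa < 1")
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    if np.ptp(x) == 0:
        raise InvalidParameterError("need >= 2 distinct doses")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    dm = 10.0 ** (-intercept / slope)
    return MedianEffectFit(m=float(slope), dm=float(dm), r2=r2,
                           n_points=int(doses.size))


def ic50(fit: MedianEffectFit, max_tested_dose: float = None,
         ) -> Union[float, str]:
    """IC50 estimate: Dm (fa = 0.5 by construction of the median-effect model).

    When the estimate exceeds the tested dose range it is censored and
    reported as the string ``"> <max dose>"``.
    """
    if max_tested_dose is not None and fit.dm > max_tested_dose:
        return f"> {max_tested_dose:g}"
    return fit.dm


def combination_index(fit1: MedianEffectFit, fit2: MedianEffectFit,
                      combo: pd.DataFrame) -> pd.DataFrame:
    """Chou-Talalay CI for each combination observation.

    ``combo`` needs columns d1_uM, d2_uM, fa. Each row yields the
    single-agent iso-effective doses Dx1/Dx2 at that row's fa and
    CI = d1/Dx1 + d2/Dx2 (the mutually exclusive two-term form). Rows with
    fa outside (0, 1) are skipped with a warning.
    """
    required = {"d1_uM", "d2_uM", "fa"}
    if not required <= set(combo.columns):
        raise InvalidParameterError(f"combo table needs columns {sorted(required)}")
    ok = (combo["fa"] > 0) & (combo["fa"] < 1)
    if not ok.all():
        warnings.warn(f"skipping {int((~ok).sum())} combination row(s) with "
                      "fa outside (0, 1)")
    sub = combo[ok]
    fa = sub["fa"].to_numpy(dtype=float)
    dx1 = fit1.dx(fa)
    dx2 = fit2.dx(fa)
    ci = sub["d1_uM"].to_numpy() / dx1 + sub["d2_uM"].to_numpy() / dx2
    return pd.DataFrame({
        "fa": fa,
        "d1_uM": sub["d1_uM"].to_numpy(),
        "d2_uM": sub["d2_uM"].to_numpy(),
        "Dx1_uM": dx1,
        "Dx2_uM": dx2,
        "ci": ci,
    })
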