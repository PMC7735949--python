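"""The Visual Behaviour Index: one exposure score per subject.

A subject's VBI accumulates their time-use over the behaviour space,
weighted by each pixel's significant effect on refractive error:

    VBI_m = sum_ij PoT_m[i, j] * B[i, j]

Because PoT sums to 1, the VBI is a convex combination of B values:
positive when time is concentrated where behaviour predicts hyperopic
shift, negative where it predicts myopic shift. A cohort's VBI is then
related back to SER with ordinary linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior_space import PoTGrid
from .kernel_regression import EffectMaps


class VBIError(ValueError):
    pass


@dataclass(frozen=True)
class VBIResult:
    subject_id: str
    vbi: float


@dataclass(frozen=True)
class VBIRegression:
    """OLS of SER on VBI across the cohort (slope in D per VBI unit)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def compute_vbi(grid: PoTGrid, maps: EffectMaps) -> VBIResult:
    """Occupancy-weighted sum of the thresholded effect map."""
    if grid.spec != maps.spec:
        raise VBIError("grid and effect maps use different grid specs")
    return VBIResult(subject_id=grid.subject_id, vbi=float(np.sum(grid.grid * maps.b_map)))


def regress_ser_on_vbi(vbis: np.ndarray, sers: np.ndarray) -> VBIRegression:
    """Ordinary least squares of SER on VBI with slope, R^2 and the
    two-sided slope p value."""
    vbis = np.asarray(vbis, dtype=float)
    sers = np.asarray(sers, dtype=float)
    if vbis.shape != sers.shape or vbis.ndim != 1:
        raise VBIError("vbis and sers must be parallel 1D vectors")
    if len(vbis) < 3:
        raise VBIError("need at least 3 subjects")
    if np.ptp(vbis) == 0:
        raise VBIError("VBI has zero variance; regression undefined")
    res = stats.linregress(vbis, sers)
    return VBIRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=len(vbis),
    )
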