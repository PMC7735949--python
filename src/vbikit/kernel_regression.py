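"""Per-pixel regression of refractive error on kernel-smoothed occupancy.

Individual occupancy of the behaviour space is sparse: most pixels are
visited by few subjects. To borrow strength from neighbouring behaviour,
each pixel's predictor is a Gaussian-kernel-weighted sum of the
subject's PoT over the pixels within a circle of radius 2*sigma (in
pixel index units):

    x_m(i, j) = sum_{(a,b): d((a,b),(i,j)) <= 2 sigma} exp(-d^2 / (2 sigma^2)) * PoT_m[a, b]

SER is then regressed on x across subjects, pixel by pixel (ordinary
least squares, two-sided t test on the slope). The effect map B keeps
the slope beta wherever p < alpha and is zero elsewhere; it is the
per-pixel influence used by the Visual Behaviour Index.

Pixels where the predictor has zero variance across subjects (nobody in
the neighbourhood) have no estimable effect; they are flagged undefined
and contribute B = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .behavior_space import GridSpec, PoTGrid


class KernelError(ValueError):
    pass


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel width in pixel units; the neighbourhood radius is
    fixed at 2*sigma."""

    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise KernelError("sigma must be positive")

    @property
    def radius(self) -> float:
        return 2.0 * self.sigma


@dataclass
class Neighborhood:
    """A pixel's in-grid neighbours and their kernel weights.

    ``members`` holds ``((a, b), weight)`` with absolute grid indices;
    the centre is a member with weight exactly 1.
    """

    center: tuple[int, int]
    members: list[tuple[tuple[int, int], float]]


@dataclass
class PixelFit:
    """OLS fit of SER on one pixel's smoothed predictor."""

    beta: float
    intercept: float
    p_value: float
    n_used: int
    defined: bool


@dataclass
class EffectMaps:
    """Grid-shaped regression results: slope (beta), intercept, p value,
    and the alpha-thresholded effect map B (beta where p < alpha, else 0)."""

    beta_map: np.ndarray
    intercept_map: np.ndarray
    p_map: np.ndarray
    b_map: np.ndarray
    defined_map: np.ndarray
    alpha: float
    kernel: KernelSpec
    spec: GridSpec = field(default_factory=GridSpec)
    n_subjects: int = 0
    correction: str = "none"


def kernel_weight(center: tuple[int, int], other: tuple[int, int], sigma: float):
    """Gaussian weight exp(-d^2 / (2 sigma^2)) for pixel distance d, or
    ``None`` when the other pixel lies beyond the 2*sigma radius."""
    if sigma <= 0:
        raise KernelError("sigma must be positive")
    d2 = (center[0] - other[0]) ** 2 + (center[1] - other[1]) ** 2
    if d2 > (2.0 * sigma) ** 2:
        return None
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _kernel_offsets(sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer offsets (da, db) with da^2 + db^2 <= (2 sigma)^2 and their
    weights."""
    r = int(np.floor(2.0 * sigma))
    da, db = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    d2 = da**2 + db**2
    inside = d2 <= (2.0 * sigma) ** 2
    return da[inside], db[inside], np.exp(-d2[inside] / (2.0 * sigma**2))


def kernel_footprint(sigma: float) -> np.ndarray:
    """The truncated Gaussian kernel as a dense (2r+1)^2 stencil with
    zeros outside the 2*sigma circle."""
    r = int(np.floor(2.0 * sigma))
    da, db = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    d2 = da**2 + db**2
    w = np.exp(-d2 / (2.0 * sigma**2))
    w[d2 > (2.0 * sigma) ** 2] = 0.0
    return w


def neighborhood(i: int, j: int, kernel: KernelSpec, grid: GridSpec = GridSpec()) -> Neighborhood:
    """All in-grid pixels within distance 2*sigma of (i, j), weighted."""
    n = grid.n_bins
    if not (0 <= i < n and 0 <= j < n):
        raise KernelError(f"pixel ({i}, {j}) outside {n}x{n} grid")
    da, db, w = _kernel_offsets(kernel.sigma)
    a, b = i + da, j + db
    keep = (a >= 0) & (a < n) & (b >= 0) & (b < n)
    members = [((int(aa), int(bb)), float(ww)) for aa, bb, ww in zip(a[keep], b[keep], w[keep])]
    return Neighborhood(center=(i, j), members=members)


def smoothed_predictor(pot_grids: list[PoTGrid], nb: Neighborhood) -> np.ndarray:
    """Per-subject kernel-weighted occupancy over one neighbourhood."""
    if not pot_grids:
        return np.zeros(0)
    spec = pot_grids[0].spec
    if any(g.spec != spec for g in pot_grids):
        raise KernelError("all grids must share one GridSpec")
    out = np.zeros(len(pot_grids))
    for m, g in enumerate(pot_grids):
        out[m] = sum(w * g.grid[a, b] for (a, b), w in nb.members)
    return out


def fit_pixel(x: np.ndarray, ser: np.ndarray) -> PixelFit:
    """OLS of SER on the smoothed predictor with a two-sided t test on
    the slope (n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    ser = np.asarray(ser, dtype=float)
    if x.shape != ser.shape or x.ndim != 1:
        raise KernelError("x and ser must be parallel 1D vectors")
    n = len(x)
    if n < 3:
        return PixelFit(beta=np.nan, intercept=np.nan, p_value=np.nan, n_used=n, defined=False)
    if np.ptp(x) == 0:
        return PixelFit(beta=np.nan, intercept=np.nan, p_value=np.nan, n_used=n, defined=False)
    res = stats.linregress(x, ser)
    return PixelFit(
        beta=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        n_used=n,
        defined=True,
    )


def smoothed_predictor_matrix(pot_grids: list[PoTGrid], kernel: KernelSpec) -> np.ndarray:
    """Smoothed predictors for every pixel at once.

    Correlating each subject's grid with the truncated kernel stencil
    (zero padding outside the grid) yields exactly the neighbourhood sum
    with off-grid candidates excluded. Returns an array of shape
    (n_subjects, n_bins, n_bins).
    """
    stencil = kernel_footprint(kernel.sigma)
    return np.stack(
        [ndimage.correlate(g.grid, stencil, mode="constant", cval=0.0) for g in pot_grids]
    )


def fit_effect_maps(
    pot_grids: list[PoTGrid],
    sers: np.ndarray,
    kernel: KernelSpec = KernelSpec(),
    alpha: float = 0.05,
    correction: str = "none",
) -> EffectMaps:
    """Fit every pixel's regression and threshold into the B map.

    The per-pixel slopes, intercepts and p values are computed with the
    closed-form OLS normal equations, vectorised over pixels (identical
    to ``fit_pixel`` pixel by pixel). ``correction="bh"`` applies
    Benjamini-Hochberg across the defined pixels before thresholding;
    the default matches a raw per-pixel alpha of 0.05.
    """
    sers = np.asarray(sers, dtype=float)
    n = len(pot_grids)
    if n < 3 or len(sers) != n:
        raise KernelError("need >= 3 subjects with one SER each")
    if correction not in ("none", "bh"):
        raise KernelError(f"unknown correction {correction!r}")
    spec = pot_grids[0].spec
    nb = spec.n_bins

    X = smoothed_predictor_matrix(pot_grids, kernel).reshape(n, -1)
    xbar = X.mean(axis=0)
    ybar = sers.mean()
    xc = X - xbar
    yc = sers - ybar
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = yc @ xc
    syy = float(yc @ yc)

    defined = sxx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(defined, sxy / np.where(defined, sxx, 1.0), np.nan)
        intercept = ybar - beta * xbar
        rss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(rss / (n - 2) / np.where(defined, sxx, 1.0))
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = np.where(defined, 2.0 * stats.t.sf(np.abs(tstat), df=n - 2), np.nan)

    p_thresh = p.copy()
    if correction == "bh":
        p_thresh[defined] = stats.false_discovery_control(p[defined], method="bh")
    b = np.where(defined & (p_thresh < alpha), beta, 0.0)

    shape = (nb, nb)
    return EffectMaps(
        beta_map=beta.reshape(shape),
        intercept_map=intercept.reshape(shape),
        p_map=p.reshape(shape),
        b_map=b.reshape(shape),
        defined_map=defined.reshape(shape),
        alpha=alpha,
        kernel=kernel,
        spec=spec,
        n_subjects=n,
        correction=correction,
    )


def sign_agreement(
    maps: EffectMaps,
    truth_map: np.ndarray,
    occupancy_counts: np.ndarray,
    min_subjects: int = 10,
) -> float:
    """Fraction of well-occupied truly-affected pixels whose fitted
    nonzero effect has the right sign.

    Restricted to pixels with at least ``min_subjects`` occupants, a
    nonzero truth and a nonzero fitted B; compositional coupling (time
    in one pixel trades off against all others) makes signs at
    truth-zero pixels uninformative about recovery.
    """
    eligible = (occupancy_counts >= min_subjects) & (truth_map != 0) & (maps.b_map != 0)
    if not eligible.any():
        return np.nan
    return float(np.mean(np.sign(maps.b_map[eligible]) == np.sign(truth_map[eligible])))
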