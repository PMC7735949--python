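"""The 2D working-distance / light-intensity behaviour space.

Each subject's paired samples are binned on a 40x40 grid spanning
0-70 cm (WD) by 0-5 log10-lux (LI). A pixel's value is the percentage
of time (PoT) the subject spent in that (distance, illuminance)
circumstance, so every subject's grid sums to 1 over their measured
wear time. Axis 0 (rows, index i) is WD; axis 1 (columns, index j) is
log10 LI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ingest import JointSeries


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Binning of the behaviour space.

    Defaults: 40 bins per axis over WD 0-70 cm and log-LI 0-5
    (bin widths 1.75 cm and 0.125 log10-lux). Bins are half-open
    [edge_k, edge_{k+1}) with the top bin closed; values outside the
    ranges clamp to the edge bins.
    """

    n_bins: int = 40
    wd_range: tuple[float, float] = (0.0, 70.0)
    logli_range: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise GridError("n_bins must be >= 2")
        for lo, hi in (self.wd_range, self.logli_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise GridError("axis ranges must be finite with low < high")

    @property
    def wd_bin_width(self) -> float:
        return (self.wd_range[1] - self.wd_range[0]) / self.n_bins

    @property
    def logli_bin_width(self) -> float:
        return (self.logli_range[1] - self.logli_range[0]) / self.n_bins

    def wd_centers(self) -> np.ndarray:
        return self.wd_range[0] + (np.arange(self.n_bins) + 0.5) * self.wd_bin_width

    def logli_centers(self) -> np.ndarray:
        return self.logli_range[0] + (np.arange(self.n_bins) + 0.5) * self.logli_bin_width

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "wd_range": list(self.wd_range),
            "logli_range": list(self.logli_range),
            "axis0": "WD (cm)",
            "axis1": "log10 LI (lux)",
        }


@dataclass
class PoTGrid:
    """A subject's percentage-of-time occupancy map."""

    subject_id: str
    grid: np.ndarray
    total_time_s: float
    spec: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (self.spec.n_bins, self.spec.n_bins):
            raise GridError(
                f"grid shape {self.grid.shape} does not match spec {self.spec.n_bins}"
            )
        if np.any(self.grid < 0):
            raise GridError("PoT entries must be non-negative")
        if self.total_time_s > 0 and abs(self.grid.sum() - 1.0) > 1e-9:
            raise GridError("PoT grid must sum to 1 when wear time is positive")


def _axis_index(values: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    width = (hi - lo) / n_bins
    idx = np.floor((np.asarray(values, dtype=float) - lo) / width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def bin_index(wd, log_li, spec: GridSpec = GridSpec()):
    """Map (WD, log-LI) coordinates to (i, j) pixel indices.

    Out-of-range values clamp to the nearest edge bin; the top edge
    belongs to the last bin.
    """
    i = _axis_index(wd, *spec.wd_range, spec.n_bins)
    j = _axis_index(log_li, *spec.logli_range, spec.n_bins)
    if np.isscalar(wd) or np.ndim(wd) == 0:
        return int(i), int(j)
    return i, j


def build_pot_grid(joint: JointSeries, spec: GridSpec = GridSpec()) -> PoTGrid:
    """Accumulate each paired sample's represented seconds into its pixel
    and normalise by the total, so the grid sums to 1."""
    if len(joint) == 0:
        raise GridError(f"{joint.subject_id}: empty joint series")
    i, j = bin_index(joint.wd, joint.log_li, spec)
    total = float(joint.sample_weight.sum())
    grid = np.zeros((spec.n_bins, spec.n_bins))
    np.add.at(grid, (i, j), joint.sample_weight)
    grid /= total
    return PoTGrid(subject_id=joint.subject_id, grid=grid, total_time_s=total, spec=spec)


def population_occupancy(grids: list[PoTGrid]) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean PoT over subjects, plus the per-pixel count of
    subjects with any occupancy (used to flag sparse pixels)."""
    if not grids:
        raise GridError("population_occupancy needs at least one grid")
    spec = grids[0].spec
    if any(g.spec != spec for g in grids):
        raise GridError("all grids must share one GridSpec")
    stack = np.stack([g.grid for g in grids])
    return stack.mean(axis=0), (stack > 0).sum(axis=0)


def save_grid(grid: PoTGrid, path: str | Path) -> None:
    """CSV grid (rows = WD bins) with a JSON sidecar for spec and totals."""
    path = Path(path)
    np.savetxt(path, grid.grid, delimiter=",", fmt="%.10g")
    sidecar = {
        "subject_id": grid.subject_id,
        "total_time_s": grid.total_time_s,
        "grid_spec": grid.spec.to_dict(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_grid(path: str | Path) -> PoTGrid:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    gs = meta["grid_spec"]
    spec = GridSpec(
        n_bins=gs["n_bins"], wd_range=tuple(gs["wd_range"]), logli_range=tuple(gs["logli_range"])
    )
    return PoTGrid(
        subject_id=meta["subject_id"],
        grid=np.loadtxt(path, delimiter=",").reshape(spec.n_bins, spec.n_bins),
        total_time_s=meta["total_time_s"],
        spec=spec,
    )
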