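"""End-to-end orchestration: streams in, effect maps, VBI and figures out.

``run_pipeline`` wires the stages together — read refraction and
streams, preprocess, bin into PoT grids, fit the per-pixel effect maps,
score every subject's VBI and regress SER on it — and serialises every
intermediate artifact plus a manifest sufficient to reproduce the run.
Figures are advisory renderings of the numeric artifacts and never feed
back into them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior_space import GridSpec, PoTGrid, build_pot_grid, population_occupancy, save_grid
from .cohort import apply_inclusion_filters, cohort_summary, read_refraction_csv, records_to_frame
from .denoise import FilterSpec, preprocess_subject
from .ingest import SensorSpec, read_series
from .kernel_regression import EffectMaps, KernelSpec, fit_effect_maps
from .vbi import compute_vbi, regress_ser_on_vbi

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    input_dir: str = "."
    out_dir: str = "out"
    grid: GridSpec = field(default_factory=GridSpec)
    filter: FilterSpec = field(default_factory=FilterSpec)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    sensor: SensorSpec = field(default_factory=SensorSpec)
    alpha: float = 0.05
    correction: str = "none"
    gap_factor: float = 2.0
    max_staleness_s: float = 120.0
    aniso_limit: float = 1.00
    seed: int = 0
    figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, klass in (("grid", GridSpec), ("filter", FilterSpec),
                           ("kernel", KernelSpec), ("sensor", SensorSpec)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in kwargs[key].items()
                }
                kwargs[key] = klass(**sub)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _save_map(arr: np.ndarray, path: Path) -> None:
    np.savetxt(path, arr, delimiter=",", fmt="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``out_dir``.

    Returns a dict with the in-memory results (records, grids, maps,
    VBI table, regression) for programmatic use.
    """
    indir = Path(config.input_dir)
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- cohort ---------------------------------------------------------
    try:
        exams = read_refraction_csv(indir / "refraction.csv")
        records = apply_inclusion_filters(exams, config.aniso_limit)
        summary = cohort_summary(records)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cohort", str(e)) from e
    records_to_frame(records).to_csv(outdir / "records.csv", index=False)
    (outdir / "cohort_summary.json").write_text(json.dumps(summary, indent=2))

    # --- streams -> PoT grids ------------------------------------------
    grids: list[PoTGrid] = []
    sers: list[float] = []
    ser_by_id = {r.subject_id: r.ser for r in records}
    counts = {"preprocessed": 0, "skipped": 0}
    for rec_id in sorted(ser_by_id):
        sdir = indir / rec_id
        try:
            wd = read_series(sdir / "WD.csv", "WD", subject_id=rec_id)
            li = read_series(sdir / "LI.csv", "LI", subject_id=rec_id)
            joint = preprocess_subject(
                wd, li, config.filter, config.sensor,
                gap_factor=config.gap_factor, max_staleness=config.max_staleness_s,
            )
            grids.append(build_pot_grid(joint, config.grid))
            sers.append(ser_by_id[rec_id])
            counts["preprocessed"] += 1
        except FileNotFoundError:
            logger.warning("no streams for subject %s; skipped", rec_id)
            counts["skipped"] += 1
    if len(grids) < 3:
        raise PipelineError("preprocess", f"only {len(grids)} subjects with usable streams")

    grid_dir = outdir / "grids"
    grid_dir.mkdir(exist_ok=True)
    for g in grids:
        save_grid(g, grid_dir / f"{g.subject_id}.csv")
    mean_occ, occ_counts = population_occupancy(grids)
    _save_map(mean_occ, outdir / "population_occupancy.csv")
    _save_map(occ_counts, outdir / "occupancy_counts.csv")

    # --- effect maps ----------------------------------------------------
    sers_arr = np.array(sers)
    try:
        maps = fit_effect_maps(grids, sers_arr, config.kernel, config.alpha, config.correction)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit", str(e)) from e
    for name, arr in (
        ("beta_map", maps.beta_map),
        ("intercept_map", maps.intercept_map),
        ("p_map", maps.p_map),
        ("b_map", maps.b_map),
    ):
        _save_map(arr, outdir / f"{name}.csv")
    (outdir / "effect_maps.json").write_text(
        json.dumps(
            {
                "alpha": maps.alpha,
                "sigma": maps.kernel.sigma,
                "correction": maps.correction,
                "n_subjects": maps.n_subjects,
                "n_defined_pixels": int(maps.defined_map.sum()),
                "n_significant_pixels": int(np.count_nonzero(maps.b_map)),
                "grid_spec": maps.spec.to_dict(),
            },
            indent=2,
        )
    )

    # --- VBI ------------------------------------------------------------
    try:
        vbis = np.array([compute_vbi(g, maps).vbi for g in grids])
        reg = regress_ser_on_vbi(vbis, sers_arr)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("vbi", str(e)) from e
    vbi_table = pd.DataFrame(
        {"subject_id": [g.subject_id for g in grids], "vbi": vbis, "ser": sers_arr}
    )
    vbi_table.to_csv(outdir / "vbi.csv", index=False, float_format="%.8g")
    (outdir / "vbi_regression.json").write_text(json.dumps(asdict(reg), indent=2))

    manifest = {
        "package": "vbikit",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    results = {
        "records": records,
        "summary": summary,
        "grids": grids,
        "occupancy": (mean_occ, occ_counts),
        "maps": maps,
        "vbi_table": vbi_table,
        "regression": reg,
    }
    if config.figures:
        render_maps(maps, mean_occ, vbi_table, outdir)
    return results


def render_maps(
    maps: EffectMaps | None,
    occupancy: np.ndarray | None,
    vbi_table: pd.DataFrame | None,
    outdir: str | Path,
) -> list[Path]:
    """Render heatmaps (occupancy, p map, B map) and the VBI-SER scatter.

    Missing artifacts are skipped with a warning; rendering never
    mutates the numeric artifacts.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _heat(arr, title, fname, cmap, **kw):
        fig, ax = plt.subplots(figsize=(5, 4.2))
        spec = maps.spec if maps is not None else GridSpec()
        im = ax.imshow(
            arr.T, origin="lower", aspect="auto", cmap=cmap,
            extent=[*spec.wd_range, *spec.logli_range], **kw,
        )
        ax.set_xlabel("working distance (cm)")
        ax.set_ylabel("log10 light intensity (lux)")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
        path = outdir / fname
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if occupancy is not None:
        _heat(occupancy, "mean occupancy (PoT)", "fig_occupancy.png", "hot")
    else:
        logger.warning("no occupancy artifact; skipping occupancy figure")
    if maps is not None:
        _heat(np.nan_to_num(maps.p_map, nan=1.0), "p value map", "fig_p_map.png", "coolwarm",
              vmin=0, vmax=1)
        bmax = float(np.max(np.abs(maps.b_map))) or 1.0
        _heat(maps.b_map, "effect map B (D per unit PoT)", "fig_b_map.png", "RdYlGn",
              vmin=-bmax, vmax=bmax)
    else:
        logger.warning("no effect maps; skipping map figures")
    if vbi_table is not None and len(vbi_table) >= 3 and vbi_table["vbi"].std() > 0:
        from scipy import stats

        fig, ax = plt.subplots(figsize=(5, 4.2))
        ax.scatter(vbi_table["vbi"], vbi_table["ser"], s=12, alpha=0.7)
        res = stats.linregress(vbi_table["vbi"], vbi_table["ser"])
        xs = np.linspace(vbi_table["vbi"].min(), vbi_table["vbi"].max(), 50)
        ax.plot(xs, res.intercept + res.slope * xs, "r-",
                label=f"slope={res.slope:.4f}, R²={res.rvalue ** 2:.3f}")
        ax.set_xlabel("VBI")
        ax.set_ylabel("SER (D)")
        ax.legend()
        path = outdir / "fig_vbi_scatter.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    else:
        logger.warning("no usable VBI table; skipping scatter figure")
    return written
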