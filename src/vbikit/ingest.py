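"""Reading, validation, segmentation and channel pairing of wearable streams.

The device samples working distance (WD, cm, infrared sensor, range
15-60 cm) every 5 s and eye-level illuminance (LI, lux, range 1-65536 lux)
every 120 s. Streams arrive as delimited text with one timestamped value
per row; downstream spectral filtering needs uniformly sampled segments,
and the 2D behaviour space needs paired (WD, LI) samples, which this
module produces by carrying the last LI observation forward onto WD
timestamps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WD_NOMINAL_INTERVAL_S = 5.0
LI_NOMINAL_INTERVAL_S = 120.0

_NOMINAL_INTERVALS = {"WD": WD_NOMINAL_INTERVAL_S, "LI": LI_NOMINAL_INTERVAL_S}


class IngestError(ValueError):
    """Raised for unusable stream input."""


@dataclass(frozen=True)
class SensorSpec:
    """Hardware measurement ranges, inclusive at both ends."""

    wd_range: tuple[float, float] = (15.0, 60.0)
    li_range: tuple[float, float] = (1.0, 65536.0)

    def range_for(self, channel: str) -> tuple[float, float]:
        return self.wd_range if channel == "WD" else self.li_range


@dataclass
class BehaviorSeries:
    """One channel's timestamped samples for one subject.

    ``timestamps`` are seconds (monotone strictly increasing), ``values``
    are cm for WD and lux for LI.
    """

    subject_id: str
    channel: str
    timestamps: np.ndarray
    values: np.ndarray
    nominal_interval: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channel not in ("WD", "LI"):
            raise IngestError(f"unknown channel {self.channel!r}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape or self.timestamps.ndim != 1:
            raise IngestError("timestamps and values must be parallel 1D arrays")
        if not self.nominal_interval:
            self.nominal_interval = _NOMINAL_INTERVALS[self.channel]
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise IngestError("timestamps must be strictly increasing")
        if len(self.values) and not np.all(np.isfinite(self.values)):
            raise IngestError("values must be finite")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class JointSeries:
    """Paired (WD, log10 LI) samples on WD timestamps for one subject.

    ``sample_weight`` is the wall-clock seconds each paired sample
    represents (the WD sampling interval).
    """

    subject_id: str
    timestamps: np.ndarray
    wd: np.ndarray
    log_li: np.ndarray
    sample_weight: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.wd = np.asarray(self.wd, dtype=float)
        self.log_li = np.asarray(self.log_li, dtype=float)
        self.sample_weight = np.asarray(self.sample_weight, dtype=float)
        n = len(self.timestamps)
        if not (len(self.wd) == len(self.log_li) == len(self.sample_weight) == n):
            raise IngestError("joint series arrays must have equal length")
        if n and not np.all(self.sample_weight > 0):
            raise IngestError("sample weights must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)


def read_series(path: str | Path, channel: str, subject_id: str | None = None) -> BehaviorSeries:
    """Read one channel from a per-channel CSV.

    Accepts either ``timestamp,value`` (optionally with ``subject_id``)
    or the combined dialect ``subject_id,timestamp,channel,value`` (rows
    for other channels ignored). Timestamps may be numeric seconds or
    ISO-8601. Unparseable rows are logged and dropped; duplicate
    timestamps keep the first occurrence.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "channel" in cols:
        df = df[df[cols["channel"]].astype(str).str.upper() == channel]
    if subject_id is None:
        subject_id = (
            str(df[cols["subject_id"]].iloc[0]) if "subject_id" in cols and len(df) else path.parent.name
        )
    tcol = next((cols[c] for c in ("timestamp", "timestamp_iso8601", "time", "t") if c in cols), None)
    vcol = next((cols[c] for c in ("value", channel.lower()) if c in cols), None)
    if tcol is None or vcol is None:
        raise IngestError(f"{path}: cannot locate timestamp/value columns in {list(df.columns)}")

    ts_raw = df[tcol]
    ts = pd.to_numeric(ts_raw, errors="coerce")
    if ts.isna().any():
        parsed = pd.to_datetime(ts_raw, errors="coerce", utc=True, format="ISO8601")
        iso = parsed.notna() & ts.isna()
        ts = ts.astype(float)
        ts[iso] = parsed[iso].astype("int64") / 1e9
    vals = pd.to_numeric(df[vcol], errors="coerce")
    good = ts.notna() & vals.notna() & np.isfinite(vals)
    n_bad = int((~good).sum())
    if n_bad:
        logger.warning("%s: dropped %d unparseable rows", path, n_bad)
    if good.sum() == 0:
        raise IngestError(f"{path}: no parseable rows")

    t = ts[good].to_numpy(dtype=float)
    v = vals[good].to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    keep = np.concatenate(([True], np.diff(t) > 0))
    if not keep.all():
        logger.warning("%s: dropped %d duplicate timestamps (kept first)", path, int((~keep).sum()))
    return BehaviorSeries(subject_id=subject_id, channel=channel, timestamps=t[keep], values=v[keep],
                          meta={"n_rows_dropped": n_bad})


def validate_series(
    series: BehaviorSeries, spec: SensorSpec = SensorSpec(), drop: bool = True
) -> tuple[BehaviorSeries, np.ndarray]:
    """Flag samples outside the sensor's measurement range (inclusive).

    Returns ``(series, out_of_range_mask)`` where the mask indexes the
    *input* series. With ``drop=True`` (default) the returned series has
    the flagged samples removed; the count is kept in ``meta``.
    """
    if len(series) == 0:
        raise IngestError("cannot validate an empty series")
    lo, hi = spec.range_for(series.channel)
    mask = (series.values < lo) | (series.values > hi)
    n_out = int(mask.sum())
    if not drop or n_out == 0:
        out = series
    else:
        out = replace(series, timestamps=series.timestamps[~mask], values=series.values[~mask])
    out.meta = dict(series.meta, n_out_of_range=n_out)
    return out, mask


def segment_uniform(series: BehaviorSeries, gap_factor: float = 2.0) -> list[BehaviorSeries]:
    """Split a series into contiguous segments at sampling gaps.

    A new segment starts wherever the inter-sample interval exceeds
    ``gap_factor * nominal_interval``; within a segment the spacing is
    near-uniform. Concatenating the segments reproduces the input.
    """
    if len(series) == 0:
        return []
    gaps = np.diff(series.timestamps)
    cuts = np.flatnonzero(gaps > gap_factor * series.nominal_interval) + 1
    bounds = np.concatenate(([0], cuts, [len(series)]))
    return [
        replace(series, timestamps=series.timestamps[a:b], values=series.values[a:b])
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def pair_channels(
    wd: BehaviorSeries,
    li: BehaviorSeries,
    max_staleness: float = 120.0,
    li_is_log: bool = False,
) -> JointSeries:
    """Attach to each WD sample the most recent LI sample (LOCF pairing).

    Only LI observations no older than ``max_staleness`` seconds qualify;
    WD samples with no eligible LI are dropped. ``li_is_log`` marks LI
    values that are already on the log10 scale (the denoising pipeline
    log-scales before filtering); raw-lux values are log-scaled here.
    """
    if wd.channel != "WD" or li.channel != "LI":
        raise IngestError("pair_channels expects (WD, LI) series in that order")
    # index of last LI timestamp <= each WD timestamp
    idx = np.searchsorted(li.timestamps, wd.timestamps, side="right") - 1
    has_prior = idx >= 0
    age = np.where(has_prior, wd.timestamps - li.timestamps[np.clip(idx, 0, None)], np.inf)
    ok = has_prior & (age <= max_staleness)
    if not ok.any():
        raise IngestError(f"{wd.subject_id}: no WD sample has an LI observation within "
                          f"{max_staleness:.0f} s")
    li_vals = li.values[idx[ok]]
    if not li_is_log:
        from .denoise import log_scale_li

        li_vals = log_scale_li(li_vals)
    n = int(ok.sum())
    return JointSeries(
        subject_id=wd.subject_id,
        timestamps=wd.timestamps[ok],
        wd=wd.values[ok],
        log_li=li_vals,
        sample_weight=np.full(n, wd.nominal_interval),
        meta={"n_wd_unpaired": int(len(wd) - n)},
    )


def concat_joint(parts: list[JointSeries]) -> JointSeries:
    """Concatenate per-segment joint series for one subject."""
    parts = [p for p in parts if len(p)]
    if not parts:
        raise IngestError("no paired samples in any segment")
    return JointSeries(
        subject_id=parts[0].subject_id,
        timestamps=np.concatenate([p.timestamps for p in parts]),
        wd=np.concatenate([p.wd for p in parts]),
        log_li=np.concatenate([p.log_li for p in parts]),
        sample_weight=np.concatenate([p.sample_weight for p in parts]),
    )
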