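"""Spectral denoising of the wearable streams.

Illuminance spans five orders of magnitude, so it is moved to a log10
scale first; both channels are then low-pass filtered with an ideal
(brick-wall) filter implemented in the frequency domain: forward FFT,
zero every coefficient above the cutoff frequency, inverse FFT. The DC
coefficient is never touched, so segment means are preserved exactly,
and removing spectral energy can only shrink the variance (Parseval).

The device gives no filter cutoffs; the defaults (WD 0.01 Hz, LI
1/600 Hz) suppress sample-to-sample sensor jitter while keeping changes
on the timescale of activity switches (minutes). Both are configurable
and recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ingest import (
    BehaviorSeries,
    IngestError,
    JointSeries,
    SensorSpec,
    concat_joint,
    pair_channels,
    segment_uniform,
    validate_series,
)


class FilterError(ValueError):
    """Raised for inputs the spectral filter cannot handle."""


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass cutoffs (Hz) per channel and the minimum segment length
    (samples) worth filtering; shorter segments pass through unchanged."""

    wd_cutoff_hz: float = 0.01
    li_cutoff_hz: float = 1.0 / 600.0
    min_segment_len: int = 4

    def __post_init__(self) -> None:
        if self.wd_cutoff_hz <= 0 or self.li_cutoff_hz <= 0:
            raise FilterError("cutoff frequencies must be positive")
        if self.min_segment_len < 4:
            raise FilterError("min_segment_len must be >= 4")

    def cutoff_for(self, channel: str) -> float:
        return self.wd_cutoff_hz if channel == "WD" else self.li_cutoff_hz


def log_scale_li(li):
    """log10 of illuminance, clamping values below 1 lux to 0 log-lux.

    The sensor floor is 1 lux; sub-unit readings carry no information
    beyond "dark" and would map to negative log values outside the
    behaviour space, so they clamp to the axis origin.
    """
    arr = np.asarray(li, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise FilterError("illuminance must be finite and non-negative")
    out = np.log10(np.maximum(arr, 1.0))
    return float(out) if np.isscalar(li) else out


def lowpass_fft(
    values: np.ndarray,
    sample_interval_s: float,
    cutoff_hz: float,
    spacing_rtol: float = 0.05,
    timestamps: np.ndarray | None = None,
) -> np.ndarray:
    """Ideal low-pass filter: zero all FFT coefficients with
    |frequency| > cutoff_hz and invert.

    Requires (near-)uniform sampling; pass ``timestamps`` to have the
    spacing checked. Output length equals input length; the mean (DC
    term) is preserved and the real part of the inverse transform is
    returned.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise FilterError("lowpass_fft needs a 1D series of length >= 4")
    if cutoff_hz <= 0 or sample_interval_s <= 0:
        raise FilterError("cutoff and sample interval must be positive")
    if timestamps is not None:
        dt = np.diff(np.asarray(timestamps, dtype=float))
        if np.any(np.abs(dt - sample_interval_s) > spacing_rtol * sample_interval_s):
            raise FilterError(
                "non-uniform sampling: split the series with segment_uniform before filtering"
            )
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=sample_interval_s)
    spec[freqs > cutoff_hz] = 0.0
    return np.fft.irfft(spec, n=len(x))


def filter_series(
    series: BehaviorSeries, filter_spec: FilterSpec, gap_factor: float = 2.0
) -> BehaviorSeries:
    """Low-pass one uniform segment in place of its values; segments
    shorter than ``min_segment_len`` pass through unfiltered.

    Isolated missed ticks (gaps up to ``gap_factor`` times the nominal
    interval, which the segmenter leaves inside a segment) are treated
    as uniform samples at the nominal rate.
    """
    if len(series) < filter_spec.min_segment_len:
        return series
    filtered = lowpass_fft(
        series.values,
        series.nominal_interval,
        filter_spec.cutoff_for(series.channel),
        spacing_rtol=max(0.05, gap_factor - 1.0),
        timestamps=series.timestamps,
    )
    from dataclasses import replace

    return replace(series, values=filtered)


def preprocess_subject(
    wd_raw: BehaviorSeries,
    li_raw: BehaviorSeries,
    filter_spec: FilterSpec = FilterSpec(),
    sensor_spec: SensorSpec = SensorSpec(),
    gap_factor: float = 2.0,
    max_staleness: float = 120.0,
) -> JointSeries:
    """Full per-subject preprocessing: validate each channel, split into
    uniform wear segments, log-scale LI, low-pass filter each segment,
    and pair the channels onto WD timestamps.

    Filtered WD may slightly overshoot the sensor range (ringing); it is
    deliberately not re-clamped, the occupancy grid covers 0-70 cm.
    """
    wd, _ = validate_series(wd_raw, sensor_spec)
    li, _ = validate_series(li_raw, sensor_spec)

    from dataclasses import replace

    li = replace(li, values=log_scale_li(li.values))

    wd_segments = [filter_series(s, filter_spec, gap_factor) for s in segment_uniform(wd, gap_factor)]
    li_segments = [filter_series(s, filter_spec, gap_factor) for s in segment_uniform(li, gap_factor)]
    if not wd_segments or not li_segments:
        raise IngestError(f"{wd_raw.subject_id}: a channel is empty after validation")

    li_all = li_segments[0]
    if len(li_segments) > 1:
        li_all = replace(
            li_all,
            timestamps=np.concatenate([s.timestamps for s in li_segments]),
            values=np.concatenate([s.values for s in li_segments]),
        )

    joint_parts = []
    for seg in wd_segments:
        try:
            joint_parts.append(pair_channels(seg, li_all, max_staleness, li_is_log=True))
        except IngestError:
            continue  # segment with no eligible LI contributes nothing
    joint = concat_joint(joint_parts)
    joint.meta = {
        "wd_out_of_range": wd.meta.get("n_out_of_range", 0),
        "li_out_of_range": li.meta.get("n_out_of_range", 0),
        "n_wd_segments": len(wd_segments),
        "filter": {
            "wd_cutoff_hz": filter_spec.wd_cutoff_hz,
            "li_cutoff_hz": filter_spec.li_cutoff_hz,
            "min_segment_len": filter_spec.min_segment_len,
        },
    }
    return joint
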