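"""Seeded generator of device-realistic synthetic cohorts.

The study device records working distance every 5 s (15-60 cm) and
eye-level illuminance every 120 s (1-65536 lux) over a week of daytime
wear. No such recordings are publicly deposited, so this module
simulates them: each subject alternates between activity states (near
reading, desk work, screens, dim-light near work, outdoor, other
indoor) in a renewal process with exponential dwell times, with
per-subject Dirichlet-distributed state preferences providing
behavioural heterogeneity. Sensor clipping, quantisation, daily wear
windows and random non-wear gaps are applied at generation, so the
emitted streams pass ingest validation unchanged.

Refractive error is generated from the same additive exposure model the
analysis assumes: SER_m = baseline + sum_ij PoT_m[i,j] * truth[i,j] + noise,
with PoT computed by the real preprocessing pipeline on the simulated
streams. The ground-truth effect map therefore defines exactly what a
perfect analysis should recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior_space import GridSpec, PoTGrid, build_pot_grid
from .denoise import FilterSpec, preprocess_subject
from .ingest import BehaviorSeries, SensorSpec


@dataclass(frozen=True)
class ActivityState:
    """One behavioural regime: the WD/LI distribution while in it.

    ``wd_mean is None`` marks states with no near target in the
    distance sensor's field (outdoor, walking around): they emit no WD
    sample. ``logli`` parameters are on the log10-lux scale.
    """

    name: str
    wd_mean: float | None
    wd_sd: float | None
    logli_mean: float
    logli_sd: float
    mean_dwell_s: float

    def __post_init__(self) -> None:
        if self.mean_dwell_s <= 0 or self.logli_sd <= 0:
            raise ValueError(f"{self.name}: dwell and spreads must be positive")
        if self.wd_mean is not None and (self.wd_sd is None or self.wd_sd <= 0):
            raise ValueError(f"{self.name}: wd_sd must be positive when wd_mean is set")


#: Default behavioural repertoire for a school-age cohort: a mix of
#: near work at varying distance and illuminance, dim-light near work,
#: outdoor time and non-near indoor time.
DEFAULT_STATES: tuple[ActivityState, ...] = (
    ActivityState("near_reading", 25.0, 3.5, 2.3, 0.35, 1500.0),
    ActivityState("desk_work", 50.0, 4.0, 2.5, 0.35, 1800.0),
    ActivityState("screen", 33.0, 4.0, 2.0, 0.35, 1800.0),
    ActivityState("dim_near", 17.0, 1.5, 0.3, 0.3, 1800.0),
    ActivityState("outdoor", None, None, 4.2, 0.4, 2400.0),
    ActivityState("indoor_other", None, None, 1.9, 0.5, 1200.0),
)

DEFAULT_BASE_PREF: tuple[float, ...] = (0.26, 0.14, 0.20, 0.06, 0.14, 0.20)

#: Seconds spent in a near-work bout's ambient light before and after
#: the bout itself (arriving in the room, lingering afterwards).
AMBIENT_INTERLUDE_RANGE_S: tuple[float, float] = (300.0, 900.0)


def default_truth_map(
    spec: GridSpec = GridSpec(),
    risky_effect: float = -6.0,
    protective_effect: float = 3.0,
    wd_risky_max_cm: float = 40.0,
    logli_risky_max: float = 3.8,
    wd_protective_max_cm: float = 20.0,
    logli_protective_max: float = 1.0,
) -> np.ndarray:
    """Ground-truth per-pixel effect grid (D per unit PoT).

    Myopiagenic (negative) effect on pixels whose centre lies at
    WD < 40 cm and log-LI < 3.8 (the detrimental zone: close work
    without bright light); within that, a mild protective (positive)
    patch at WD < 20 cm and log-LI < 1 emulating the dim-light niche.
    Zero elsewhere: beyond 40 cm or above ~6300 lux behaviour is
    neutral. Pixel membership is decided by bin centres.
    """
    wd = spec.wd_centers()[:, None]
    logli = spec.logli_centers()[None, :]
    truth = np.zeros((spec.n_bins, spec.n_bins))
    truth[(wd < wd_risky_max_cm) & (logli < logli_risky_max)] = risky_effect
    truth[(wd < wd_protective_max_cm) & (logli < logli_protective_max)] = protective_effect
    return truth


@dataclass(frozen=True)
class SimConfig:
    """Everything the generator needs; reproducible from (config, seed)."""

    states: tuple[ActivityState, ...] = DEFAULT_STATES
    base_pref: tuple[float, ...] = DEFAULT_BASE_PREF
    pref_concentration: float = 30.0
    days: int = 7
    wd_interval_s: float = 5.0
    li_interval_s: float = 120.0
    wear_start_h: float = 7.5
    wear_end_h: float = 21.5
    nonwear_gaps_per_day: int = 2
    nonwear_gap_minutes: tuple[float, float] = (10.0, 40.0)
    sensor: SensorSpec = SensorSpec()
    wd_quantum_cm: float = 0.1
    # ser_baseline is the refraction of a hypothetical subject with zero
    # risky exposure; with the default behaviour mix (mean exposure about
    # -3.7 D) these defaults put the cohort SER near mean +0.22, SD 1.18 D.
    ser_baseline: float = 3.89
    ser_noise_sd: float = 0.75
    grid_spec: GridSpec = GridSpec()
    truth_map: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.states) != len(self.base_pref):
            raise ValueError("base_pref must have one weight per state")
        if self.days < 1 or self.seed is None:
            raise ValueError("days >= 1 and an explicit seed are required")
        if not (0 <= self.wear_start_h < self.wear_end_h <= 24):
            raise ValueError("wear window must lie within one day")

    def resolved_truth_map(self) -> np.ndarray:
        return self.truth_map if self.truth_map is not None else default_truth_map(self.grid_spec)


@dataclass
class SimulatedSubject:
    subject_id: str
    wd: BehaviorSeries
    li: BehaviorSeries
    ser: float
    pot: PoTGrid
    exposure: float  # sum(PoT * truth), the noiseless SER shift
    pref: np.ndarray


@dataclass
class SimulatedCohort:
    subjects: list[SimulatedSubject]
    truth_map: np.ndarray
    config: SimConfig

    @property
    def sers(self) -> np.ndarray:
        return np.array([s.ser for s in self.subjects])

    @property
    def pot_grids(self) -> list[PoTGrid]:
        return [s.pot for s in self.subjects]


def subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    """Stable per-subject generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(master_seed), int(subject_index))))


def stationary_occupancy(pref: np.ndarray, states: tuple[ActivityState, ...]) -> np.ndarray:
    """Long-run fraction of time spent in each state's light context.

    For the renewal process this is the preference weight times the
    expected cycle length: the mean dwell, plus the two ambient
    interludes that sandwich near-work bouts (which share the bout's
    illumination), normalised over states.
    """
    amb = float(np.mean(AMBIENT_INTERLUDE_RANGE_S))
    cycle = np.array(
        [s.mean_dwell_s + (2.0 * amb if s.wd_mean is not None else 0.0) for s in states]
    )
    w = np.asarray(pref, dtype=float) * cycle
    return w / w.sum()


def _wear_intervals(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(start, end) second pairs of device wear, one window per day with
    random non-wear gaps punched out."""
    lo_min, hi_min = config.nonwear_gap_minutes
    intervals: list[tuple[float, float]] = []
    for d in range(config.days):
        start = d * 86400.0 + config.wear_start_h * 3600.0
        end = d * 86400.0 + config.wear_end_h * 3600.0
        gaps = []
        for _ in range(config.nonwear_gaps_per_day):
            dur = rng.uniform(lo_min * 60.0, hi_min * 60.0)
            g0 = rng.uniform(start, end - dur)
            gaps.append((g0, g0 + dur))
        cur = start
        for g0, g1 in sorted(gaps):
            if g0 > cur:
                intervals.append((cur, g0))
            cur = max(cur, g1)
        if cur < end:
            intervals.append((cur, end))
    return np.array(intervals)


def _state_timeline(
    config: SimConfig, pref: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Renewal-process activity sequence covering the whole simulated span.

    At each renewal the next state is drawn from the subject's
    preferences and held for an exponential dwell. A near-work bout is
    sandwiched between "ambient" interludes lit like the bout itself but
    with no near target: the subject is in the room before picking up
    the task and lingers after putting it down. This keeps illumination
    attached to locations (people do not teleport between light
    environments) and leaves the distance stream segmented at task
    switches instead of ramping between targets.

    Returns ``(starts, li_state, wd_state)`` where ``wd_state`` is -1
    during periods with no near target.
    """
    horizon = config.days * 86400.0
    dwell_means = np.array([s.mean_dwell_s for s in config.states])
    has_target = np.array([s.wd_mean is not None for s in config.states])
    starts: list[float] = []
    li_state: list[int] = []
    wd_state: list[int] = []
    t = 0.0
    while t < horizon:
        k = int(rng.choice(len(config.states), p=pref))
        if has_target[k]:
            pre, post = rng.uniform(*AMBIENT_INTERLUDE_RANGE_S, size=2)
            starts.append(t)
            li_state.append(k)
            wd_state.append(-1)
            t += pre
            starts.append(t)
            li_state.append(k)
            wd_state.append(k)
            t += rng.exponential(dwell_means[k])
            starts.append(t)
            li_state.append(k)
            wd_state.append(-1)
            t += post
        else:
            starts.append(t)
            li_state.append(k)
            wd_state.append(k)
            t += rng.exponential(dwell_means[k])
    return np.array(starts), np.array(li_state, dtype=int), np.array(wd_state, dtype=int)


def _ticks_in_wear(interval_s: float, wear: np.ndarray, horizon: float) -> np.ndarray:
    ticks = np.arange(0.0, horizon, interval_s)
    idx = np.searchsorted(wear[:, 0], ticks, side="right") - 1
    ok = (idx >= 0) & (ticks < wear[np.clip(idx, 0, None), 1])
    return ticks[ok]


def simulate_subject(
    config: SimConfig, subject_seed_index: int, subject_id: str | None = None
) -> tuple[BehaviorSeries, BehaviorSeries, np.ndarray]:
    """Generate one subject's WD and LI streams.

    Returns (wd, li, pref). WD values are truncated to the sensor range
    and quantised to 0.1 cm; LI values are drawn log-normally per state,
    clipped to 1-65536 lux and rounded to integer lux. States with no
    near target emit no WD sample; non-wear periods emit nothing.
    """
    rng = subject_rng(config.seed, subject_seed_index)
    if subject_id is None:
        subject_id = f"S{subject_seed_index:04d}"
    pref = rng.dirichlet(np.asarray(config.base_pref) * config.pref_concentration)

    wear = _wear_intervals(config, rng)
    seg_starts, seg_li, seg_wd = _state_timeline(config, pref, rng)
    horizon = config.days * 86400.0

    wd_lo, wd_hi = config.sensor.wd_range
    li_lo, li_hi = config.sensor.li_range
    has_target = np.array([s.wd_mean is not None for s in config.states])
    wd_mu = np.array([s.wd_mean if s.wd_mean is not None else np.nan for s in config.states])
    wd_sd = np.array([s.wd_sd if s.wd_sd is not None else np.nan for s in config.states])
    li_mu = np.array([s.logli_mean for s in config.states])
    li_sd = np.array([s.logli_sd for s in config.states])

    wd_t = _ticks_in_wear(config.wd_interval_s, wear, horizon)
    wd_state = seg_wd[np.searchsorted(seg_starts, wd_t, side="right") - 1]
    emit = (wd_state >= 0) & has_target[np.clip(wd_state, 0, None)]
    wd_t = wd_t[emit]
    ws = wd_state[emit]
    wd_vals = rng.normal(wd_mu[ws], wd_sd[ws])
    wd_vals = np.clip(wd_vals, wd_lo, wd_hi)
    wd_vals = np.round(wd_vals / config.wd_quantum_cm) * config.wd_quantum_cm

    li_t = _ticks_in_wear(config.li_interval_s, wear, horizon)
    li_state = seg_li[np.searchsorted(seg_starts, li_t, side="right") - 1]
    logli = rng.normal(li_mu[li_state], li_sd[li_state])
    li_vals = np.clip(np.round(10.0**logli), li_lo, li_hi)

    wd = BehaviorSeries(subject_id=subject_id, channel="WD", timestamps=wd_t, values=wd_vals)
    li = BehaviorSeries(subject_id=subject_id, channel="LI", timestamps=li_t, values=li_vals)
    return wd, li, pref


def simulate_cohort(
    n: int,
    config: SimConfig = SimConfig(),
    filter_spec: FilterSpec = FilterSpec(),
) -> SimulatedCohort:
    """Simulate ``n`` subjects and their refraction.

    Each subject's PoT grid is computed by the real preprocessing
    pipeline (validate, segment, filter, pair, bin) on the simulated
    streams; SER is then the baseline plus the occupancy-weighted truth
    effect plus Gaussian noise.
    """
    if n < 3:
        raise ValueError("simulate_cohort needs n >= 3")
    truth = config.resolved_truth_map()
    subjects = []
    for m in range(n):
        wd, li, pref = simulate_subject(config, m)
        joint = preprocess_subject(wd, li, filter_spec, config.sensor)
        pot = build_pot_grid(joint, config.grid_spec)
        exposure = float(np.sum(pot.grid * truth))
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=(int(config.seed), int(m), 7))
        )
        eps = noise_rng.normal(0.0, config.ser_noise_sd) if config.ser_noise_sd > 0 else 0.0
        subjects.append(
            SimulatedSubject(
                subject_id=wd.subject_id,
                wd=wd,
                li=li,
                ser=config.ser_baseline + exposure + float(eps),
                pot=pot,
                exposure=exposure,
                pref=pref,
            )
        )
    return SimulatedCohort(subjects=subjects, truth_map=truth, config=config)


def sample_random_grids(
    n_subjects: int,
    spec: GridSpec,
    rng: np.random.Generator,
    points_per_subject: int = 1500,
    n_clusters: int = 3,
) -> list[PoTGrid]:
    """Fast direct sampler of heterogeneous PoT grids (no streams).

    Each subject gets a random mixture of Gaussian activity clusters in
    (WD, log-LI) space; sampled points are binned and normalised. Used
    for calibration studies (e.g. null-distribution checks) where
    simulating full sensor streams would be wasteful.
    """
    from .behavior_space import bin_index

    grids = []
    for m in range(n_subjects):
        weights = rng.dirichlet(np.ones(n_clusters) * 2.0)
        mu_wd = rng.uniform(15.0, 55.0, n_clusters)
        mu_li = rng.uniform(0.5, 4.5, n_clusters)
        comp = rng.choice(n_clusters, size=points_per_subject, p=weights)
        wd = rng.normal(mu_wd[comp], 5.0)
        logli = rng.normal(mu_li[comp], 0.4)
        i, j = bin_index(wd, logli, spec)
        grid = np.zeros((spec.n_bins, spec.n_bins))
        np.add.at(grid, (i, j), 1.0)
        grid /= grid.sum()
        grids.append(
            PoTGrid(subject_id=f"G{m:04d}", grid=grid,
                    total_time_s=float(points_per_subject), spec=spec)
        )
    return grids


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Serialise a cohort in the ingest dialect: per-subject WD.csv /
    LI.csv, refraction.csv, truth_map.csv and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        sdir = outdir / s.subject_id
        sdir.mkdir(exist_ok=True)
        for series, fname in ((s.wd, "WD.csv"), (s.li, "LI.csv")):
            pd.DataFrame({"timestamp": series.timestamps, "value": series.values}).to_csv(
                sdir / fname, index=False
            )
    # SER is encoded as plain sphere with zero cylinder in both eyes
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort.subjects],
            "sphere_r": [round(s.ser, 4) for s in cohort.subjects],
            "cyl_r": 0.0,
            "sphere_l": [round(s.ser, 4) for s in cohort.subjects],
            "cyl_l": 0.0,
        }
    ).to_csv(outdir / "refraction.csv", index=False)
    np.savetxt(outdir / "truth_map.csv", cohort.truth_map, delimiter=",", fmt="%.10g")
    manifest = {
        "n_subjects": len(cohort.subjects),
        "seed": cohort.config.seed,
        "days": cohort.config.days,
        "ser_baseline": cohort.config.ser_baseline,
        "ser_noise_sd": cohort.config.ser_noise_sd,
        "states": [s.name for s in cohort.config.states],
        "grid_spec": cohort.config.grid_spec.to_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
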