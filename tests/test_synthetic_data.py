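import numpy as np
import pytest

from vbikit.behavior_space import GridSpec, bin_index, build_pot_grid
from vbikit.denoise import preprocess_subject
from vbikit.ingest import validate_series
from vbikit.synthetic_data import (
    ActivityState,
    SimConfig,
    _state_timeline,
    default_truth_map,
    sample_random_grids,
    simulate_cohort,
    simulate_subject,
    stationary_occupancy,
    subject_rng,
    write_cohort,
)


class TestDefaultTruthMap:
    def test_safe_distance_is_neutral(self):
        truth = default_truth_map()
        assert truth[bin_index(50.0, 2.0)] == 0.0

    def test_close_work_is_myopiagenic(self):
        truth = default_truth_map()
        assert truth[bin_index(30.0, 2.0)] < 0

    def test_dim_close_patch_is_protective(self):
        truth = default_truth_map()
        assert truth[bin_index(17.0, 0.5)] > 0

    def test_nonzero_count_matches_enumeration(self):
        spec = GridSpec()
        truth = default_truth_map(spec)
        wd = spec.wd_centers()
        ll = spec.logli_centers()
        n_risky = sum(
            1 for i in range(40) for j in range(40) if wd[i] < 40.0 and ll[j] < 3.8
        )
        assert np.count_nonzero(truth) == n_risky
        n_prot = sum(
            1 for i in range(40) for j in range(40) if wd[i] < 20.0 and ll[j] < 1.0
        )
        assert (truth > 0).sum() == n_prot


def one_hour_config(**kw):
    """A single-day config whose wear window is exactly one hour."""
    defaults = dict(days=1, wear_start_h=8.0, wear_end_h=9.0,
                    nonwear_gaps_per_day=0, seed=5)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateSubject:
    def test_device_sampling_rates_over_continuous_wear(self):
        """One hour of continuous wear yields 3600/5 = 720 distance ticks
        and 3600/120 = 30 illuminance samples; distance samples are only
        emitted while a near target is present."""
        config = one_hour_config()
        wd, li, _ = simulate_subject(config, 0)
        assert len(li) == 30
        assert len(wd) <= 720
        # ticks stay on the 5 s / 120 s device clocks
        assert np.all(np.mod(wd.timestamps, 5.0) == 0)
        assert np.all(np.mod(li.timestamps, 120.0) == 0)
        # a permanent near target (one unbounded bout) emits on every tick
        always_near = (ActivityState("read", 30.0, 3.0, 2.0, 0.3, 1e9),)
        c2 = one_hour_config(states=always_near, base_pref=(1.0,))
        wd2, li2, _ = simulate_subject(c2, 0)
        assert len(wd2) == 720
        assert len(li2) == 30

    def test_same_seed_identical_streams(self):
        config = SimConfig(days=2, seed=77)
        a_wd, a_li, a_pref = simulate_subject(config, 3)
        b_wd, b_li, b_pref = simulate_subject(config, 3)
        assert np.array_equal(a_wd.values, b_wd.values)
        assert np.array_equal(a_li.timestamps, b_li.timestamps)
        assert np.array_equal(a_pref, b_pref)

    def test_different_subjects_differ(self):
        config = SimConfig(days=1, seed=77)
        a = simulate_subject(config, 0)[0]
        b = simulate_subject(config, 1)[0]
        m = min(len(a), len(b))
        assert not np.array_equal(a.values[:m], b.values[:m])

    def test_streams_pass_validation_with_zero_flags(self):
        config = SimConfig(days=2, seed=9)
        wd, li, _ = simulate_subject(config, 1)
        _, wd_mask = validate_series(wd, config.sensor)
        _, li_mask = validate_series(li, config.sensor)
        assert not wd_mask.any() and not li_mask.any()
        assert np.all(li.values == np.round(li.values))  # integer lux
        q = np.mod(np.round(wd.values / 0.1), 1)  # 0.1 cm quantisation
        assert np.allclose(q, 0)

    def test_single_state_concentrates_occupancy(self):
        reading = (ActivityState("read", 25.0, 1.0, np.log10(300.0), 0.05, 1e9),)
        config = SimConfig(days=1, states=reading, base_pref=(1.0,), seed=4)
        wd, li, _ = simulate_subject(config, 0)
        joint = preprocess_subject(wd, li)
        grid = build_pot_grid(joint)
        i0, j0 = bin_index(25.0, np.log10(300.0))
        window = grid.grid[i0 - 2 : i0 + 3, j0 - 2 : j0 + 3]
        assert window.sum() > 0.9


class TestSimulateCohort:
    def test_zero_truth_zero_noise_gives_baseline(self):
        config = SimConfig(days=1, seed=2, truth_map=np.zeros((40, 40)),
                           ser_noise_sd=0.0)
        cohort = simulate_cohort(3, config)
        assert np.allclose(cohort.sers, config.ser_baseline)

    def test_cohort_reproducible(self):
        config = SimConfig(days=1, seed=123)
        a = simulate_cohort(4, config)
        b = simulate_cohort(4, config)
        assert np.array_equal(a.sers, b.sers)
        for sa, sb in zip(a.subjects, b.subjects):
            assert np.array_equal(sa.pot.grid, sb.pot.grid)

    def test_ser_is_baseline_plus_exposure_plus_noise(self):
        config = SimConfig(days=1, seed=6)
        cohort = simulate_cohort(3, config)
        for s in cohort.subjects:
            manual = float(np.sum(s.pot.grid * cohort.truth_map))
            assert s.exposure == pytest.approx(manual, abs=1e-12)
        noiseless = simulate_cohort(3, SimConfig(days=1, seed=6, ser_noise_sd=0.0))
        for s, s0 in zip(cohort.subjects, noiseless.subjects):
            assert s0.ser == pytest.approx(config.ser_baseline + s0.exposure)
            assert s.ser != s0.ser  # noise actually applied

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError):
            simulate_cohort(2, SimConfig(days=1, seed=1))


def test_stationary_occupancy_long_run():
    """Empirical light-context occupancy over 28-day horizons approaches
    the renewal process's stationary distribution: per-subject deviations
    stay within sampling noise and average out across subjects."""
    config = SimConfig(days=28, seed=31)
    devs = []
    for m in range(6):
        rng = subject_rng(config.seed, m)
        pref = rng.dirichlet(np.asarray(config.base_pref) * config.pref_concentration)
        starts, li_state, _ = _state_timeline(config, pref, rng)
        ends = np.append(starts[1:], config.days * 86400.0)
        durations = np.minimum(ends, config.days * 86400.0) - starts
        emp = np.zeros(len(config.states))
        np.add.at(emp, li_state, durations)
        emp /= emp.sum()
        dev = emp - stationary_occupancy(pref, config.states)
        assert np.max(np.abs(dev)) < 0.06  # ~a thousand renewals of noise
        devs.append(dev)
    assert np.max(np.abs(np.mean(devs, axis=0))) < 0.02  # no systematic bias


def test_sample_random_grids_are_valid(rng):
    spec = GridSpec(n_bins=20)
    grids = sample_random_grids(10, spec, rng)
    for g in grids:
        assert abs(g.grid.sum() - 1.0) <= 1e-9
        assert np.all(g.grid >= 0)


def test_write_cohort_layout_and_determinism(tmp_path):
    config = SimConfig(days=1, seed=8)
    cohort = simulate_cohort(3, config)
    out1 = tmp_path / "a"
    out2 = tmp_path / "b"
    write_cohort(cohort, out1)
    write_cohort(simulate_cohort(3, config), out2)
    for rel in ["refraction.csv", "truth_map.csv", "manifest.json",
                "S0000/WD.csv", "S0000/LI.csv", "S0002/LI.csv"]:
        assert (out1 / rel).exists()
        assert (out1 / rel).read_bytes() == (out2 / rel).read_bytes()
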