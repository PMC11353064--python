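"""Schedule builder and synthetic listener: balance, determinism, recovery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from echofit import (
    DesignConfig,
    PHASE_CONDITIONS,
    PopulationParams,
    SimulationConfig,
    SubjectParams,
    build_schedule,
    draw_subject_params,
    hz_to_semitone,
    simulate_experiment,
    simulate_listener,
)
from echofit.measures import compute_phase_measures


class TestSchedule:
    @pytest.mark.parametrize("experiment, per_phase", [(1, 27), (2, 39)])
    def test_analyzed_trials_per_phase(self, experiment, per_phase):
        design = DesignConfig.for_experiment(experiment)
        sched = build_schedule(design, seed=0)
        analyzed = sched[~sched["is_practice"]]
        counts = analyzed.groupby("phase_rad").size()
        assert (counts == per_phase).all()
        assert design.analyzed_trials_per_phase == per_phase

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_every_block_balanced(self, seed):
        design = DesignConfig.for_experiment(1)
        sched = build_schedule(design, seed=seed)
        for block, grp in sched.groupby("block"):
            assert len(grp) == 15
            counts = grp.groupby("phase_rad").size()
            assert set(counts.index) == set(PHASE_CONDITIONS)
            assert (counts == design.trials_per_phase_per_block).all()

    def test_targets_drawn_from_grid(self):
        design = DesignConfig.for_experiment(1)
        sched = build_schedule(design, seed=3)
        grid = design.f0_grid
        assert np.all(np.isin(np.round(sched["target_f0_hz"], 9),
                              np.round(grid, 9)))

    def test_practice_flagged_first_block(self):
        sched = build_schedule(DesignConfig.for_experiment(2), seed=1)
        assert sched.loc[sched["block"] == 1, "is_practice"].all()
        assert not sched.loc[sched["block"] > 1, "is_practice"].any()

    def test_invalid_design(self):
        with pytest.raises(ValueError):
            DesignConfig(n_blocks=1, practice_blocks=1)


class TestSubjectParams:
    @pytest.mark.parametrize("kwargs", [
        {"gamma1": 0.4, "gamma0": 0.3},   # modulation deeper than baseline
        {"sigma0": 0.0},
        {"rho": 1.0},
    ])
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            SubjectParams(**kwargs)

    def test_high_kappa_concentrates_offsets_at_zero(self):
        pop = PopulationParams(kappa_phase=1e8)
        rng = np.random.default_rng(0)
        cs = [draw_subject_params(pop, rng).c_subject for _ in range(50)]
        dist = np.minimum(np.abs(cs), 2 * math.pi - np.abs(cs))
        assert np.max(dist) < 1e-3

    def test_zero_kappa_gives_uniform_offsets(self):
        pop = PopulationParams(kappa_phase=0.0)
        rng = np.random.default_rng(1)
        cs = np.array([draw_subject_params(pop, rng).c_subject
                       for _ in range(10_000)])
        rbar = abs(np.exp(1j * cs).mean())
        assert rbar < 0.03  # resultant of a uniform circular sample

    def test_zero_modulation_population(self):
        pop = PopulationParams(gamma1_mean=0.0, gamma1_sd=0.0)
        rng = np.random.default_rng(2)
        assert all(draw_subject_params(pop, rng).gamma1 == 0.0 for _ in range(20))


class TestListener:
    def test_identity_listener_matches_exactly(self):
        design = DesignConfig.for_experiment(1)
        sched = build_schedule(design, seed=0)
        params = SubjectParams(gamma0=0.0, gamma1=0.0, sigma0=1e-12, beta=0.0)
        done = simulate_listener(sched, params, np.random.default_rng(0), design)
        assert np.allclose(done["matched_f0_hz"], done["target_f0_hz"], rtol=1e-9)

    def test_pure_compression_gives_flat_3st_accuracy(self, noiseless_compression_table):
        # gamma0 = 0.25, no modulation, no noise -> slope 0.75 and a
        # 12 * 0.25 = 3-semitone accuracy error at every phase
        measures = compute_phase_measures(noiseless_compression_table)
        assert np.allclose(measures["slope"], 0.75, atol=1e-9)
        assert np.allclose(measures["accuracy_st"], 3.0, atol=1e-9)

    def test_accuracy_extremes_at_in_and_anti_phase(self):
        # strong cyclic modulation, no noise: error lowest at 0/2pi, highest at pi
        design = DesignConfig.for_experiment(1)
        pop = PopulationParams(gamma0_mean=0.3, gamma0_sd=0.0,
                               gamma1_mean=0.15, gamma1_sd=0.0,
                               sigma0_mean=1e-9, sigma0_sd=0.0,
                               beta_sd=0.0, kappa_phase=1e9)
        cfg = SimulationConfig(n_subjects=2, design=design, population=pop, seed=5)
        table, _ = simulate_experiment(cfg)
        prof = compute_phase_measures(table).groupby("phase_rad")["accuracy_st"].mean()
        assert prof.idxmax() == pytest.approx(math.pi)
        assert prof[0.0] == pytest.approx(prof[2 * math.pi], abs=1e-3)
        assert prof[0.0] == pytest.approx(12 * (0.3 - 0.15), abs=1e-3)
        assert prof[math.pi] == pytest.approx(12 * (0.3 + 0.15), abs=1e-3)

    def test_responses_clamped_to_pad_range(self):
        design = DesignConfig.for_experiment(1)
        sched = build_schedule(design, seed=0)
        params = SubjectParams(gamma0=0.0, gamma1=0.0, sigma0=12.0, beta=0.0)
        done = simulate_listener(sched, params, np.random.default_rng(3), design)
        assert done["matched_f0_hz"].between(220.0 - 1e-9, 880.0 + 1e-9).all()

    def test_clamping_rare_under_default_conditions(self):
        cfg = SimulationConfig(n_subjects=26, seed=11)
        table, _ = simulate_experiment(cfg)
        v = hz_to_semitone(table["matched_f0_hz"].to_numpy())
        at_edge = (np.isclose(v, -12.0) | np.isclose(v, 12.0)).mean()
        assert at_edge < 0.01


class TestExperiment:
    def test_row_counts(self):
        cfg = SimulationConfig(n_subjects=4, seed=0)
        table, _ = simulate_experiment(cfg)
        assert len(table) == 4 * 150
        assert (table["is_practice"] == 0).sum() == 4 * 135

    def test_same_seed_reproduces_exactly(self):
        cfg = SimulationConfig(n_subjects=3, seed=9)
        t1, g1 = simulate_experiment(cfg)
        t2, g2 = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert g1 == g2

    def test_different_seeds_differ(self):
        t1, _ = simulate_experiment(SimulationConfig(n_subjects=3, seed=1))
        t2, _ = simulate_experiment(SimulationConfig(n_subjects=3, seed=2))
        assert not t1["matched_f0_hz"].equals(t2["matched_f0_hz"])

    def test_ground_truth_records_all_subjects(self):
        cfg = SimulationConfig(n_subjects=5, seed=4)
        table, truth = simulate_experiment(cfg)
        assert set(truth["subjects"]) == set(table["subject_id"].unique())
        for p in truth["subjects"].values():
            assert 0.0 <= p["gamma1"] <= p["gamma0"]
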