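"""Synthetic study designs, subject sampling and measurement simulation."""

import numpy as np
import pytest

from facefd import (
    AnatomicalPriors,
    ConfigError,
    NoiseModel,
    build_dslr_design,
    build_smartphone_design,
    dslr_camera_specs,
    estimate_all,
    sample_subjects,
    simulate_measurements,
    smartphone_camera_specs,
)
from facefd.evaluation import error_metrics

PRIORS = AnatomicalPriors(30.7, 1.2)


class TestDslrDesign:
    def test_counts_per_body_and_total(self):
        rows = build_dslr_design(n_participants=1)
        assert len(rows) == 360  # three bodies
        per_body = {}
        for r in rows:
            per_body.setdefault(r.camera_name.split("|")[0], []).append(r)
        assert set(map(len, per_body.values())) == {120}

    def test_single_cell_design(self):
        config = {
            "bodies": [
                {
                    "name": "b",
                    "pixel_size_um": 6.0,
                    "sensor_mm": [36, 24],
                    "lenses": [{"label": "p", "type": "prime", "focal_length_mm": 50}],
                }
            ],
            "distances_m": [2],
        }
        rows = build_dslr_design(1, config=config, replicates=1)
        assert len(rows) == 2  # one station, frontal + profile
        rows = [r for r in rows if r.view == "frontal"]
        assert len(rows) == 1

    def test_deterministic_order(self):
        assert build_dslr_design(2) == build_dslr_design(2)

    def test_empty_camera_list_rejected(self):
        with pytest.raises(ConfigError):
            build_dslr_design(1, config={"bodies": [], "distances_m": [1]})


class TestSmartphoneDesign:
    def test_row_count_matches_hand_count(self):
        # 5 back cameras x 8 distances + 4 front cameras x 9 distances
        # = 76 stations, each with 2 views x 2 replicates
        rows = build_smartphone_design(1)
        assert len(rows) == (5 * 8 + 4 * 9) * 2 * 2 == 304

    def test_zero_participants_empty(self):
        assert build_smartphone_design(0) == []

    def test_dropout_removes_exactly_one_camera_block(self):
        full = build_smartphone_design(2)
        dropped = build_smartphone_design(2, dropouts=[(1, "Oppo A57|back")])
        removed = set(full) - set(dropped)
        assert len(full) - len(dropped) == 8 * 2 * 2  # back distances x views x reps
        assert {(r.participant_id, r.camera_name) for r in removed} == {(1, "Oppo A57|back")}

    def test_unknown_dropout_camera_rejected(self):
        with pytest.raises(ConfigError):
            build_smartphone_design(1, dropouts=[(1, "Nokia 3310|back")])


class TestSampleSubjects:
    def test_reproducible(self):
        a = sample_subjects(50, PRIORS, seed=7)
        b = sample_subjects(50, PRIORS, seed=7)
        assert a == b

    def test_zero_sd_pins_all_at_mean(self):
        subs = sample_subjects(20, AnatomicalPriors(30.7, 0.0), pcs_sd_mm=0.0, seed=1)
        assert all(s.pfl_true_mm == 30.7 and s.pcs_true_mm == 65.0 for s in subs)

    def test_sample_sd_converges(self):
        """At n = 1e5 the sample SD of fissure lengths sits within sampling error of 1.2."""
        subs = sample_subjects(100_000, PRIORS, seed=3)
        sd = np.std([s.pfl_true_mm for s in subs], ddof=1)
        assert 1.18 <= sd <= 1.22

    def test_all_positive(self):
        subs = sample_subjects(200, AnatomicalPriors(2.0, 1.5), pcs_mean_mm=2.0, pcs_sd_mm=1.5, seed=5)
        assert all(s.pfl_true_mm > 0 and s.pcs_true_mm > 0 for s in subs)


class TestSimulateMeasurements:
    def _small_design(self, replicates=1):
        config = {
            "bodies": [
                {
                    "name": "Canon EOS 6D",
                    "pixel_size_um": 6.55,
                    "sensor_mm": [35.8, 23.9],
                    "lenses": [
                        {"label": "prime_100", "type": "prime", "focal_length_mm": 100},
                        {"label": "zoom_min_24", "type": "zoom_min", "focal_length_mm": 24},
                    ],
                }
            ],
            "distances_m": [1, 10],
        }
        return build_dslr_design(1, config=config, replicates=replicates), dslr_camera_specs()

    def test_noise_free_identity_end_to_end(self):
        """Subjects at population means, no noise: every estimate equals ground truth."""
        design, cams = self._small_design(replicates=2)
        subs = sample_subjects(1, AnatomicalPriors(30.7, 0.0), pcs_sd_mm=0.0, seed=0)
        meas = simulate_measurements(design, subs, cams, NoiseModel(), seed=0)
        est = estimate_all(meas, cams, PRIORS)
        assert np.allclose(est["fd_est_mm"], est["fd_true_mm"], rtol=1e-12)

    def test_reproducible_given_seed(self):
        design, cams = self._small_design()
        subs = sample_subjects(1, PRIORS, seed=1)
        a = simulate_measurements(design, subs, cams, NoiseModel(0.5, True), seed=9)
        b = simulate_measurements(design, subs, cams, NoiseModel(0.5, True), seed=9)
        assert a == b

    def test_quantization_degrades_long_wide_angle_fd(self):
        """Whole-pixel rounding alone: far worse relative error at 10 m than 1 m for f=24."""
        design, cams = self._small_design()
        design = [r for r in design if r.lens_label == "zoom_min_24" and r.view == "frontal"]
        subs = sample_subjects(1, AnatomicalPriors(30.7, 0.0), pcs_sd_mm=0.0, seed=0)
        meas = simulate_measurements(design, subs, cams, NoiseModel(0.0, True), seed=0)
        assert all(float(m.pfl_px).is_integer() for m in meas)
        est = estimate_all(meas, cams, AnatomicalPriors(30.7, 0.0))
        rel_err = (est["fd_est_mm"] - est["fd_true_mm"]).abs() / est["fd_true_mm"]
        err_by_fd = dict(zip(est["fd_true_mm"], rel_err))
        assert err_by_fd[10000.0] > err_by_fd[1000.0]

    def test_jitter_matches_independent_monte_carlo_oracle(self, full_frame_cam):
        """Mean signed error under 0.5 px jitter agrees with a brute-force oracle."""
        from facefd import DesignRow

        cams = {"ff_100": full_frame_cam}
        design = [
            DesignRow(pid, "ff_100", "prime_100", 100.0, 3000.0, "frontal", 1)
            for pid in range(1, 1001)
        ]
        subs = sample_subjects(1000, AnatomicalPriors(30.7, 0.0), pcs_sd_mm=0.0, seed=0)
        meas = simulate_measurements(design, subs, cams, NoiseModel(0.5, False), seed=11)
        est = estimate_all(meas, cams, AnatomicalPriors(30.7, 0.0))
        mse = error_metrics(est["fd_est_mm"], est["fd_true_mm"]).mse_mm

        # independent oracle: direct Monte Carlo on fd * x / (x + eps)
        rng = np.random.default_rng(2024)
        fd, f, y, A = 3000.0, 100.0, 0.00655, 30.7
        x = f * A / (fd * y)
        sim = fd * x / (x + rng.normal(0.0, 0.5, size=400_000)) - fd
        se = sim.std() / np.sqrt(len(est))
        assert abs(mse - sim.mean()) < 4 * se

    def test_unresolvable_camera_rejected(self):
        design, cams = self._small_design()
        subs = sample_subjects(1, PRIORS, seed=0)
        with pytest.raises(ConfigError):
            simulate_measurements(design, subs, {}, NoiseModel(), seed=0)

    def test_unresolvable_participant_rejected(self):
        config_design, cams = self._small_design()
        design = build_dslr_design(3, config={
            "bodies": [{"name": "Canon EOS 6D", "pixel_size_um": 6.55, "sensor_mm": [35.8, 23.9],
                        "lenses": [{"label": "prime_100", "type": "prime", "focal_length_mm": 100}]}],
            "distances_m": [1],
        })
        subs = sample_subjects(1, PRIORS, seed=0)
        with pytest.raises(ConfigError):
            simulate_measurements(design, subs, cams, NoiseModel(), seed=0)


def test_fixture_camera_specs_complete():
    dslr = dslr_camera_specs()
    assert len(dslr) == 15  # 3 bodies x 5 lens configs
    assert dslr["Canon EOS 6D|prime_100"].pixel_size_mm == pytest.approx(0.00655)
    phones = smartphone_camera_specs()
    assert len(phones) == 9  # 5 back + 4 front cameras
    assert "iPhone XR|front" not in phones
    assert phones["Samsung Galaxy A31|back"].focal_length_mm == pytest.approx(4.60)
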