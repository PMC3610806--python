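import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endoqc import metrics
from endoqc.errors import InvalidArgumentError, ValidationError
from endoqc.optics import (
    DegradationRates,
    DustSpeck,
    EndoscopeState,
    FleetHistoryConfig,
    REFERENCE_SERIAL,
    Repair,
    age_endoscope,
    render_through_endoscope,
    repair_endoscope,
    simulate_fleet_history,
    simulate_transmission_measurement,
)
from endoqc.patterns import generate_line_pattern, generate_roi_pattern


def field_mask(shape):
    h, w = shape
    cy, cx = (h - 1) / 2, (w - 1) / 2
    yy, xx = np.ogrid[:h, :w]
    return np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) <= min(h, w) / 2


class TestRender:
    def test_pristine_is_masked_identity(self, pristine_state):
        pattern = generate_line_pattern(0, 128)
        out = render_through_endoscope(pattern, pristine_state)
        expected = np.where(field_mask(pattern.shape), pattern.pixels, 0)
        assert np.array_equal(out, expected)

    def test_full_glare_is_uniform_inside_mask(self):
        state = EndoscopeState(serial="S", type_id="T", veiling_glare=1.0)
        pattern = generate_line_pattern(0, 128)
        out = render_through_endoscope(pattern, state)
        inside = out[field_mask(pattern.shape)]
        assert len(np.unique(inside)) == 1

    def test_contrast_nonincreasing_with_blur(self):
        roi = metrics.ROISpec(center=(63.5, 63.5), radius=25.0)
        pattern = generate_line_pattern(4, 128)
        contrasts = []
        for sigma in (0.0, 1.0, 2.0, 4.0):
            state = EndoscopeState(serial="S", type_id="T", blur_sigma=sigma)
            cap = render_through_endoscope(pattern, state)
            contrasts.append(metrics.compute_contrast(cap, roi))
        assert contrasts == sorted(contrasts, reverse=True)

    def test_vignetting_zero_equals_no_stage(self, pristine_state):
        pattern = generate_roi_pattern(96)
        a = render_through_endoscope(pattern, pristine_state)
        b = render_through_endoscope(
            pattern, EndoscopeState(serial="S", type_id="T", vignetting=0.0)
        )
        assert np.array_equal(a, b)

    def test_vignetting_darkens_edges(self):
        uniform = np.full((96, 96), 200, dtype=np.uint8)
        state = EndoscopeState(serial="S", type_id="T", vignetting=0.5)
        out = render_through_endoscope(uniform, state)
        center = out[48, 48]
        edge = out[48, 2]
        assert edge < center

    def test_dust_darkens_only_its_disc(self):
        uniform = np.full((96, 96), 200, dtype=np.uint8)
        speck = DustSpeck(center=(48.0, 48.0), radius_px=5.0, opacity=0.5)
        state = EndoscopeState(serial="S", type_id="T", dust=(speck,))
        out = render_through_endoscope(uniform, state)
        assert out[48, 48] == 100
        assert out[48, 60] == 200

    def test_noise_is_seeded(self, pristine_state):
        pattern = generate_line_pattern(0, 128)
        a = render_through_endoscope(pattern, pristine_state, seed=5, noise_sd=2.0)
        b = render_through_endoscope(pattern, pristine_state, seed=5, noise_sd=2.0)
        c = render_through_endoscope(pattern, pristine_state, seed=6, noise_sd=2.0)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_output_range(self, pristine_state):
        pattern = generate_line_pattern(0, 128)
        out = render_through_endoscope(pattern, pristine_state, seed=1, noise_sd=50.0)
        assert out.dtype == np.uint8

    def test_sensor_shape_mismatch(self, pristine_state):
        pattern = generate_line_pattern(0, 128)
        with pytest.raises(InvalidArgumentError):
            render_through_endoscope(pattern, pristine_state, sensor_shape=(64, 64))


class TestTransmissionSimulation:
    def test_full_transmission_zero_noise(self):
        state = EndoscopeState(serial="S", type_id="T", fibre_transmission=1.0)
        reading = simulate_transmission_measurement(state)
        assert reading.endoscope_signal == reading.calibration_signal

    def test_half_transmission(self):
        state = EndoscopeState(serial="S", type_id="T", fibre_transmission=0.5)
        reading = simulate_transmission_measurement(state)
        assert reading.endoscope_signal == pytest.approx(
            0.5 * reading.calibration_signal
        )

    def test_monte_carlo_mean(self):
        # 1000 seeded draws at 1% relative noise recover the parameter
        state = EndoscopeState(serial="S", type_id="T", fibre_transmission=0.7)
        ratios = [
            (r := simulate_transmission_measurement(state, seed=i, noise_sd=0.01))
            .endoscope_signal
            / r.calibration_signal
            for i in range(1000)
        ]
        assert np.mean(ratios) == pytest.approx(0.700, abs=0.001)

    def test_signal_floored_at_zero(self):
        state = EndoscopeState(serial="S", type_id="T", fibre_transmission=0.01)
        for seed in range(50):
            reading = simulate_transmission_measurement(state, seed=seed, noise_sd=2.0)
            assert reading.endoscope_signal >= 0


class TestAging:
    def test_zero_cycles_identity(self, pristine_state):
        assert age_endoscope(pristine_state, 0) == pristine_state

    def test_fibre_decay_closed_form(self):
        state = EndoscopeState(
            serial="S", type_id="T", fibre_transmission=0.8,
            rates=DegradationRates(fibre_decay=0.01),
        )
        aged = age_endoscope(state, 10)
        assert aged.fibre_transmission == pytest.approx(0.8 * 0.99**10)

    def test_input_not_mutated(self, pristine_state):
        state = EndoscopeState(
            serial="S", type_id="T", fibre_transmission=0.8,
            rates=DegradationRates(fibre_decay=0.01, blur_growth=0.1),
        )
        age_endoscope(state, 5)
        assert state.fibre_transmission == 0.8
        assert state.blur_sigma == 0.0

    def test_negative_cycles_rejected(self, pristine_state):
        with pytest.raises(InvalidArgumentError):
            age_endoscope(pristine_state, -1)

    @given(
        transmission=st.floats(0.1, 1.0),
        blur=st.floats(0, 3),
        glare=st.floats(0, 0.5),
        decay=st.floats(0, 0.05),
        blur_growth=st.floats(0, 0.1),
        glare_growth=st.floats(0, 0.05),
        a=st.integers(0, 30),
        b=st.integers(0, 30),
    )
    @settings(max_examples=60, deadline=None)
    def test_aging_composes(
        self, transmission, blur, glare, decay, blur_growth, glare_growth, a, b
    ):
        state = EndoscopeState(
            serial="S", type_id="T",
            fibre_transmission=transmission, blur_sigma=blur, veiling_glare=glare,
            rates=DegradationRates(
                fibre_decay=decay, blur_growth=blur_growth, glare_growth=glare_growth
            ),
        )
        stepped = age_endoscope(age_endoscope(state, a), b)
        direct = age_endoscope(state, a + b)
        assert stepped.fibre_transmission == pytest.approx(
            direct.fibre_transmission, rel=1e-12
        )
        assert stepped.blur_sigma == pytest.approx(direct.blur_sigma, rel=1e-12)
        assert stepped.veiling_glare == pytest.approx(direct.veiling_glare, rel=1e-12)


class TestRepair:
    def test_clean_dust(self):
        dust = tuple(
            DustSpeck(center=(float(i), float(i)), radius_px=2.0, opacity=0.3)
            for i in range(3)
        )
        state = EndoscopeState(serial="S", type_id="T", dust=dust, blur_sigma=1.0)
        repaired = repair_endoscope(state, {Repair.CLEAN_DUST})
        assert repaired.dust == ()
        assert repaired.blur_sigma == state.blur_sigma
        assert repaired.fibre_transmission == state.fibre_transmission

    def test_fix_moisture(self):
        state = EndoscopeState(serial="S", type_id="T", moisture=True)
        assert repair_endoscope(state, {Repair.FIX_MOISTURE}).moisture is False

    def test_rod_lens_restore_mapping(self):
        # lower-is-better parameters come back to factory / fraction
        state = EndoscopeState(
            serial="S", type_id="T", blur_sigma=2.0, factory_blur_sigma=0.5
        )
        repaired = repair_endoscope(
            state, {Repair.REPLACE_ROD_LENS}, restore_fraction=0.95
        )
        assert repaired.blur_sigma == pytest.approx(0.5 / 0.95)

    def test_fibre_restore_mapping(self):
        state = EndoscopeState(
            serial="S", type_id="T",
            fibre_transmission=0.3, factory_fibre_transmission=0.9,
        )
        repaired = repair_endoscope(
            state, {Repair.REPLACE_FIBRES}, restore_fraction=0.95
        )
        assert repaired.fibre_transmission == pytest.approx(0.9 * 0.95)

    def test_seeded_restore_within_range(self):
        state = EndoscopeState(
            serial="S", type_id="T",
            fibre_transmission=0.3, factory_fibre_transmission=0.9,
        )
        for seed in range(20):
            repaired = repair_endoscope(state, {Repair.REPLACE_FIBRES}, seed=seed)
            assert 0.9 * 0.9 <= repaired.fibre_transmission <= 0.9

    def test_empty_repair_set_rejected(self, pristine_state):
        with pytest.raises(InvalidArgumentError):
            repair_endoscope(pristine_state, set())


class TestStateValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fibre_transmission": 1.5},
            {"fibre_transmission": -0.1},
            {"veiling_glare": 2.0},
            {"vignetting": -1.0},
            {"blur_sigma": -0.5},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            EndoscopeState(serial="S", type_id="T", **kwargs)

    def test_json_roundtrip(self):
        state = EndoscopeState(
            serial="S", type_id="T", blur_sigma=1.2, veiling_glare=0.1,
            dust=(DustSpeck(center=(3.0, 4.0), radius_px=2.0, opacity=0.5),),
            fibre_transmission=0.8, moisture=True,
            rates=DegradationRates(fibre_decay=0.01),
        )
        assert EndoscopeState.from_json_dict(state.to_json_dict()) == state


@pytest.fixture(scope="module")
def small_history():
    cfg = FleetHistoryConfig(
        n_types=1, endoscopes_per_type=3, n_sessions=12, image_size=128, seed=7
    )
    return cfg, simulate_fleet_history(cfg)


class TestFleetHistory:
    def test_deterministic(self, small_history):
        cfg, history = small_history
        again = simulate_fleet_history(cfg)
        assert [r.to_row() for r in again.records] == [
            r.to_row() for r in history.records
        ]
        assert again.states == history.states

    def test_reference_state_constant(self, small_history):
        _, history = small_history
        series = history.ground_truth_series(REFERENCE_SERIAL, "fibre_transmission")
        assert len(set(series)) == 1
        assert len(series) == 12

    def test_some_endoscope_degrades(self, small_history):
        _, history = small_history
        degraded = False
        for serial in {r.serial for r in history.records} - {REFERENCE_SERIAL}:
            series = history.ground_truth_series(serial, "fibre_transmission")
            if all(b < a for a, b in zip(series, series[1:])):
                degraded = True
        assert degraded

    def test_record_counts(self, small_history):
        cfg, history = small_history
        expected = cfg.n_sessions * (cfg.n_types * cfg.endoscopes_per_type + 1)
        assert len(history.records) == expected

    def test_csv_exports(self, small_history, tmp_path):
        _, history = small_history
        n = history.export_records_csv(tmp_path / "records.csv")
        assert n == len(history.records)
        m = history.export_ground_truth_csv(tmp_path / "truth.csv")
        assert m == len(history.states)
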