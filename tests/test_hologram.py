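import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holofoci import (
    DegenerateFieldError,
    EmptyInputError,
    EnvelopeModel,
    InvalidParameterError,
    PhaseMap,
    SpotTarget,
    ZernikeSpec,
    compute_amplitude_weights,
    extract_phase,
    gen_hologram,
    park_spots,
    quantize_phase,
    superpose_field,
    with_phase_diversity,
)

TWO_PI = 2 * math.pi


class TestSpotTarget:
    def test_defaults(self):
        s = SpotTarget(1.0, 2.0)
        assert (s.z, s.weight, s.phase, s.vortex_charge, s.active) == (0.0, 1.0, 0.0, 0, True)

    @pytest.mark.parametrize(
        "kwargs",
        [{"weight": -0.1}, {"x": float("nan")}, {"z": float("inf")}, {"vortex_charge": 0.5}],
    )
    def test_validation(self, kwargs):
        base = {"x": 0.0, "y": 0.0}
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            SpotTarget(**base)


class TestSuperposeField:
    def test_centered_spot_gives_constant_field(self, small_config):
        field = superpose_field([SpotTarget(0, 0, 0)], small_config)
        assert np.allclose(field, field[0, 0])
        phase = extract_phase(field)
        assert np.allclose(phase.values, phase.values[0, 0])

    def test_lateral_spot_gives_linear_ramp(self, small_config):
        x1 = 4.0
        field = superpose_field([SpotTarget(x1, 0, 0)], small_config)
        phase = np.angle(field)
        # slope along u: 2 pi alpha x1 du per column
        du = 2.0 / small_config.slm_pixels
        expected_step = TWO_PI * small_config.scale_x * x1 * du
        steps = np.angle(np.exp(1j * np.diff(phase, axis=1)))
        assert np.allclose(steps, np.angle(np.exp(1j * expected_step)), atol=1e-9)

    def test_two_symmetric_spots_make_binary_phase(self, small_config):
        # arg(2 A cos(...)) takes only the values 0 and pi
        field = superpose_field(
            [SpotTarget(6.0, 0, 0), SpotTarget(-6.0, 0, 0)], small_config
        )
        phase = extract_phase(field).values
        dist_to_binary = np.minimum.reduce(
            [np.abs(phase), np.abs(phase - math.pi), np.abs(phase - TWO_PI)]
        )
        assert dist_to_binary.max() < 1e-6

    def test_superposition_identity(self, small_config):
        spots = [
            SpotTarget(3.0, -2.0, 1.0, weight=0.8, phase=0.4),
            SpotTarget(-5.0, 4.0, -2.0, weight=1.2, phase=1.9),
            SpotTarget(0.0, 7.0, 0.0, vortex_charge=1),
        ]
        total = superpose_field(spots, small_config)
        parts = sum(superpose_field([s], small_config) for s in spots)
        assert np.allclose(total, parts, atol=1e-12)

    def test_conjugate_spot_symmetry(self, small_config):
        spots = [SpotTarget(3.0, -2.0, 1.5), SpotTarget(-1.0, 4.0, -0.5)]
        neg = [SpotTarget(-s.x, -s.y, -s.z) for s in spots]
        f = superpose_field(spots, small_config)
        g = superpose_field(neg, small_config)
        assert np.allclose(g, np.conj(f), atol=1e-12)

    def test_inactive_and_zero_weight_excluded(self, small_config):
        keep = SpotTarget(2.0, 0, 0)
        spots = [
            keep,
            SpotTarget(5.0, 5.0, 0, active=False),
            SpotTarget(-3.0, 1.0, 0, weight=0.0),
        ]
        assert np.allclose(
            superpose_field(spots, small_config), superpose_field([keep], small_config)
        )

    def test_empty_active_list_rejected(self, small_config):
        with pytest.raises(EmptyInputError):
            superpose_field([SpotTarget(0, 0, active=False)], small_config)

    def test_per_spot_zernike_sequence(self, small_config):
        spec = ZernikeSpec([(2, -2, 0.8)])
        spots = [SpotTarget(2.0, 0, 0), SpotTarget(-2.0, 0, 0)]
        mixed = superpose_field(spots, small_config, [spec, None])
        by_hand = superpose_field([spots[0]], small_config, spec) + superpose_field(
            [spots[1]], small_config
        )
        assert np.allclose(mixed, by_hand, atol=1e-12)
        with pytest.raises(InvalidParameterError):
            superpose_field(spots, small_config, [spec])


class TestExtractPhase:
    def test_constant_field(self):
        field = np.full((8, 8), np.exp(1j * 1.234))
        assert np.allclose(extract_phase(field).values, 1.234)

    def test_negative_real_field_gives_pi(self):
        assert np.allclose(extract_phase(-np.ones((4, 4))).values, math.pi)

    def test_conjugation_negates_phase_mod_2pi(self):
        rng = np.random.default_rng(0)
        field = np.exp(1j * rng.uniform(0.1, TWO_PI - 0.1, (16, 16)))
        a = extract_phase(field).values
        b = extract_phase(np.conj(field)).values
        assert np.allclose(np.mod(a + b, TWO_PI), 0.0, atol=1e-9) or np.allclose(
            np.mod(a + b, TWO_PI), TWO_PI, atol=1e-9
        )

    def test_zero_magnitude_points_get_phase_zero(self):
        field = np.ones((4, 4), complex)
        field[1, 1] = 0
        assert extract_phase(field).values[1, 1] == 0.0

    def test_all_zero_field_rejected(self):
        with pytest.raises(DegenerateFieldError):
            extract_phase(np.zeros((4, 4), complex))


class TestQuantizePhase:
    @pytest.mark.parametrize(
        "phase,level",
        [(0.0, 0), (math.pi, 128), (TWO_PI * 255.6 / 256, 0)],  # wrap-around case
    )
    def test_level_mapping(self, phase, level):
        pm = PhaseMap(np.full((2, 2), phase))
        assert quantize_phase(pm).levels[0, 0] == level

    @given(st.floats(0, TWO_PI, exclude_max=True))
    @settings(derandomize=True, max_examples=200)
    def test_round_trip_error_bounded(self, phase):
        pm = PhaseMap(np.full((1, 1), phase))
        back = quantize_phase(pm).dequantize().values[0, 0]
        err = abs(math.remainder(back - phase, TWO_PI))
        assert err <= math.pi / 256 + 1e-12


class TestAmplitudeWeights:
    def setup_method(self):
        self.env = EnvelopeModel(dx_max=112.5, axial_sigma=50.0, max_gain=4.0)

    def test_origin_spot_gain_one_then_renormalized(self):
        spots = [SpotTarget(0, 0, 0)]
        out = compute_amplitude_weights(spots, self.env)
        assert out[0].weight == pytest.approx(1.0)

    def test_nyquist_gain_and_renormalization(self):
        spots = [SpotTarget(0, 0, 0), SpotTarget(112.5, 0, 0)]
        out = compute_amplitude_weights(spots, self.env)
        # outer spot got gain pi/2 = 1.571..., then weights scaled so max is 1
        assert max(s.weight for s in out) == pytest.approx(1.0)
        assert out[0].weight == pytest.approx(1.0 / (math.pi / 2))
        assert out[1].weight == pytest.approx(1.0)

    def test_cap_engages(self):
        spots = [SpotTarget(220.0, 220.0, 150.0)]
        out = compute_amplitude_weights(spots, self.env)
        # single spot, gain capped at max_gain then renormalized to 1
        assert out[0].weight == pytest.approx(1.0)
        gain = self.env.gain(220.0, 220.0, 150.0)
        assert gain == 4.0

    def test_flattens_delivered_intensity(self):
        spots = [SpotTarget(0, 0, 0), SpotTarget(90.0, 0, 0), SpotTarget(0, 0, 30.0)]
        out = compute_amplitude_weights(spots, self.env)
        delivered = [s.weight**2 * self.env.efficiency(s.x, s.y, s.z) for s in out]
        assert max(delivered) / min(delivered) == pytest.approx(1.0, rel=1e-9)


class TestParkSpots:
    def test_all_active_is_identity(self, default_config):
        spots = [SpotTarget(1, 2, 3), SpotTarget(-4, 5, 0)]
        assert park_spots(spots, 2, default_config) == spots

    def test_parked_positions_outside_window(self, default_config):
        spots = [SpotTarget(float(i), 0, 0) for i in range(6)]
        out = park_spots(spots, 2, default_config)
        hw = default_config.fov_aperture_halfwidth
        assert out[:2] == spots[:2]
        for s in out[2:]:
            assert max(abs(s.x), abs(s.y)) > hw
            assert abs(s.x) < default_config.dx_max and abs(s.y) < default_config.dx_max
            assert s.active

    def test_parked_positions_distinct(self, default_config):
        out = park_spots([SpotTarget(0, 0, 0)] * 8, 1, default_config)
        coords = {(round(s.x, 6), round(s.y, 6)) for s in out[1:]}
        assert len(coords) == 7

    @pytest.mark.parametrize("n_active", [0, 5])
    def test_n_active_out_of_range(self, default_config, n_active):
        with pytest.raises(InvalidParameterError):
            park_spots([SpotTarget(0, 0, 0)] * 4, n_active, default_config)


class TestPhaseDiversity:
    def test_offsets_are_quadratic_and_first_is_zero(self):
        spots = [SpotTarget(float(i), 0, 0) for i in range(4)]
        out = with_phase_diversity(spots)
        assert out[0].phase == 0.0
        c = out[1].phase / math.pi
        for i, s in enumerate(out):
            assert s.phase == pytest.approx((math.pi * c * i**2) % TWO_PI)

    def test_positions_and_weights_untouched(self):
        spots = [SpotTarget(1.0, 2.0, 3.0, weight=0.5)]
        out = with_phase_diversity(spots)
        assert (out[0].x, out[0].y, out[0].z, out[0].weight) == (1.0, 2.0, 3.0, 0.5)


class TestGenHologram:
    def test_single_centered_spot_is_flat(self, small_config):
        holo = gen_hologram([SpotTarget(0, 0, 0)], small_config)
        assert np.all(holo.levels == holo.levels[0, 0])

    def test_deterministic(self, small_config):
        spots = [SpotTarget(3, 1, 0), SpotTarget(-2, 4, 2)]
        a = gen_hologram(spots, small_config, weighting=True)
        b = gen_hologram(spots, small_config, weighting=True)
        assert np.array_equal(a.levels, b.levels)
        assert a.provenance == b.provenance

    def test_shifted_spots_add_linear_ramp(self, small_config):
        spots = [SpotTarget(2.0, -1.0, 0), SpotTarget(-3.0, 4.0, 0)]
        dx = 5.0
        shifted = [SpotTarget(s.x + dx, s.y, s.z) for s in spots]
        a = gen_hologram(spots, small_config).dequantize().values
        b = gen_hologram(shifted, small_config).dequantize().values
        u, _ = small_config.pupil_coords()
        ramp = TWO_PI * small_config.scale_x * u * dx
        resid = np.angle(np.exp(1j * (b - a - ramp)))
        # difference equals the ramp up to two quantization steps
        assert np.abs(resid).max() <= 2 * math.pi / 256 + 1e-9

    def test_explicit_phases_suppress_auto_diversity(self, small_config):
        spots = [SpotTarget(3, 0, 0, phase=0.5), SpotTarget(-3, 0, 0, phase=1.0)]
        a = gen_hologram(spots, small_config)
        b = quantize_phase(extract_phase(superpose_field(spots, small_config)))
        assert np.array_equal(a.levels, b.levels)
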