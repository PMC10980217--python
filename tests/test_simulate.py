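"""Device simulator: ideal kinematics, device model, determinism."""

import numpy as np
import pytest

from shakerval import (
    DeviceSpec,
    MountingOrientation,
    brand_preset,
    build_validity_protocol,
    build_reliability_sequence,
    compute_enmo,
    ideal_enmo_stats,
    ideal_plate_acceleration,
    reference_acceleration_mg,
    simulate_device_stream,
)
from shakerval.pipeline import aggregate_to_seconds

from conftest import noiseless_spec


class TestIdealPlateAcceleration:
    def test_rest_reads_pure_gravity(self, validity_protocol, cfg):
        v = ideal_plate_acceleration(5.0, validity_protocol, cfg)
        assert np.allclose(v, [0.0, 0.0, 1.0])

    def test_oscillation_horizontal_magnitude(self, validity_protocol, cfg):
        t = np.linspace(20.0, 130.0, 50)  # inside the 3.2 Hz segment
        v = ideal_plate_acceleration(t, validity_protocol, cfg)
        mag = np.hypot(v[:, 0], v[:, 1])
        expected = reference_acceleration_mg(3.2, cfg) / 1000.0
        assert np.allclose(mag, expected)
        assert np.allclose(v[:, 2], 1.0)

    def test_phase_advances_full_turn_per_cycle(self, validity_protocol, cfg):
        f = 3.2
        t0 = 20.0
        v0 = ideal_plate_acceleration(t0, validity_protocol, cfg)
        v1 = ideal_plate_acceleration(t0 + 1.0 / f, validity_protocol, cfg)
        assert np.allclose(v0, v1, atol=1e-9)

    def test_time_outside_protocol_rejected(self, validity_protocol, cfg):
        with pytest.raises(ValueError):
            ideal_plate_acceleration(-1.0, validity_protocol, cfg)
        with pytest.raises(ValueError):
            ideal_plate_acceleration(870.0, validity_protocol, cfg)


class TestIdealEnmoStats:
    def test_perpendicular_mounting_closed_form(self, cfg):
        mount = MountingOrientation.gravity_perpendicular()
        mean, rms = ideal_enmo_stats(3.2, mount, cfg)
        a = reference_acceleration_mg(3.2, cfg) / 1000.0
        expected = (np.sqrt(1 + a * a) - 1) * 1000.0
        assert mean == pytest.approx(expected)
        assert rms == pytest.approx(expected)

    def test_zero_frequency(self, cfg):
        assert ideal_enmo_stats(0.0, config=cfg) == (0.0, 0.0)

    def test_small_amplitude_expansion_in_plane(self):
        # for gravity in the orbit plane, mean ENMO ~ a^2/4 for small a
        from shakerval.shaker import ShakerConfig

        # pick a frequency whose amplitude is 0.01 g by scaling gravity
        a = 0.01
        cfg = ShakerConfig()
        f = np.sqrt(a * 1000.0 / reference_acceleration_mg(1.0, cfg))
        mean, _ = ideal_enmo_stats(f, MountingOrientation.gravity_in_plane(), cfg)
        assert mean == pytest.approx(a * a / 4 * 1000.0, rel=0.01)

    def test_rms_dominates_mean_in_plane(self, cfg):
        mean, rms = ideal_enmo_stats(3.2, MountingOrientation.gravity_in_plane(), cfg)
        assert rms > abs(mean)
        a = reference_acceleration_mg(3.2, cfg) / 1000.0
        assert rms == pytest.approx(a / np.sqrt(2) * 1000.0, rel=0.02)


class TestMounting:
    def test_rotation_must_be_orthonormal(self):
        with pytest.raises(ValueError):
            MountingOrientation(np.ones((3, 3)))

    def test_in_plane_fraction(self):
        assert MountingOrientation.gravity_perpendicular().in_plane_fraction == 0.0
        assert MountingOrientation.gravity_in_plane().in_plane_fraction == pytest.approx(1.0)


class TestDeviceStream:
    def test_seed_determinism(self, validity_protocol, cfg):
        spec = brand_preset("garmin", noise_sd_g=0.01, dropout_rate=0.02)
        s1 = simulate_device_stream(validity_protocol, spec, cfg, seed=7)
        s2 = simulate_device_stream(validity_protocol, spec, cfg, seed=7)
        assert np.array_equal(s1.t_s, s2.t_s)
        assert np.array_equal(s1.xyz, s2.xyz)
        s3 = simulate_device_stream(validity_protocol, spec, cfg, seed=8)
        assert not np.array_equal(s1.xyz, s3.xyz)

    def test_noiseless_rest_reads_unit_gravity(self, cfg):
        from shakerval import ProtocolSegment, TrialProtocol

        p = TrialProtocol(segments=(ProtocolSegment("rest", 0.0, 0.0, 10.0),))
        stream = simulate_device_stream(p, noiseless_spec(), cfg, seed=0)
        assert np.allclose(stream.xyz, [0.0, 0.0, 1.0])

    def test_clipping_bounds_every_component(self, validity_protocol, cfg):
        spec = DeviceSpec(
            device_id="clip", sampling_hz=50, dynamic_range_g=1.0,
            noise_sd_g=0.3, bias_g=(0.5, 0.0, 0.0),
        )
        stream = simulate_device_stream(validity_protocol, spec, cfg, seed=3)
        assert np.all(np.abs(stream.xyz) <= 1.0)
        assert np.any(np.abs(stream.xyz) == 1.0)  # the clip is exercised

    def test_fault_mode_gives_all_negative_enmo(self, validity_protocol, cfg):
        spec = noiseless_spec(fault_mode="all_negative_enmo")
        stream = simulate_device_stream(validity_protocol, spec, cfg, seed=0)
        assert np.all(compute_enmo(stream) < 0.0)

    def test_dropout_removes_whole_seconds(self, cfg):
        p = build_reliability_sequence(0.6, 1)
        spec = noiseless_spec(sampling_hz=50.0, dropout_rate=0.3)
        stream = simulate_device_stream(p, spec, cfg, seed=11)
        counts = np.bincount(np.floor(stream.t_s).astype(int), minlength=150)
        assert set(counts) <= {0, 50}  # seconds are either intact or gone
        assert (counts == 0).sum() > 0
        assert stream.duration_s == p.duration_s

    def test_rms_at_least_abs_mean_per_second(self, validity_protocol, cfg):
        spec = brand_preset("fitbit", device_id="f1", noise_sd_g=0.02)
        stream = simulate_device_stream(validity_protocol, spec, cfg, seed=5)
        enmo = compute_enmo(stream)
        per_sec = aggregate_to_seconds(stream.t_s, enmo, stream.sampling_hz)
        assert np.all(
            per_sec["enmo_rms_mg"] >= np.abs(per_sec["enmo_mean_mg"]) - 1e-9
        )


class TestBrandPresets:
    @pytest.mark.parametrize(
        "brand,hz,rng_g",
        [("actigraph", 100, 8), ("apple", 100, 8), ("garmin", 25, 8), ("fitbit", 50, 4)],
    )
    def test_preset_values(self, brand, hz, rng_g):
        spec = brand_preset(brand)
        assert spec.sampling_hz == hz
        assert spec.dynamic_range_g == rng_g
        assert spec.brand == brand

    def test_unknown_brand_rejected(self):
        with pytest.raises(ValueError, match="unknown brand"):
            brand_preset("polar")

    def test_overrides(self):
        spec = brand_preset("actigraph", device_id="a7", noise_sd_g=0.0)
        assert spec.device_id == "a7" and spec.noise_sd_g == 0.0
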