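"""Synthetic raw triaxial accelerometer streams from devices on an orbital shaker.

The simulator generates the specific force an ideal accelerometer reports
while clamped to the shaker plate: a rotating centripetal component of
amplitude ``a`` (in g) in the orbit plane plus the constant 1 g gravity
reaction, then applies a device model — mounting orientation, per-axis gain
and bias, additive Gaussian noise, dynamic-range clipping, and optional
whole-second dropout or a fault mode.

Mounting geometry.  ENMO is a function of the vector norm, which a rigid
rotation of the whole signal cannot change.  What does change the norm is
the angle between gravity and the orbit plane, so the mounting rotation is
applied to the orbital (motion) component only while gravity stays on the
device z-axis — equivalent to tilting the orbit plane relative to gravity:

* identity rotation — gravity perpendicular to the orbit plane; the signal
  is (a cos th, a sin th, 1) and ENMO is the constant sqrt(1 + a^2) - 1;
* 90-degree tilt — gravity in the orbit plane; the norm becomes
  sqrt(1 + 2 a cos th + a^2), oscillating once per orbit cycle.

The in-plane geometry is the default because its per-second RMS ENMO scales
like a/sqrt(2), the magnitude regime the validation study operates in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .shaker import ShakerConfig, TrialProtocol, reference_acceleration_mg

__all__ = [
    "MountingOrientation",
    "DeviceSpec",
    "RawStream",
    "BRAND_PRESETS",
    "brand_preset",
    "ideal_plate_acceleration",
    "ideal_enmo_stats",
    "simulate_device_stream",
]

Brand = Literal["actigraph", "apple", "garmin", "fitbit", "custom"]
FaultMode = Literal["none", "all_negative_enmo"]


def _check_rotation(rot: np.ndarray) -> np.ndarray:
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3) or not np.allclose(rot.T @ rot, np.eye(3), atol=1e-9):
        raise ValueError("mounting rotation must be a 3x3 orthonormal matrix")
    return rot


@dataclass(frozen=True)
class MountingOrientation:
    """Orientation of the orbit plane relative to the device (and gravity).

    ``rotation`` maps shaker-frame axes (X, Y span the orbit plane, Z up)
    into the device frame; gravity remains along the device z-axis.  The
    z-row of the rotated in-plane basis determines how much of the orbital
    motion projects onto gravity (``in_plane_fraction``).
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))

    @classmethod
    def gravity_perpendicular(cls) -> "MountingOrientation":
        """Orbit plane horizontal: gravity perpendicular to the motion."""
        return cls(np.eye(3))

    @classmethod
    def gravity_in_plane(cls) -> "MountingOrientation":
        """Orbit plane vertical: gravity lies in the plane of the motion."""
        # 90-degree rotation about x: shaker y-axis maps onto device z.
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]]))

    @property
    def in_plane_fraction(self) -> float:
        """Projection of the orbital motion onto gravity, in [0, 1].

        0 = perpendicular mounting (constant ENMO), 1 = fully in-plane.
        """
        r = self.rotation
        return float(np.hypot(r[2, 0], r[2, 1]))

    def __eq__(self, other) -> bool:  # dataclass eq fails on arrays
        return isinstance(other, MountingOrientation) and np.array_equal(
            self.rotation, other.rotation
        )

    def __hash__(self) -> int:
        return hash(self.rotation.tobytes())


@dataclass(frozen=True)
class DeviceSpec:
    """Hardware model of one simulated device."""

    device_id: str
    brand: Brand = "custom"
    sampling_hz: float = 100.0
    dynamic_range_g: float = 8.0
    noise_sd_g: float = 0.01
    bias_g: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gain: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mounting: MountingOrientation = field(
        default_factory=MountingOrientation.gravity_in_plane
    )
    dropout_rate: float = 0.0
    fault_mode: FaultMode = "none"

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.dynamic_range_g <= 0:
            raise ValueError("dynamic_range_g must be positive")
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be non-negative")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.fault_mode not in ("none", "all_negative_enmo"):
            raise ValueError(f"unknown fault_mode {self.fault_mode!r}")


@dataclass
class RawStream:
    """Raw triaxial samples from one device, device frame, units of g.

    ``duration_s`` is the nominal recording span (set by the simulator to
    the protocol duration); it may exceed the last timestamp when trailing
    1 s blocks were dropped.
    """

    device_id: str
    sampling_hz: float
    t_s: np.ndarray
    xyz: np.ndarray  # shape (n, 3)
    duration_s: float | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (len(self.t_s), 3):
            raise ValueError("xyz must have shape (len(t_s), 3)")
        if len(self.t_s) > 1 and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def x_g(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y_g(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z_g(self) -> np.ndarray:
        return self.xyz[:, 2]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "timestamp_s": self.t_s,
                "x_g": self.xyz[:, 0],
                "y_g": self.xyz[:, 1],
                "z_g": self.xyz[:, 2],
            }
        )


#: Sampling rate and dynamic range per brand.  Rates are the recorded ones
#: (ActiGraph and Apple 100 Hz, Fitbit 50 Hz, Garmin 25 Hz); ActiGraph's
#: range is +/-8 g and Fitbit's +/-4 g as documented for those devices, the
#: Apple and Garmin ranges are package defaults (not published).
BRAND_PRESETS: dict[str, dict] = {
    "actigraph": {"sampling_hz": 100.0, "dynamic_range_g": 8.0},
    "apple": {"sampling_hz": 100.0, "dynamic_range_g": 8.0},
    "garmin": {"sampling_hz": 25.0, "dynamic_range_g": 8.0},
    "fitbit": {"sampling_hz": 50.0, "dynamic_range_g": 4.0},
}


def brand_preset(brand: str, device_id: str | None = None, **overrides) -> DeviceSpec:
    """DeviceSpec preset for a known brand; extra fields may be overridden."""
    if brand not in BRAND_PRESETS:
        raise ValueError(
            f"unknown brand {brand!r}; expected one of {sorted(BRAND_PRESETS)}"
        )
    kw = dict(BRAND_PRESETS[brand])
    kw.update(overrides)
    return DeviceSpec(device_id=device_id or brand, brand=brand, **kw)


def _segment_amplitudes_g(
    protocol: TrialProtocol, config: ShakerConfig
) -> list[float]:
    return [
        reference_acceleration_mg(seg.frequency_hz, config) / 1000.0
        if seg.label == "oscillation"
        else 0.0
        for seg in protocol.segments
    ]


def ideal_plate_acceleration(
    t_s: float | np.ndarray,
    protocol: TrialProtocol,
    config: ShakerConfig | None = None,
    segment_phases: Sequence[float] | None = None,
) -> np.ndarray:
    """Ideal specific force on the plate, shaker frame, units of g.

    During oscillation at frequency f the components are
    (a cos th, a sin th, 1) with th = 2 pi f (t - segment start) + phase;
    during rest (0, 0, 1).  ``segment_phases`` gives one phase per protocol
    segment (default 0).  Returns shape (3,) for scalar ``t_s``, else (n, 3).
    """
    if config is None:
        config = ShakerConfig()
    scalar = np.isscalar(t_s)
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    if np.any(t < 0) or np.any(t >= protocol.duration_s):
        raise ValueError("t outside protocol duration")
    amps = _segment_amplitudes_g(protocol, config)
    phases = list(segment_phases) if segment_phases is not None else [0.0] * len(
        protocol.segments
    )
    out = np.zeros((len(t), 3))
    out[:, 2] = 1.0
    for seg, a, ph in zip(protocol.segments, amps, phases):
        if seg.label != "oscillation":
            continue
        m = (t >= seg.start_s) & (t < seg.end_s)
        if not m.any():
            continue
        th = 2.0 * np.pi * seg.frequency_hz * (t[m] - seg.start_s) + ph
        out[m, 0] = a * np.cos(th)
        out[m, 1] = a * np.sin(th)
    return out[0] if scalar else out


def ideal_enmo_stats(
    f_hz: float,
    mounting: MountingOrientation | None = None,
    config: ShakerConfig | None = None,
    n_quad: int = 4096,
) -> tuple[float, float]:
    """Cycle-average (mean, RMS) ENMO in mg for an ideal noiseless device.

    For gravity perpendicular to the orbit plane ENMO is the constant
    (sqrt(1 + a^2) - 1) * 1000.  For a general tilt with in-plane fraction
    c, ENMO(th) = sqrt(1 + 2 a c cos th + a^2) - 1 is averaged over a full
    cycle by uniform-grid quadrature (spectrally accurate for smooth
    periodic integrands).
    """
    if config is None:
        config = ShakerConfig()
    if mounting is None:
        mounting = MountingOrientation.gravity_in_plane()
    if f_hz < 0:
        raise ValueError("frequency must be non-negative")
    if f_hz == 0:
        return (0.0, 0.0)
    a = reference_acceleration_mg(f_hz, config) / 1000.0
    c = mounting.in_plane_fraction
    if c == 0.0:
        e = (np.sqrt(1.0 + a * a) - 1.0) * 1000.0
        return (e, e)
    th = np.linspace(0.0, 2.0 * np.pi, n_quad, endpoint=False)
    enmo = (np.sqrt(1.0 + 2.0 * a * c * np.cos(th) + a * a) - 1.0) * 1000.0
    return (float(enmo.mean()), float(np.sqrt(np.mean(enmo**2))))


def simulate_device_stream(
    protocol: TrialProtocol,
    spec: DeviceSpec,
    config: ShakerConfig | None = None,
    seed: int = 0,
) -> RawStream:
    """Simulate one device's raw stream over a protocol.

    The ideal orbital motion (with a seeded random phase per segment) is
    rotated by the mounting, combined with gravity on the device z-axis,
    then passed through the device model: per-axis gain, bias, Gaussian
    noise, and clipping at +/- dynamic range.  Whole 1 s blocks are dropped
    with probability ``dropout_rate``.  ``fault_mode="all_negative_enmo"``
    halves the clean signal and suppresses noise so every sample's norm is
    below 1 g (downstream ENMO always negative), emulating a faulty unit.

    Deterministic: the same (protocol, spec, config, seed) reproduce the
    stream bit for bit.
    """
    if config is None:
        config = ShakerConfig()
    rng = np.random.default_rng(seed)
    fs = spec.sampling_hz
    n = int(round(protocol.duration_s * fs))
    t = np.arange(n) / fs

    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(protocol.segments))
    amps = _segment_amplitudes_g(protocol, config)
    motion = np.zeros((n, 3))
    for seg, a, ph in zip(protocol.segments, amps, phases):
        if seg.label != "oscillation" or a == 0.0:
            continue
        m = (t >= seg.start_s) & (t < seg.end_s)
        th = 2.0 * np.pi * seg.frequency_hz * (t[m] - seg.start_s) + ph
        motion[m, 0] = a * np.cos(th)
        motion[m, 1] = a * np.sin(th)

    signal = motion @ spec.mounting.rotation.T
    signal[:, 2] += 1.0  # gravity on the device z-axis

    if spec.fault_mode == "all_negative_enmo":
        signal = 0.5 * signal
    else:
        signal = signal * np.asarray(spec.gain) + np.asarray(spec.bias_g)
        if spec.noise_sd_g > 0:
            signal = signal + rng.normal(0.0, spec.noise_sd_g, size=signal.shape)
    signal = np.clip(signal, -spec.dynamic_range_g, spec.dynamic_range_g)

    if spec.dropout_rate > 0:
        n_seconds = int(np.ceil(protocol.duration_s))
        dropped = rng.random(n_seconds) < spec.dropout_rate
        keep = ~dropped[np.floor(t).astype(int)]
        t, signal = t[keep], signal[keep]

    return RawStream(
        device_id=spec.device_id,
        sampling_hz=fs,
        t_s=t,
        xyz=signal,
        duration_s=protocol.duration_s,
    )
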