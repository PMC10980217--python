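"""Orbital-shaker reference model and trial protocols.

An orbital shaker translates its plate in a horizontal circle of radius
``r`` at frequency ``f`` (rotations per second) without rotating the plate
itself.  A device clamped to the plate therefore experiences a centripetal
acceleration of constant magnitude rotating in the orbit plane.  With the
plate speed ``v = 2*pi*r*f``, the textbook centripetal acceleration is

    a = v**2 / r = 4 * pi**2 * r * f**2        (``as_printed``)

The study protocol this package reproduces reports reference values
(4.4 mg at 0.6 Hz, 124.7 mg at 3.2 Hz for a 1.9 cm orbit) that equal this
expression divided by pi, i.e.

    a = 4 * pi * r * f**2                      (``as_used``)

Both conversions are implemented; ``as_used`` is the default because it
matches the published reference accelerations.  Accelerations are expressed
in milligravity (mg, 1/1000 of g) by dividing by gravity and scaling by 1000.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "ShakerConfig",
    "OscillationLevel",
    "ProtocolSegment",
    "TrialProtocol",
    "VALIDITY_FREQUENCIES_HZ",
    "RELIABILITY_SPEEDS_HZ",
    "reference_acceleration_mg",
    "build_validity_protocol",
    "build_reliability_sequence",
    "reference_trace",
    "reference_trace_frame",
]

#: Oscillation frequencies of the validity trial, in protocol order (Hz).
VALIDITY_FREQUENCIES_HZ: tuple[float, ...] = (3.2, 2.8, 2.4, 1.9, 1.5, 1.0, 0.6)

#: The two speeds used for the reliability trials (Hz).
RELIABILITY_SPEEDS_HZ: tuple[float, float] = (0.6, 3.2)

REST_DURATION_S = 15.0
OSCILLATION_DURATION_S = 120.0

ConversionVariant = Literal["as_printed", "as_used"]


@dataclass(frozen=True)
class ShakerConfig:
    """Orbit geometry and the frequency-to-acceleration conversion.

    Parameters
    ----------
    orbit_diameter_cm
        Diameter of the orbital path (2r), default 1.9 cm.
    gravity_cm_s2
        Gravitational acceleration used to express results in g / mg,
        default 980 cm/s^2.
    conversion_variant
        ``"as_used"`` (default) uses a = 4*pi*r*f**2, which reproduces the
        published reference accelerations; ``"as_printed"`` uses the
        textbook a = 4*pi^2*r*f**2.  The two differ by exactly pi.
    """

    orbit_diameter_cm: float = 1.9
    gravity_cm_s2: float = 980.0
    conversion_variant: ConversionVariant = "as_used"

    def __post_init__(self) -> None:
        if self.orbit_diameter_cm <= 0:
            raise ValueError("orbit_diameter_cm must be positive")
        if self.gravity_cm_s2 <= 0:
            raise ValueError("gravity_cm_s2 must be positive")
        if self.conversion_variant not in ("as_printed", "as_used"):
            raise ValueError(
                f"unknown conversion_variant {self.conversion_variant!r}"
            )

    @property
    def radius_cm(self) -> float:
        return self.orbit_diameter_cm / 2.0


def reference_acceleration_mg(f_hz: float, config: ShakerConfig | None = None) -> float:
    """Reference (centripetal) acceleration at shaker frequency ``f_hz``, in mg.

    Strictly increasing and quadratic in ``f_hz``; zero at rest.
    Raises ``ValueError`` for negative frequency.
    """
    if config is None:
        config = ShakerConfig()
    f = np.asarray(f_hz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    r = config.radius_cm
    if config.conversion_variant == "as_printed":
        a_cm_s2 = 4.0 * np.pi**2 * r * f**2
    else:
        a_cm_s2 = 4.0 * np.pi * r * f**2
    out = a_cm_s2 / config.gravity_cm_s2 * 1000.0
    return float(out) if np.isscalar(f_hz) else out


@dataclass(frozen=True)
class OscillationLevel:
    """A shaker speed paired with its derived reference acceleration."""

    frequency_hz: float
    reference_mg: float

    @classmethod
    def from_frequency(cls, f_hz: float, config: ShakerConfig | None = None) -> "OscillationLevel":
        return cls(frequency_hz=f_hz, reference_mg=reference_acceleration_mg(f_hz, config))


@dataclass(frozen=True)
class ProtocolSegment:
    """One contiguous rest or oscillation block of a trial timeline."""

    label: Literal["rest", "oscillation"]
    frequency_hz: float
    start_s: float
    duration_s: float
    trial_id: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("segment duration must be positive")
        if self.label == "rest" and self.frequency_hz != 0:
            raise ValueError("rest segments must have frequency 0")
        if self.label == "oscillation" and self.frequency_hz <= 0:
            raise ValueError("oscillation segments must have positive frequency")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class TrialProtocol:
    """An ordered, gap-free sequence of protocol segments."""

    segments: tuple[ProtocolSegment, ...]
    kind: Literal["reliability", "validity", "custom"] = "custom"

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        t = 0.0
        for seg in segs:
            if abs(seg.start_s - t) > 1e-9:
                raise ValueError(
                    f"segments must tile the timeline: expected start {t}, got {seg.start_s}"
                )
            t = seg.end_s

    @property
    def duration_s(self) -> float:
        return self.segments[-1].end_s

    @property
    def oscillation_segments(self) -> tuple[ProtocolSegment, ...]:
        return tuple(s for s in self.segments if s.label == "oscillation")

    def segment_at(self, t_s: float) -> ProtocolSegment:
        """Segment containing time ``t_s`` (half-open [start, end))."""
        if t_s < 0 or t_s >= self.duration_s:
            raise ValueError(f"t={t_s} outside protocol [0, {self.duration_s})")
        for seg in self.segments:
            if seg.start_s <= t_s < seg.end_s:
                return seg
        raise AssertionError("unreachable: segments tile the timeline")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "segments": [
                {
                    "label": s.label,
                    "frequency_hz": s.frequency_hz,
                    "duration_s": s.duration_s,
                    **({"trial_id": s.trial_id} if s.trial_id is not None else {}),
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialProtocol":
        segs, t = [], 0.0
        for s in d["segments"]:
            segs.append(
                ProtocolSegment(
                    label=s["label"],
                    frequency_hz=float(s["frequency_hz"]),
                    start_s=t,
                    duration_s=float(s["duration_s"]),
                    trial_id=s.get("trial_id"),
                )
            )
            t += float(s["duration_s"])
        return cls(segments=tuple(segs), kind=d.get("kind", "custom"))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "TrialProtocol":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def build_validity_protocol(config: ShakerConfig | None = None) -> TrialProtocol:
    """The 14 min 30 s validity trial.

    15 s rest, seven 2-minute oscillation blocks at 3.2, 2.8, 2.4, 1.9, 1.5,
    1.0 and 0.6 Hz in that order, then a closing 15 s rest; 870 s in total.
    """
    segs = [ProtocolSegment("rest", 0.0, 0.0, REST_DURATION_S)]
    t = REST_DURATION_S
    for f in VALIDITY_FREQUENCIES_HZ:
        segs.append(ProtocolSegment("oscillation", f, t, OSCILLATION_DURATION_S))
        t += OSCILLATION_DURATION_S
    segs.append(ProtocolSegment("rest", 0.0, t, REST_DURATION_S))
    return TrialProtocol(segments=tuple(segs), kind="validity")


def build_reliability_sequence(
    speed_hz: float,
    n_trials: int,
    rest_per_trial: bool = False,
) -> TrialProtocol:
    """A batch of back-to-back 2-minute reliability trials at one speed.

    Default (bookend) layout is 15 s rest + ``n_trials`` consecutive 120 s
    oscillation trials + 15 s rest, which reproduces the published batch
    duration of 10 min 30 s for five trials.  ``rest_per_trial=True`` inserts
    a 15 s rest before every trial instead (plus the closing rest).
    Each oscillation segment carries a 1-based ``trial_id``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if speed_hz <= 0:
        raise ValueError("speed_hz must be positive")
    segs: list[ProtocolSegment] = []
    t = 0.0
    if not rest_per_trial:
        segs.append(ProtocolSegment("rest", 0.0, t, REST_DURATION_S))
        t += REST_DURATION_S
    for trial in range(1, n_trials + 1):
        if rest_per_trial:
            segs.append(ProtocolSegment("rest", 0.0, t, REST_DURATION_S))
            t += REST_DURATION_S
        segs.append(
            ProtocolSegment("oscillation", speed_hz, t, OSCILLATION_DURATION_S, trial_id=trial)
        )
        t += OSCILLATION_DURATION_S
    segs.append(ProtocolSegment("rest", 0.0, t, REST_DURATION_S))
    return TrialProtocol(segments=tuple(segs), kind="reliability")


def reference_trace(protocol: TrialProtocol, config: ShakerConfig | None = None) -> np.ndarray:
    """Per-second reference acceleration (mg) over the protocol.

    One value per whole second, 0-based half-open [s, s+1) convention; rest
    seconds are 0 mg, oscillation seconds carry the segment's reference.
    """
    if config is None:
        config = ShakerConfig()
    n = int(round(protocol.duration_s))
    out = np.zeros(n)
    for seg in protocol.segments:
        if seg.label == "oscillation":
            lo, hi = int(round(seg.start_s)), int(round(seg.end_s))
            out[lo:hi] = reference_acceleration_mg(seg.frequency_hz, config)
    return out


def reference_trace_frame(
    protocol: TrialProtocol, config: ShakerConfig | None = None
):
    """Reference trace as a two-column table (second, reference_mg)."""
    import pandas as pd

    trace = reference_trace(protocol, config)
    return pd.DataFrame({"second": np.arange(len(trace)), "reference_mg": trace})
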