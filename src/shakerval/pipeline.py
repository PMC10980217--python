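"""Raw stream -> second-level ENMO epoch table.

Processing chain: per-sample ENMO (Euclidean Norm Minus One, scaled to
milligravity), aggregation to 1 s epochs (mean and RMS), extraction of the
middle minute of each 2-minute oscillation block, and a join against the
shaker reference trace.  Negative ENMO is retained throughout — the study's
device-exclusion rule ("every ENMO value below zero") only makes sense if
negative values are representable — with truncation at zero available as an
off-by-default option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .shaker import ShakerConfig, TrialProtocol, reference_acceleration_mg
from .simulate import RawStream

__all__ = [
    "EPOCH_COLUMNS",
    "EpochTable",
    "compute_enmo",
    "aggregate_to_seconds",
    "extract_middle_minute",
    "build_epoch_table",
    "flag_implausible_devices",
]

EPOCH_COLUMNS = [
    "device_id",
    "brand",
    "trial_id",
    "frequency_hz",
    "second_index",
    "enmo_mean_mg",
    "enmo_rms_mg",
    "reference_mg",
]

#: Half-open window of each 120 s oscillation block kept by
#: middle-minute extraction: seconds [30, 90) from segment start.
MIDDLE_MINUTE = (30, 90)


@dataclass
class EpochTable:
    """Long-format second-level table, one row per device-second.

    Rows are unique on (device_id, trial_id, frequency_hz, second_index);
    ``provenance`` records the processing parameters that produced it.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EPOCH_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"epoch table missing columns: {missing}")
        self.df = self.df[EPOCH_COLUMNS].reset_index(drop=True)
        key = ["device_id", "trial_id", "frequency_hz", "second_index"]
        if len(self.df) and self.df.duplicated(subset=key).any():
            raise ValueError("duplicate (device, trial, frequency, second) rows")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def empty(cls, provenance: dict | None = None) -> "EpochTable":
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            EPOCH_COLUMNS,
            [str, str, int, float, int, float, float, float],
        )})
        return cls(df=df, provenance=provenance or {})


def compute_enmo(stream: RawStream, truncate: bool = False) -> np.ndarray:
    """Per-sample ENMO in mg: (||(x,y,z)|| - 1) * 1000.

    Negative values are kept by default; ``truncate=True`` clamps at zero
    (the GGIR-style convention), which breaks the all-negative exclusion
    rule and is therefore off by default.
    """
    if len(stream) == 0:
        raise ValueError("empty stream")
    enmo = (np.linalg.norm(stream.xyz, axis=1) - 1.0) * 1000.0
    return np.maximum(enmo, 0.0) if truncate else enmo


def aggregate_to_seconds(
    t_s: np.ndarray,
    enmo_mg: np.ndarray,
    sampling_hz: float,
) -> pd.DataFrame:
    """Aggregate per-sample ENMO to whole seconds (mean and RMS).

    Seconds are 0-based half-open windows [s, s+1) on the stream clock.
    Seconds with no samples are absent; partial seconds (fewer than the
    nominal ``sampling_hz`` samples, e.g. stream boundaries) are dropped.
    Returns columns second_index, enmo_mean_mg, enmo_rms_mg.
    """
    t_s = np.asarray(t_s, dtype=float)
    enmo_mg = np.asarray(enmo_mg, dtype=float)
    if t_s.shape != enmo_mg.shape:
        raise ValueError("t_s and enmo_mg must have equal length")
    sec = np.floor(t_s).astype(int)
    g = pd.DataFrame({"second_index": sec, "enmo": enmo_mg}).groupby(
        "second_index", sort=True
    )["enmo"]
    out = pd.DataFrame(
        {
            "enmo_mean_mg": g.mean(),
            "enmo_rms_mg": np.sqrt(g.apply(lambda v: np.mean(np.square(v)))),
            "n_samples": g.size(),
        }
    ).reset_index()
    full = int(round(sampling_hz))
    out = out[out["n_samples"] >= full].drop(columns="n_samples")
    return out.reset_index(drop=True)


def extract_middle_minute(
    per_second: pd.DataFrame,
    protocol: TrialProtocol,
) -> pd.DataFrame:
    """Keep seconds [30, 90) of each 120 s oscillation block.

    ``per_second`` must carry protocol-clock ``second_index`` values (as
    produced by :func:`aggregate_to_seconds` on a protocol-aligned stream).
    Adds segment metadata (frequency_hz, trial_id) and rebases
    ``second_index`` to seconds from segment start.  Rest segments
    contribute nothing.  Raises if an oscillation segment is shorter than
    120 s (protocol mismatch).
    """
    lo, hi = MIDDLE_MINUTE
    pieces = []
    for seg in protocol.oscillation_segments:
        if seg.duration_s < 120.0:
            raise ValueError(
                f"oscillation segment at {seg.frequency_hz} Hz is shorter than 120 s"
            )
        start = int(round(seg.start_s))
        keep = per_second[
            (per_second["second_index"] >= start + lo)
            & (per_second["second_index"] < start + hi)
        ].copy()
        keep["second_index"] = keep["second_index"] - start
        keep["frequency_hz"] = seg.frequency_hz
        keep["trial_id"] = seg.trial_id if seg.trial_id is not None else 0
        pieces.append(keep)
    if not pieces:
        return per_second.iloc[0:0].assign(frequency_hz=[], trial_id=[])
    return pd.concat(pieces, ignore_index=True)


def build_epoch_table(
    streams: Sequence[RawStream],
    protocol: TrialProtocol,
    config: ShakerConfig | None = None,
    brands: Mapping[str, str] | None = None,
    run_id: int | None = None,
    truncate: bool = False,
) -> EpochTable:
    """Process raw streams through the full chain into one long table.

    ``brands`` maps device_id -> brand label (default "custom").  For
    protocols whose segments carry no trial number (the validity trial),
    ``run_id`` labels the whole run's trial_id (default 0).  Streams must
    be aligned to the protocol clock and cover it entirely.
    """
    if config is None:
        config = ShakerConfig()
    brands = dict(brands or {})
    rows = []
    for stream in streams:
        coverage = stream.duration_s
        if coverage is None:
            coverage = (
                stream.t_s[-1] + 1.0 / stream.sampling_hz if len(stream) else 0.0
            )
        if coverage < protocol.duration_s - 1e-6:
            raise ValueError(
                f"stream {stream.device_id!r} shorter than protocol "
                f"({coverage:.1f} s < {protocol.duration_s:.0f} s)"
            )
        enmo = compute_enmo(stream, truncate=truncate)
        per_second = aggregate_to_seconds(stream.t_s, enmo, stream.sampling_hz)
        mid = extract_middle_minute(per_second, protocol)
        if run_id is not None:
            mid["trial_id"] = np.where(mid["trial_id"] == 0, run_id, mid["trial_id"])
        mid["device_id"] = stream.device_id
        mid["brand"] = brands.get(stream.device_id, "custom")
        mid["reference_mg"] = reference_acceleration_mg(
            np.asarray(mid["frequency_hz"], dtype=float), config
        ) if len(mid) else pd.Series(dtype=float)
        rows.append(mid)
    if rows:
        df = pd.concat(rows, ignore_index=True)
    else:
        return EpochTable.empty(
            provenance={"conversion_variant": config.conversion_variant}
        )
    df["trial_id"] = df["trial_id"].astype(int)
    df["second_index"] = df["second_index"].astype(int)
    table = EpochTable(
        df=df[EPOCH_COLUMNS],
        provenance={
            "conversion_variant": config.conversion_variant,
            "truncate": truncate,
            "n_streams": len(streams),
        },
    )
    return table


def flag_implausible_devices(
    table: EpochTable,
    device_ids: Sequence[str] | None = None,
) -> tuple[EpochTable, list[str]]:
    """Exclude devices whose every mean-aggregate ENMO value is below zero.

    Mirrors the study's exclusion of a faulty unit reporting uniformly
    sub-zero ENMO.  A device with even one non-negative value is kept; a
    device contributing no rows is kept with a warning (the rule is vacuous
    on an empty record set).
    Returns (kept table, excluded device ids).
    """
    df = table.df
    if device_ids is not None:
        for dev in device_ids:
            if dev not in set(df["device_id"]):
                warnings.warn(
                    f"device {dev!r} contributed no epochs; the all-negative "
                    "rule is vacuous and the device is kept",
                    stacklevel=2,
                )
    excluded: list[str] = []
    for device_id, grp in df.groupby("device_id", sort=False):
        if len(grp) and (grp["enmo_mean_mg"] < 0).all():
            excluded.append(str(device_id))
    if not excluded:
        return table, []
    kept = df[~df["device_id"].isin(excluded)].reset_index(drop=True)
    prov = dict(table.provenance)
    prov["excluded_devices"] = list(excluded)
    prov["exclusion_rule"] = "all mean-aggregate ENMO values below 0 mg"
    return EpochTable(df=kept, provenance=prov), excluded
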