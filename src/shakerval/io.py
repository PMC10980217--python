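"""Readers/writers for raw device exports and pipeline tables, and the
end-to-end synthetic study runner.

Device exports are plain CSV in assorted dialects (column names, header
junk, timestamp conventions, g vs milli-g units); a :class:`ColumnDialect`
maps any of them onto the canonical internal schema rather than bit-parsing
proprietary formats.  ``run_study`` drives the whole pipeline — simulate,
process, analyze, report — from a YAML/JSON config with declared seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (
    _AGG_COLUMN,
    bland_altman_points,
    per_speed_error_summary,
    reliability_matrix,
    summarize_reliability,
    summarize_validity,
)
from .equivalence import EquivalenceBounds, table3_report
from .pipeline import EPOCH_COLUMNS, EpochTable, build_epoch_table, flag_implausible_devices
from .shaker import (
    RELIABILITY_SPEEDS_HZ,
    ShakerConfig,
    TrialProtocol,
    build_reliability_sequence,
    build_validity_protocol,
)
from .simulate import BRAND_PRESETS, DeviceSpec, RawStream, brand_preset, simulate_device_stream

__all__ = [
    "ColumnDialect",
    "DIALECTS",
    "read_raw_csv",
    "write_raw_csv",
    "write_epoch_table",
    "read_epoch_table",
    "read_aggregated_xlsx",
    "default_config",
    "build_device_fleet",
    "simulate_fleet",
    "run_study",
]

logger = logging.getLogger("shakerval")


# ---------------------------------------------------------------------------
# Raw CSV dialects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnDialect:
    """Mapping from one device-export CSV layout onto the internal schema."""

    name: str
    column_map: Mapping[str, str]  # logical {timestamp,x,y,z} -> source column
    header_rows_to_skip: int = 0
    timestamp_format: str = "seconds"  # "seconds" or a strptime pattern
    units: Literal["g", "milli_g"] = "g"

    def __post_init__(self) -> None:
        missing = {"timestamp", "x", "y", "z"} - set(self.column_map)
        if missing:
            raise ValueError(f"dialect {self.name!r} missing mappings: {sorted(missing)}")


DIALECTS: dict[str, ColumnDialect] = {
    # The simulator's own export format.
    "generic": ColumnDialect(
        name="generic",
        column_map={"timestamp": "timestamp_s", "x": "x_g", "y": "y_g", "z": "z_g"},
    ),
    # ActiLife-style RAW export: banner lines then datetime + per-axis columns.
    "actilife_raw": ColumnDialect(
        name="actilife_raw",
        column_map={
            "timestamp": "Timestamp",
            "x": "Accelerometer X",
            "y": "Accelerometer Y",
            "z": "Accelerometer Z",
        },
        header_rows_to_skip=10,
        timestamp_format="%Y-%m-%d %H:%M:%S.%f",
    ),
    # Timestamped x/y/z logger reporting milli-g.
    "milli_g_log": ColumnDialect(
        name="milli_g_log",
        column_map={"timestamp": "time_s", "x": "ax_mg", "y": "ay_mg", "z": "az_mg"},
        units="milli_g",
    ),
}


class RawFormatError(ValueError):
    """Raised when a raw CSV does not match its declared dialect."""


def read_raw_csv(
    path: str | Path,
    dialect: ColumnDialect | str = "generic",
    device_id: str | None = None,
    sampling_hz: float | None = None,
) -> RawStream:
    """Read a raw triaxial CSV into a :class:`RawStream` (units of g).

    Timestamps are converted to seconds from the first sample when the
    dialect declares a datetime format, and must be strictly increasing.
    ``sampling_hz`` defaults to the median sample spacing.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    path = Path(path)
    df = pd.read_csv(path, skiprows=dialect.header_rows_to_skip)
    for logical, source in dialect.column_map.items():
        if source not in df.columns:
            raise RawFormatError(
                f"{path.name}: missing column {source!r} (maps to {logical!r})"
            )
    tcol = dialect.column_map["timestamp"]
    if dialect.timestamp_format == "seconds":
        try:
            t = df[tcol].astype(float).to_numpy()
        except ValueError as exc:
            raise RawFormatError(f"{path.name}: unparseable timestamp: {exc}") from exc
    else:
        try:
            ts = pd.to_datetime(df[tcol], format=dialect.timestamp_format)
        except ValueError as exc:
            bad = pd.to_datetime(
                df[tcol], format=dialect.timestamp_format, errors="coerce"
            )
            row = int(bad.isna().idxmax()) + dialect.header_rows_to_skip + 2
            raise RawFormatError(
                f"{path.name}: unparseable timestamp at line {row}"
            ) from exc
        t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + dialect.header_rows_to_skip + 3
        raise RawFormatError(
            f"{path.name}: non-increasing timestamp at line {row}"
        )
    xyz = df[[dialect.column_map[a] for a in ("x", "y", "z")]].to_numpy(dtype=float)
    if dialect.units == "milli_g":
        xyz = xyz / 1000.0
    if sampling_hz is None:
        sampling_hz = float(1.0 / np.median(dt)) if len(dt) else 1.0
    return RawStream(
        device_id=device_id or path.stem,
        sampling_hz=sampling_hz,
        t_s=t,
        xyz=xyz,
    )


def write_raw_csv(stream: RawStream, path: str | Path, spec: DeviceSpec | None = None, seed: int | None = None) -> None:
    """Write a stream in the generic dialect, with a JSON sidecar of the
    generating device spec and seed when given."""
    path = Path(path)
    stream.to_dataframe().to_csv(path, index=False, float_format="%.9g")
    if spec is not None:
        sidecar = {
            "device_id": spec.device_id,
            "brand": spec.brand,
            "sampling_hz": spec.sampling_hz,
            "dynamic_range_g": spec.dynamic_range_g,
            "noise_sd_g": spec.noise_sd_g,
            "bias_g": list(spec.bias_g),
            "gain": list(spec.gain),
            "mounting_rotation": spec.mounting.rotation.tolist(),
            "dropout_rate": spec.dropout_rate,
            "fault_mode": spec.fault_mode,
            "seed": seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# Epoch-table round trip
# ---------------------------------------------------------------------------

def write_epoch_table(table: EpochTable, path: str | Path) -> None:
    """Lossless CSV export of an epoch table (full float precision)."""
    path = Path(path)
    table.df.to_csv(path, index=False, float_format="%.17g")


def read_epoch_table(path: str | Path) -> EpochTable:
    """Read an epoch-table CSV written by :func:`write_epoch_table`."""
    df = pd.read_csv(path)
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epoch table at {path} missing columns: {missing}")
    if df.empty:
        return EpochTable.empty(provenance={"source": str(path)})
    df["device_id"] = df["device_id"].astype(str)
    df["brand"] = df["brand"].astype(str)
    return EpochTable(df=df, provenance={"source": str(path)})


def read_aggregated_xlsx(
    path: str | Path,
    column_map: Mapping[str, str],
    sheet_name: int | str = 0,
    defaults: Mapping[str, object] | None = None,
) -> EpochTable:
    """Read an externally aggregated second-level XLSX into an EpochTable.

    ``column_map`` maps epoch-table columns to the workbook's column names;
    columns absent from the map are filled from ``defaults`` (e.g.
    ``{"trial_id": 0}``).  Requires openpyxl.  No fixed workbook layout is
    assumed — the mapping is entirely user-supplied.
    """
    df = pd.read_excel(Path(path), sheet_name=sheet_name)
    defaults = dict(defaults or {})
    out = {}
    for col in EPOCH_COLUMNS:
        if col in column_map:
            src = column_map[col]
            if src not in df.columns:
                raise ValueError(f"{path}: mapped column {src!r} not found")
            out[col] = df[src]
        elif col in defaults:
            out[col] = defaults[col]
        else:
            raise ValueError(f"no mapping or default for column {col!r}")
    frame = pd.DataFrame(out)
    frame["device_id"] = frame["device_id"].astype(str)
    frame["brand"] = frame["brand"].astype(str)
    return EpochTable(df=frame, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# End-to-end study runner
# ---------------------------------------------------------------------------

_ALLOWED_TOP_KEYS = {
    "seed",
    "shaker",
    "bound",
    "brands",
    "reliability",
    "output_dir",
    "write_raw",
    "write_bland_altman",
}
_ALLOWED_BRAND_KEYS = {
    "n_devices",
    "noise_sd_g",
    "bias_sd_g",
    "gain_sd",
    "dropout_rate",
    "include_faulty",
    "sampling_hz",
    "dynamic_range_g",
}


def default_config() -> dict:
    """Default synthetic-study configuration.

    Ten devices per brand for the validity trial, two batches of five
    co-mounted devices per brand at 0.6 and 3.2 Hz (five 2-minute trials
    each) for reliability; one faulty all-negative unit among the
    ActiGraphs (exercising the exclusion rule) and per-second dropout on
    the Fitbits (emulating their missingness).  Device-to-device spread
    comes from per-device gain and bias draws sized as post-factory-
    calibration residuals (~1 mg offset, ~0.1% scale) — much larger
    residuals would push a healthy device's tiny mean-aggregate ENMO
    uniformly below zero and trip the exclusion rule meant for faulty
    hardware.
    """
    brands = {}
    for brand in BRAND_PRESETS:
        brands[brand] = {
            "n_devices": 10,
            "noise_sd_g": 0.01,
            "bias_sd_g": 0.001,
            "gain_sd": 0.001,
            "dropout_rate": 0.0,
            "include_faulty": False,
        }
    brands["actigraph"]["include_faulty"] = True
    brands["fitbit"]["dropout_rate"] = 0.05
    return {
        "seed": 0,
        "shaker": {
            "orbit_diameter_cm": 1.9,
            "gravity_cm_s2": 980.0,
            "conversion_variant": "as_used",
        },
        "bound": {"bound_mg": 6.3, "derivation": "fixed", "fraction": 0.10},
        "reliability": {"speeds": list(RELIABILITY_SPEEDS_HZ), "n_trials": 5, "batches": 2},
        "output_dir": "results/study",
        "write_raw": False,
        "write_bland_altman": True,
    } | {"brands": brands}


def _validate_config(cfg: dict) -> None:
    bad = set(cfg) - _ALLOWED_TOP_KEYS
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    for brand, bcfg in cfg.get("brands", {}).items():
        bad = set(bcfg) - _ALLOWED_BRAND_KEYS
        if bad:
            raise ValueError(f"unknown keys for brand {brand!r}: {sorted(bad)}")


def build_device_fleet(
    brand: str, bcfg: dict, rng: np.random.Generator
) -> list[DeviceSpec]:
    """Per-device specs with seeded gain/bias draws; optionally the last
    device is replaced by a faulty all-negative unit."""
    n = int(bcfg.get("n_devices", 10))
    specs = []
    for i in range(1, n + 1):
        overrides: dict = {
            "noise_sd_g": float(bcfg.get("noise_sd_g", 0.01)),
            "dropout_rate": float(bcfg.get("dropout_rate", 0.0)),
            "bias_g": tuple(rng.normal(0.0, float(bcfg.get("bias_sd_g", 0.001)), 3)),
            "gain": tuple(1.0 + rng.normal(0.0, float(bcfg.get("gain_sd", 0.001)), 3)),
        }
        for key in ("sampling_hz", "dynamic_range_g"):
            if key in bcfg:
                overrides[key] = float(bcfg[key])
        specs.append(brand_preset(brand, device_id=f"{brand}_{i:02d}", **overrides))
    if bcfg.get("include_faulty", False):
        specs[-1] = replace(specs[-1], fault_mode="all_negative_enmo")
    return specs


def simulate_fleet(
    specs: Sequence[DeviceSpec],
    protocol: TrialProtocol,
    config: ShakerConfig,
    seed_seq: np.random.SeedSequence,
) -> list[RawStream]:
    child_seeds = seed_seq.generate_state(len(specs))
    return [
        simulate_device_stream(protocol, spec, config, seed=int(s) % 2**31)
        for spec, s in zip(specs, child_seeds)
    ]


def run_study(
    config: str | Path | dict | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Run the full synthetic validation study from a config.

    Simulates validity and reliability recordings for every configured
    brand, processes them to epoch tables, applies the all-negative-ENMO
    exclusion, and writes the report bundle: the epoch table, reliability
    ICC table, validity summary, per-speed errors, equivalence (TOST)
    table, optional Bland-Altman exports, and a run log with seeds and
    exclusion decisions.  Deterministic for a fixed config.

    Returns a dict with the in-memory tables and output paths.
    """
    if config is None:
        cfg = default_config()
    elif isinstance(config, (str, Path)):
        text = Path(config).read_text()
        cfg = (
            json.loads(text)
            if str(config).endswith(".json")
            else yaml.safe_load(text)
        )
    else:
        cfg = dict(config)
    _validate_config(cfg)
    base = default_config()
    merged = {**base, **cfg}
    merged["brands"] = {
        b: {**base["brands"].get(b, {}), **bc} for b, bc in cfg.get("brands", base["brands"]).items()
    }
    cfg = merged

    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    shaker_cfg = ShakerConfig(**cfg["shaker"])
    bounds = EquivalenceBounds(**cfg["bound"])
    validity_protocol = build_validity_protocol(shaker_cfg)

    root_seq = np.random.SeedSequence(seed)
    spec_rng = np.random.default_rng(root_seq.spawn(1)[0])

    log_lines = [
        f"shakerval {__version__}",
        f"config_hash {hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]}",
        f"seed {seed}",
        f"conversion_variant {shaker_cfg.conversion_variant}",
    ]

    # --- validity arm ----------------------------------------------------
    validity_streams: list[RawStream] = []
    brand_map: dict[str, str] = {}
    all_specs: dict[str, list[DeviceSpec]] = {}
    for brand, bcfg in cfg["brands"].items():
        specs = build_device_fleet(brand, bcfg, spec_rng)
        all_specs[brand] = specs
        streams = simulate_fleet(
            specs, validity_protocol, shaker_cfg, root_seq.spawn(1)[0]
        )
        validity_streams.extend(streams)
        brand_map.update({s.device_id: brand for s in specs})
        if cfg.get("write_raw", False):
            raw_dir = out / "raw"
            raw_dir.mkdir(exist_ok=True)
            for spec, stream in zip(specs, streams):
                write_raw_csv(stream, raw_dir / f"{spec.device_id}.csv", spec=spec, seed=seed)

    epoch_table = build_epoch_table(
        validity_streams, validity_protocol, shaker_cfg, brands=brand_map
    )
    kept, excluded = flag_implausible_devices(epoch_table)
    for dev in excluded:
        logger.warning("excluding device %s: all ENMO values below 0", dev)
        log_lines.append(f"excluded {dev} (all mean-aggregate ENMO below 0)")
    write_epoch_table(kept, out / "epoch_table.csv")

    # --- reliability arm -------------------------------------------------
    rel_cfg = cfg["reliability"]
    icc_rows = []
    for brand, specs in all_specs.items():
        clean = [s for s in specs if s.fault_mode == "none"]
        groups = [clean[i : i + 5] for i in range(0, len(clean), 5)]
        # stacking across batches needs equal clamp counts; an undersized
        # trailing group (a faulty unit's batch) is left out of the ICC
        batches = [g for g in groups if len(g) == len(groups[0]) and len(g) >= 2]
        batches = batches[: int(rel_cfg["batches"])]
        if len(batches) < len(groups):
            log_lines.append(
                f"reliability {brand}: {len(groups) - len(batches)} undersized "
                "batch(es) left out of the ICC stack"
            )
        mats: dict[str, list[np.ndarray]] = {"mean": [], "rms": []}
        for batch in batches:
            for speed in rel_cfg["speeds"]:
                protocol = build_reliability_sequence(
                    float(speed), int(rel_cfg["n_trials"])
                )
                streams = simulate_fleet(
                    batch, protocol, shaker_cfg, root_seq.spawn(1)[0]
                )
                batch_table = build_epoch_table(
                    streams, protocol, shaker_cfg, brands=brand_map
                )
                for aggregation in ("mean", "rms"):
                    mats[aggregation].append(
                        reliability_matrix(
                            batch_table,
                            aggregation,
                            device_order=[s.device_id for s in batch],
                        )
                    )
        for aggregation in ("mean", "rms"):
            if mats[aggregation]:
                res = summarize_reliability(mats[aggregation], aggregation, brand=brand)
                icc_rows.append(res.__dict__)
    table1 = pd.DataFrame(icc_rows)[
        ["brand", "aggregation", "icc", "ci_low", "ci_high", "n_subjects", "k_raters", "interpretation"]
    ]
    table1.to_csv(out / "table1_icc.csv", index=False)

    # --- validity + equivalence reports ----------------------------------
    table2 = pd.concat(
        [summarize_validity(kept, agg) for agg in ("mean", "rms")], ignore_index=True
    )
    table2.to_csv(out / "table2_validity.csv", index=False)
    per_speed = pd.concat(
        [per_speed_error_summary(kept, agg) for agg in ("mean", "rms")],
        ignore_index=True,
    )
    per_speed.to_csv(out / "per_speed_errors.csv", index=False)
    table3 = table3_report(kept, bounds)
    table3.to_csv(out / "table3_tost.csv", index=False)

    if cfg.get("write_bland_altman", True):
        ba_dir = out / "bland_altman"
        ba_dir.mkdir(exist_ok=True)
        for aggregation in ("mean", "rms"):
            col = _AGG_COLUMN[aggregation]
            for brand, grp in kept.df.groupby("brand"):
                pts = bland_altman_points(
                    grp[col].to_numpy(), grp["reference_mg"].to_numpy()
                )
                pts.to_csv(ba_dir / f"{brand}_{aggregation}.csv", index=False)

    log_lines.append(f"validity_rows {len(kept)}")
    log_lines.append(f"reliability_trials {len(cfg['brands']) * int(rel_cfg['batches']) * len(rel_cfg['speeds']) * int(rel_cfg['n_trials'])}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    logger.info("study complete: %d validity rows, outputs in %s", len(kept), out)

    return {
        "epoch_table": kept,
        "excluded_devices": excluded,
        "table1_icc": table1,
        "table2_validity": table2,
        "per_speed_errors": per_speed,
        "table3_tost": table3,
        "output_dir": out,
        "config": cfg,
    }
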