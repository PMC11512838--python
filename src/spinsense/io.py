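"""File readers and writers shared by all subcommands.

Traces travel as two-column CSV (``time_s,value``) or, for audio,
16-bit PCM WAV at the trace's sampling rate; images as 8/16-bit
grayscale PNG or TIFF; masks as PNG; configurations as YAML or JSON
(YAML is a superset, so one loader covers both). Every reader raises
:class:`~spinsense.errors.ParseError` naming the offending row or field.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .errors import ParseError
from .protocol import (
    CapillaryValve,
    Chamber,
    DiscConfig,
    SiphonValve,
    TransferEvent,
)
from .tachometry import SensorTrace

__all__ = [
    "read_trace",
    "write_trace_csv",
    "read_trace_csv",
    "write_wav",
    "read_wav",
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "read_config",
    "write_config",
    "events_to_frame",
    "write_events_csv",
    "disc_to_dict",
    "disc_from_dict",
    "write_manifest",
]


# --------------------------------------------------------------------------
# sensor traces

def write_trace_csv(trace: SensorTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "value": trace.samples})
    df.to_csv(path, index=False, float_format="%.9g")


def read_trace_csv(path: str | Path, kind: str) -> SensorTrace:
    """Read a ``time_s,value`` CSV; sampling rate from the time column."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((numeric.isna()).idxmax()) + 2  # 1-based incl. header
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = numeric
    dt = np.diff(df["time_s"].to_numpy())
    if dt.size == 0 or np.any(dt <= 0):
        raise ParseError(f"{path}: time_s must be strictly increasing")
    rate = 1.0 / float(np.median(dt))
    return SensorTrace(df["value"].to_numpy(), rate, kind)


def write_wav(trace: SensorTrace, path: str | Path) -> None:
    """Write an audio trace as 16-bit PCM WAV (values clipped to [-1, 1])."""
    pcm = np.clip(trace.samples, -1.0, 1.0)
    pcm = np.round(pcm * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(round(trace.sampling_rate)), pcm)


def read_wav(path: str | Path, kind: str = "audio") -> SensorTrace:
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: not a readable WAV file ({exc})") from exc
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483647.0
    else:
        samples = data.astype(float)
    return SensorTrace(samples, float(rate), kind)


def read_trace(path: str | Path, kind: str) -> SensorTrace:
    path = Path(path)
    if path.suffix.lower() == ".wav":
        return read_wav(path, kind)
    return read_trace_csv(path, kind)


# --------------------------------------------------------------------------
# images and masks

def write_image(pixels: np.ndarray, path: str | Path, bit_depth: int = 16) -> None:
    """Write a [0, 1] float image as 8- or 16-bit grayscale PNG/TIFF."""
    if bit_depth == 16:
        arr = np.round(np.clip(pixels, 0, 1) * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(np.clip(pixels, 0, 1) * 255.0).astype(np.uint8)
    else:
        raise ParseError(f"unsupported bit depth {bit_depth}")
    iio.imwrite(str(path), arr)


def read_image(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PNG/TIFF image; returns ([0, 1] float array, source bit depth)."""
    try:
        arr = iio.imread(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: not a readable image ({exc})") from exc
    if np.issubdtype(arr.dtype, np.integer):
        bits = np.iinfo(arr.dtype).bits
        return arr.astype(float) / np.iinfo(arr.dtype).max, bits
    return arr.astype(float), 8


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    arr, _ = read_image(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0.5


# --------------------------------------------------------------------------
# configs, events, manifests

def read_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration into a dict."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ParseError(f"{path}: top level must be a mapping")
    return data


def write_config(data: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def events_to_frame(events: list[TransferEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "time_s": e.time,
                "rpm": e.rpm,
                "liquid": e.liquid_id,
                "source": e.source,
                "target": e.target,
                "volume_ul": e.volume,
                "valve": e.valve_id,
            }
            for e in events
        ],
        columns=["time_s", "rpm", "liquid", "source", "target", "volume_ul", "valve"],
    )


def write_events_csv(events: list[TransferEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def disc_to_dict(disc: DiscConfig) -> dict:
    return {
        "chambers": [
            {
                "id": c.id,
                "capacity_ul": None if c.capacity == float("inf") else c.capacity,
                "contents": [{"liquid": l, "volume_ul": v} for l, v in c.contents],
            }
            for c in disc.chambers
        ],
        "capillary_valves": [
            {"id": v.id, "source": v.source, "target": v.target, "burst_rpm": v.burst_rpm}
            for v in disc.capillary_valves
        ],
        "siphon_valves": [
            {
                "id": v.id,
                "source": v.source,
                "target": v.target,
                "prime_rpm_max": v.prime_rpm_max,
                "transfer_rpm_min": v.transfer_rpm_min,
                "prime_volume_ul": v.prime_volume_ul,
            }
            for v in disc.siphon_valves
        ],
    }


def disc_from_dict(data: dict) -> DiscConfig:
    try:
        chambers = [
            Chamber(
                id=c["id"],
                capacity=float("inf") if c.get("capacity_ul") is None else float(c["capacity_ul"]),
                contents=[(x["liquid"], float(x["volume_ul"])) for x in c.get("contents", [])],
            )
            for c in data["chambers"]
        ]
        cvs = [
            CapillaryValve(
                id=v["id"], source=v["source"], target=v["target"],
                burst_rpm=float(v["burst_rpm"]),
            )
            for v in data.get("capillary_valves", [])
        ]
        svs = [
            SiphonValve(
                id=v["id"], source=v["source"], target=v["target"],
                prime_rpm_max=float(v.get("prime_rpm_max", 100.0)),
                transfer_rpm_min=float(v.get("transfer_rpm_min", 300.0)),
                prime_volume_ul=(
                    None if v.get("prime_volume_ul") is None else float(v["prime_volume_ul"])
                ),
            )
            for v in data.get("siphon_valves", [])
        ]
    except KeyError as exc:
        raise ParseError(f"disc config missing field {exc}") from exc
    disc = DiscConfig(chambers=chambers, capillary_valves=cvs, siphon_valves=svs)
    disc.validate()
    return disc


def write_manifest(path: str | Path, subcommand: str, parameters: dict, seed: int | None,
                   inputs: list[str] = (), outputs: list[str] = ()) -> None:
    """Record everything needed to reproduce a run next to its outputs."""
    from . import __version__

    manifest = {
        "tool": "spinsense",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": parameters,
        "seed": seed,
        "inputs": list(inputs),
        "outputs": list(outputs),
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
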