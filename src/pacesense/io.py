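"""Waveform CSV I/O and serializable run configuration.

Waveforms travel as two-column CSV (``time_s,amp_mv``) with a uniform time
base; a :class:`RunConfig` bundles the seed and every stage's parameters and
round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .errors import FormatError
from .overlay import PreampParams
from .recording import EgmRecording
from .sensing import DetectionParams, SensingParams

__all__ = ["read_waveform_csv", "write_waveform_csv", "RunConfig"]

_HEADER = ["time_s", "amp_mv"]


def read_waveform_csv(path: str | Path) -> EgmRecording:
    """Read a ``time_s,amp_mv`` CSV into a recording, inferring the sampling rate.

    The time column must be strictly increasing and uniform: the maximum
    timestamp jitter must stay below 1% of the mean sample interval.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if list(df.columns) != _HEADER:
        raise FormatError(f"{path}: expected header {','.join(_HEADER)!r}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based numbering
        raise FormatError(f"{path}: non-monotone time at line {bad[0] + 2}")
    mean_dt = float(dt.mean())
    jitter = np.abs(dt - mean_dt)
    bad = np.flatnonzero(jitter >= 0.01 * mean_dt)
    if bad.size:
        raise FormatError(f"{path}: non-uniform sample interval at line {bad[0] + 2}")
    return EgmRecording(
        samples=df["amp_mv"].to_numpy(dtype=float), fs=1.0 / mean_dt, label=path.name
    )


def write_waveform_csv(rec: EgmRecording, path: str | Path) -> None:
    """Write a recording as ``time_s,amp_mv`` CSV (6-decimal amplitudes)."""
    df = pd.DataFrame({"time_s": rec.times_s, "amp_mv": rec.samples})
    df.to_csv(path, index=False, float_format="%.6f")


class RunConfig(BaseModel):
    """Complete, serializable description of a simulation run.

    Unknown keys are rejected on load; a YAML round-trip is the identity.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int = 0
    sensing: SensingParams = SensingParams()
    detection: DetectionParams = DetectionParams()
    preamp: PreampParams = PreampParams()
    grid_widths_ms: tuple[float, ...] = (0.24, 0.40, 1.00)
    grid_amps_mv: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)
    grid_rates_ppm: tuple[float, ...] = (60.0, 90.0, 150.0, 180.0)
    mc_n_samples: int = 50_000
    mc_threshold_mm: float = 35.0
    mc_truncate_low_mm: float | None = None

    def to_yaml(self, path: str | Path) -> None:
        payload = self.model_dump()
        for key in ("sensing", "detection", "preamp"):
            payload[key] = asdict(getattr(self, key))
        for key in ("grid_widths_ms", "grid_amps_mv", "grid_rates_ppm"):
            payload[key] = list(payload[key])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise FormatError(f"{path}: expected a mapping at top level")
        for key, typ in (("sensing", SensingParams), ("detection", DetectionParams), ("preamp", PreampParams)):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = typ(**payload[key])
        return cls(**payload)
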