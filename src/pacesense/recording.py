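"""The electrogram (EGM) container that flows through every signal stage.

An :class:`EgmRecording` is a uniformly sampled amplitude series in millivolts
together with its sampling rate.  Device-rate signals in this package are
sampled at 256 Hz, the rate at which extravascular-ICD episode recordings are
stored; higher internal rates appear only transiently inside the pacing
overlay stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError

DEVICE_FS_HZ = 256.0


@dataclass(frozen=True)
class EgmRecording:
    """A uniformly sampled millivolt waveform.

    Parameters
    ----------
    samples
        Amplitude series in mV.  At least two samples, all finite.
    fs
        Sampling rate in Hz, strictly positive.
    label
        Free-text provenance annotation.
    markers
        Optional ``(time_s, tag)`` annotations, e.g. true pacing-pulse times.
    """

    samples: np.ndarray
    fs: float = DEVICE_FS_HZ
    label: str = ""
    markers: tuple[tuple[float, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ParameterError("samples must be a 1-D array of length >= 2")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("samples must all be finite")
        if not (self.fs > 0):
            raise ParameterError("fs must be > 0")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "markers", tuple(self.markers))

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray, **kwargs) -> "EgmRecording":
        """Return a copy with ``samples`` (and any other fields) replaced."""
        return replace(self, samples=samples, **kwargs)
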