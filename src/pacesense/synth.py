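"""Seeded generators for every input the study data would otherwise provide.

Three families of inputs are produced here:

* **VF episodes** — short (6–10 s) ventricular-fibrillation electrograms at the
  256 Hz device rate.  The waveform model is a train of biphasic intracardiac
  deflections with cycle-to-cycle frequency jitter, per-cycle amplitude
  modulation and additive band-limited noise.  It reproduces the amplitude and
  interval statistics a sense amplifier consumes without claiming
  physiological fidelity: sensed VF amplitudes span 0.15–1.0 mV with a
  reference mean of 0.86 mV, and mean cycle lengths fall in the 140–330 ms
  range typical of VF.
* **Implant-distance pairs** — (D1, D2) inter-electrode distances in mm drawn
  from a multivariate normal, the population model used for Monte Carlo risk
  estimation.
* **Pacing programs** — programmed pacemaker outputs whose amplitude
  distribution is calibrated to real-world programming prevalence anchors:
  90.5% of devices at or below 1 V and 96.5% at or below 3 V (at 0.24 ms).

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import ParameterError
from .geometry import DistancePair
from .recording import DEVICE_FS_HZ, EgmRecording

__all__ = [
    "VfModelParams",
    "PacingProgram",
    "DEFAULT_AMPLITUDE_PMF",
    "generate_vf_episode",
    "generate_episode_library",
    "sample_distance_pairs",
    "sample_pacing_programs",
    "quantize_8bit",
]


@dataclass(frozen=True)
class VfModelParams:
    """Parameters of the synthetic VF waveform model.

    ``dominant_freq_hz`` is the mean VF cycle frequency (4.5 Hz gives a
    222 ms mean cycle length); ``freq_jitter`` the relative std of
    cycle-to-cycle frequency; ``target_mean_amp_mv`` the mean per-cycle peak
    amplitude; ``amp_cv`` its coefficient of variation; ``noise_rms_mv`` the
    RMS of additive band-limited noise; ``deflection_width_frac`` the width
    (Gaussian sigma) of each biphasic deflection as a fraction of its cycle.
    """

    target_mean_amp_mv: float = 0.86
    dominant_freq_hz: float = 4.5
    freq_jitter: float = 0.15
    amp_cv: float = 0.2
    noise_rms_mv: float = 0.02
    duration_s: float = 8.0
    seed: int = 0
    fs: float = DEVICE_FS_HZ
    deflection_width_frac: float = 0.05

    def __post_init__(self) -> None:
        if not (self.target_mean_amp_mv > 0):
            raise ParameterError("target_mean_amp_mv must be > 0")
        if not (0 <= self.amp_cv < 1):
            raise ParameterError("amp_cv must be in [0, 1)")
        if not (0 <= self.freq_jitter < 1):
            raise ParameterError("freq_jitter must be in [0, 1)")
        if self.noise_rms_mv < 0:
            raise ParameterError("noise_rms_mv must be >= 0")
        if not (self.dominant_freq_hz > 0 and self.fs > 0):
            raise ParameterError("dominant_freq_hz and fs must be > 0")
        if self.duration_s * self.dominant_freq_hz < 2:
            raise ParameterError("duration_s too short: fewer than two VF cycles")
        if not (0 < self.deflection_width_frac < 0.25):
            raise ParameterError("deflection_width_frac must be in (0, 0.25)")


@dataclass(frozen=True)
class PacingProgram:
    """A programmed pacemaker output: amplitude (V), pulse width (ms), rate (ppm)."""

    amplitude_v: float
    pulse_width_ms: float = 0.24
    rate_ppm: float = 60.0

    def __post_init__(self) -> None:
        if not (self.amplitude_v > 0 and self.pulse_width_ms > 0 and self.rate_ppm > 0):
            raise ParameterError("amplitude_v, pulse_width_ms and rate_ppm must be > 0")


def _cycle_shape(n: int, sigma_frac: float) -> np.ndarray:
    """One VF cycle on ``n`` samples: a biphasic (Gaussian-derivative) deflection
    centred in the cycle, normalized to unit peak amplitude."""
    u = np.arange(n) / n
    d = u - 0.5
    sigma = sigma_frac
    w = -d * np.exp(-(d**2) / (2 * sigma**2))
    # |w| peaks at |d| = sigma with value sigma * exp(-1/2)
    return w / (sigma * math.exp(-0.5))


def generate_vf_episode(params: VfModelParams) -> EgmRecording:
    """Generate one synthetic VF episode at the device rate.

    The episode is built cycle by cycle.  Cycle lengths are realized in whole
    samples from a jittered dominant frequency; per-cycle peak amplitudes are
    drawn with coefficient of variation ``amp_cv`` and rescaled so their mean
    equals ``target_mean_amp_mv`` exactly before noise is added.  Reproducible
    for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n_total = int(round(params.duration_s * params.fs))

    # Draw enough cycles to cover the episode.
    n_cycles_max = int(math.ceil(params.duration_s * params.dominant_freq_hz * 3)) + 4
    freq = params.dominant_freq_hz * (
        1.0 + params.freq_jitter * rng.standard_normal(n_cycles_max)
    )
    freq = np.clip(freq, 0.5 * params.dominant_freq_hz, 1.5 * params.dominant_freq_hz)
    cycle_len = np.maximum(np.round(params.fs / freq).astype(int), 4)

    amps = params.target_mean_amp_mv * (
        1.0 + params.amp_cv * rng.standard_normal(n_cycles_max)
    )
    amps = np.clip(amps, 0.1 * params.target_mean_amp_mv, None)
    amps *= params.target_mean_amp_mv / amps.mean()

    pieces = []
    total = 0
    for n_i, a_i in zip(cycle_len, amps):
        pieces.append(a_i * _cycle_shape(int(n_i), params.deflection_width_frac))
        total += int(n_i)
        if total >= n_total:
            break
    x = np.concatenate(pieces)[:n_total]

    if params.noise_rms_mv > 0:
        noise = rng.standard_normal(n_total)
        sos = signal.butter(2, [1.0, 40.0], btype="bandpass", fs=params.fs, output="sos")
        noise = signal.sosfilt(sos, noise)
        noise *= params.noise_rms_mv / max(np.sqrt(np.mean(noise**2)), 1e-30)
        x = x + noise

    label = f"synthetic VF (target {params.target_mean_amp_mv:.3f} mV, seed {params.seed})"
    return EgmRecording(samples=x, fs=params.fs, label=label)


def generate_episode_library(
    n: int,
    amp_range_mv: tuple[float, float],
    base: VfModelParams | None = None,
    seed: int = 0,
) -> list[EgmRecording]:
    """Generate ``n`` VF episodes with target mean amplitudes drawn uniformly
    from ``amp_range_mv`` and durations drawn uniformly from 6–10 s.

    Episode ``i`` is seeded deterministically from ``(seed, i)``, so libraries
    are reproducible element-wise and insensitive to the order of generation.
    """
    low, high = amp_range_mv
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not (0 < low < high):
        raise ParameterError("amplitude range must satisfy 0 < low < high")
    base = base or VfModelParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA3E]))
    targets = rng.uniform(low, high, size=n)
    durations = rng.uniform(6.0, 10.0, size=n)
    out = []
    for i in range(n):
        ep_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        p = replace(
            base,
            target_mean_amp_mv=float(targets[i]),
            duration_s=float(durations[i]),
            seed=ep_seed,
        )
        out.append(generate_vf_episode(p))
    return out


def sample_distance_pairs(
    n: int,
    mean: tuple[float, float],
    cov: np.ndarray,
    seed: int = 0,
) -> list[DistancePair]:
    """Draw ``n`` (D1, D2) implant-distance pairs (mm) from a multivariate normal.

    Negative draws are retained; truncation at a feasibility bound is a caller
    decision made in the risk module.
    """
    mean_arr = np.asarray(mean, dtype=float)
    cov_arr = np.asarray(cov, dtype=float)
    if cov_arr.shape != (2, 2) or mean_arr.shape != (2,):
        raise ParameterError("mean must be a 2-vector and cov a 2x2 matrix")
    if not np.allclose(cov_arr, cov_arr.T, atol=1e-10):
        raise ParameterError("cov must be symmetric")
    if np.min(np.linalg.eigvalsh(cov_arr)) < -1e-10:
        raise ParameterError("cov must be positive semi-definite")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(mean_arr, cov_arr, size=n, method="svd")
    return [DistancePair(float(d1), float(d2), allow_negative=True) for d1, d2 in draws]


#: Default programmed-amplitude distribution at 0.24 ms pulse width, calibrated
#: to real-world programming prevalence: P(<= 1.0 V) = 0.905, P(<= 3.0 V) = 0.965.
DEFAULT_AMPLITUDE_PMF: dict[float, float] = {
    0.5: 0.305,
    1.0: 0.600,
    1.5: 0.030,
    2.0: 0.015,
    3.0: 0.015,
    5.0: 0.035,
}


def sample_pacing_programs(
    n: int,
    seed: int = 0,
    amplitude_pmf: dict[float, float] | None = None,
    pulse_width_ms: float = 0.24,
    rate_ppm: float = 60.0,
) -> list[PacingProgram]:
    """Sample ``n`` pacing programs from a discrete amplitude distribution.

    The default distribution places its cumulative mass at the two prevalence
    anchors: 90.5% of programs at or below 1.0 V and 96.5% at or below 3.0 V.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    pmf = amplitude_pmf if amplitude_pmf is not None else DEFAULT_AMPLITUDE_PMF
    amps = np.array(sorted(pmf), dtype=float)
    probs = np.array([pmf[a] for a in amps], dtype=float)
    if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ParameterError("amplitude_pmf must be a probability distribution summing to 1")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(amps, size=n, p=probs)
    return [PacingProgram(float(a), pulse_width_ms, rate_ppm) for a in drawn]


def quantize_8bit(rec: EgmRecording, full_scale_mv: float = 8.0) -> EgmRecording:
    """Quantize a recording to 256 uniform levels over ±``full_scale_mv``.

    Samples are clipped at the rails; the maximum quantization error for
    in-range samples is one half LSB (``full_scale_mv / 255``).
    """
    if not (full_scale_mv > 0):
        raise ParameterError("full_scale_mv must be > 0")
    step = 2.0 * full_scale_mv / 255.0
    idx = np.clip(np.round((rec.samples + full_scale_mv) / step), 0, 255)
    q = -full_scale_mv + idx * step
    return rec.with_samples(q, label=rec.label + " [8-bit]")
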