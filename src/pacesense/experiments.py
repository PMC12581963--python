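"""Sweep harnesses for the in-silico detection studies.

Each harness takes a library of VF episodes, loops every episode to 60 s,
superimposes an asynchronous pacing train (random, seeded phase per episode)
and runs the frozen detector, producing the study's result surfaces:

* ``run_grid`` — percentage of episodes detected over a (rate, amplitude,
  pulse-width) grid, with the no-pacing baseline;
* ``detection_vs_ratio`` — detection percentage as a function of the
  spike-to-VF amplitude ratio, the study's key undersensing covariate;
* ``timing_vs_ratio`` — mean and interquartile range of time to detection and
  time to therapy over detected episodes;
* ``closest_case_table`` — detect/no-detect outcomes for the bench-measured
  pacing outputs of the closest (anatomically unrealistic) device placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .looping import loop_episode
from .overlay import OverlaySpec, PreampParams, compute_ratio, overlay_pacing
from .recording import EgmRecording
from .sensing import DetectionParams, DetectionResult, SensingParams, run_detector
from .synth import VfModelParams, generate_vf_episode

__all__ = [
    "DetectionGrid",
    "CLOSEST_CASE_PROGRAMS",
    "run_grid",
    "detection_vs_ratio",
    "timing_vs_ratio",
    "closest_case_table",
]

LOOP_DURATION_S = 60.0

#: Programmed outputs and bench-measured sensed spike amplitudes (mV) for the
#: closest-case device placement: (programmed amplitude V, pulse width ms,
#: sensed spike amplitude mV).  Inputs to the closest-case study.
CLOSEST_CASE_PROGRAMS: tuple[tuple[float, float, float], ...] = (
    (5.0, 1.00, 6.04),
    (5.0, 0.40, 3.75),
    (5.0, 0.24, 2.26),
    (3.0, 1.00, 5.46),
    (3.0, 0.40, 2.13),
    (3.0, 0.24, 1.39),
    (2.0, 1.00, 3.67),
    (2.0, 0.40, 1.71),
    (2.0, 0.24, 1.09),
    (1.5, 1.00, 2.90),
    (1.5, 0.40, 1.26),
    (1.5, 0.24, 0.82),
)


@dataclass(frozen=True)
class DetectionGrid:
    """Detection percentages over (rate, amplitude, width) cells.

    ``cells[i, j, k]`` is the percentage of episodes detected at
    ``rates_ppm[i]``, ``amps_mv[j]`` (sensed spike amplitude), ``widths_ms[k]``.
    ``baseline_pct`` is detection with no pacing on the identical library.
    """

    rates_ppm: tuple[float, ...]
    amps_mv: tuple[float, ...]
    widths_ms: tuple[float, ...]
    cells: np.ndarray
    n_episodes: int
    baseline_pct: float

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, r in enumerate(self.rates_ppm):
            for j, a in enumerate(self.amps_mv):
                for k, w in enumerate(self.widths_ms):
                    recs.append(
                        {
                            "rate_ppm": r,
                            "spike_amp_mv": a,
                            "pulse_width_ms": w,
                            "pct_detected": self.cells[i, j, k],
                        }
                    )
        return pd.DataFrame(recs)


def _prepare(library: list[EgmRecording]) -> list[EgmRecording]:
    if not library:
        raise ParameterError("episode library must be non-empty")
    return [loop_episode(e, LOOP_DURATION_S) for e in library]


def _phase_fractions(n: int, seed: int) -> np.ndarray:
    """One random pacing-phase fraction per episode, stable across cells so
    that detection is comparable (and monotone in amplitude) cell-to-cell."""
    return np.random.default_rng(np.random.SeedSequence([seed, 0x9A])).uniform(0.0, 1.0, n)


def _detect_overlaid(
    ep: EgmRecording,
    spec: OverlaySpec,
    sp: SensingParams,
    dp: DetectionParams,
    preamp: PreampParams,
) -> DetectionResult:
    return run_detector(overlay_pacing(ep, spec, preamp), sp, dp)


def run_grid(
    library: list[EgmRecording],
    widths_ms: list[float],
    amps_mv: list[float],
    rates_ppm: list[float],
    sp: SensingParams | None = None,
    dp: DetectionParams | None = None,
    seed: int = 0,
    preamp: PreampParams | None = None,
) -> DetectionGrid:
    """Percentage of episodes detected per (rate, sensed amplitude, width) cell.

    A zero amplitude means no overlay, so that column equals the baseline
    exactly.
    """
    if not (widths_ms and amps_mv and rates_ppm):
        raise ParameterError("all grid axes must be non-empty")
    sp = sp or SensingParams()
    dp = dp or DetectionParams()
    preamp = preamp or PreampParams()
    looped = _prepare(library)
    n = len(looped)
    phases = _phase_fractions(n, seed)
    baseline = [run_detector(e, sp, dp).detected for e in looped]
    baseline_pct = 100.0 * sum(baseline) / n

    cells = np.zeros((len(rates_ppm), len(amps_mv), len(widths_ms)))
    for i, rate in enumerate(rates_ppm):
        for j, amp in enumerate(amps_mv):
            for k, width in enumerate(widths_ms):
                if amp == 0:
                    cells[i, j, k] = baseline_pct
                    continue
                det = 0
                for e, frac in zip(looped, phases):
                    spec = OverlaySpec(
                        rate_ppm=rate,
                        spike_amp_mv=amp,
                        pulse_width_ms=width,
                        phase_s=frac * 60.0 / rate,
                    )
                    det += _detect_overlaid(e, spec, sp, dp, preamp).detected
                cells[i, j, k] = 100.0 * det / n
    return DetectionGrid(
        tuple(rates_ppm), tuple(amps_mv), tuple(widths_ms), cells, n, baseline_pct
    )


def detection_vs_ratio(
    library: list[EgmRecording],
    ratios: list[float],
    rate_ppm: float,
    width_ms: float,
    sp: SensingParams | None = None,
    dp: DetectionParams | None = None,
    seed: int = 0,
    preamp: PreampParams | None = None,
) -> list[tuple[float, float]]:
    """Detection percentage at each spike-to-VF amplitude ratio.

    The spike amplitude is set per episode to ``ratio`` times that episode's
    own mean VF amplitude; ratio 0 is the no-pacing baseline.
    """
    sp = sp or SensingParams()
    dp = dp or DetectionParams()
    preamp = preamp or PreampParams()
    looped = _prepare(library)
    n = len(looped)
    phases = _phase_fractions(n, seed)
    curve = []
    for ratio in ratios:
        if ratio == 0:
            det = sum(run_detector(e, sp, dp).detected for e in looped)
        else:
            det = 0
            for e, frac in zip(looped, phases):
                spec = OverlaySpec(
                    rate_ppm=rate_ppm,
                    ratio=ratio,
                    pulse_width_ms=width_ms,
                    phase_s=frac * 60.0 / rate_ppm,
                )
                det += _detect_overlaid(e, spec, sp, dp, preamp).detected
        curve.append((ratio, 100.0 * det / n))
    return curve


def timing_vs_ratio(
    library: list[EgmRecording],
    ratios: list[float],
    rate_ppm: float,
    sp: SensingParams | None = None,
    dp: DetectionParams | None = None,
    seed: int = 0,
    width_ms: float = 1.0,
    preamp: PreampParams | None = None,
) -> pd.DataFrame:
    """Time-to-detection and time-to-therapy statistics over detected episodes.

    Returns one row per ratio with the mean and interquartile range of
    ``t_detect`` and ``t_therapy`` over episodes that were detected; rows with
    zero detections carry NaN statistics (absent, not an error).
    ``t_therapy - t_detect`` equals the charge time exactly by construction.
    """
    sp = sp or SensingParams()
    dp = dp or DetectionParams()
    preamp = preamp or PreampParams()
    looped = _prepare(library)
    phases = _phase_fractions(len(looped), seed)
    rows = []
    for ratio in ratios:
        tds = []
        for e, frac in zip(looped, phases):
            if ratio == 0:
                res = run_detector(e, sp, dp)
            else:
                spec = OverlaySpec(
                    rate_ppm=rate_ppm,
                    ratio=ratio,
                    pulse_width_ms=width_ms,
                    phase_s=frac * 60.0 / rate_ppm,
                )
                res = _detect_overlaid(e, spec, sp, dp, preamp)
            if res.detected:
                tds.append(res.t_detect_s)
        tds_arr = np.asarray(tds)
        row = {"ratio": ratio, "n_detected": len(tds)}
        if tds_arr.size:
            q25, q75 = np.percentile(tds_arr, [25, 75])
            row.update(
                t_detect_mean_s=float(np.mean(tds_arr)),
                t_detect_q25_s=float(q25),
                t_detect_q75_s=float(q75),
                t_therapy_mean_s=float(np.mean(tds_arr)) + dp.charge_time_s,
                t_therapy_q25_s=float(q25) + dp.charge_time_s,
                t_therapy_q75_s=float(q75) + dp.charge_time_s,
            )
        else:
            row.update(
                t_detect_mean_s=np.nan,
                t_detect_q25_s=np.nan,
                t_detect_q75_s=np.nan,
                t_therapy_mean_s=np.nan,
                t_therapy_q25_s=np.nan,
                t_therapy_q75_s=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def closest_case_table(
    vf_amp_mv: float = 0.86,
    sensed_spikes: tuple[tuple[float, float, float], ...] = CLOSEST_CASE_PROGRAMS,
    sp: SensingParams | None = None,
    dp: DetectionParams | None = None,
    seed: int = 0,
    rate_ppm: float = 80.0,
    preamp: PreampParams | None = None,
) -> pd.DataFrame:
    """Detect/no-detect outcomes for each programmed output at the closest case.

    A synthetic VF episode at ``vf_amp_mv`` mean amplitude is looped to 60 s;
    for each (programmed amplitude, pulse width, sensed spike amplitude) row a
    pacing train at ``rate_ppm`` with that sensed amplitude is superimposed and
    the detector is run.  The reported ratio is sensed spike over ``vf_amp_mv``
    to two decimals.
    """
    if not (vf_amp_mv > 0):
        raise ParameterError("vf_amp_mv must be > 0")
    sp = sp or SensingParams()
    dp = dp or DetectionParams()
    preamp = preamp or PreampParams()
    ep_seed = int(np.random.SeedSequence([seed, 0xCC]).generate_state(1)[0] % (2**31))
    ep = loop_episode(
        generate_vf_episode(VfModelParams(target_mean_amp_mv=vf_amp_mv, seed=ep_seed)),
        LOOP_DURATION_S,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCD]))
    rows = []
    for amp_v, width_ms, sensed_mv in sensed_spikes:
        spec = OverlaySpec(
            rate_ppm=rate_ppm,
            spike_amp_mv=sensed_mv,
            pulse_width_ms=width_ms,
            phase_s=rng.uniform(0.0, 60.0 / rate_ppm),
        )
        res = _detect_overlaid(ep, spec, sp, dp, preamp)
        rows.append(
            {
                "amplitude_v": amp_v,
                "pulse_width_ms": width_ms,
                "sense_egm_mv": sensed_mv,
                "ratio": compute_ratio(sensed_mv, vf_amp_mv),
                "vf_detected": bool(res.detected),
            }
        )
    return pd.DataFrame(rows)
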