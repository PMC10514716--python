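"""EPSC train quantification for voltage-clamp recordings.

Per-condition sweeps (three to seven trials) are averaged pointwise and
all amplitude metrics are computed on the averaged trace.  Each pulse's
amplitude is the peak-to-trough difference between the current at the
light-pulse onset (baseline) and the most negative sample in the
post-pulse search window; amplitudes are reported as positive
magnitudes.  The decay time constant of a pulse is a single-exponential
least-squares fit from the peak sample to the end of the decay window.

Five normalization schemes relate a test train to its control train:

=======================  =====================================================
``first_vs_first``        EPSC_1 / Control_1 (single value)
``train_vs_first_control``EPSC_n / Control_1
``pointwise_vs_control``  EPSC_n / Control_n
``mean_vs_mean``          mean(EPSC) / mean(Control) (single value)
``within_train``          EPSC_n / EPSC_1 (control unused)
=======================  =====================================================

Recordings are excluded when the series resistance exceeds 30 MOhm at
any check or drifts more than 15 % from its first value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .ephys_sim import SweepRecording

__all__ = [
    "NORMALIZATION_SCHEMES",
    "QcResult",
    "NormalizedTrain",
    "EpscTrainMetrics",
    "average_trials",
    "measure_pulse_amplitudes",
    "fit_decay_tau",
    "normalize_train",
    "paired_pulse_ratio",
    "steady_state_ratio",
    "qc_series_resistance",
    "quantify_train",
]

NORMALIZATION_SCHEMES = (
    "first_vs_first",
    "train_vs_first_control",
    "pointwise_vs_control",
    "mean_vs_mean",
    "within_train",
)

RS_MAX_MOHM = 30.0
RS_MAX_DRIFT = 0.15


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reason: str | None = None


@dataclass
class NormalizedTrain:
    scheme: str
    values: np.ndarray
    undefined: np.ndarray  # True where the divisor was zero


@dataclass
class EpscTrainMetrics:
    """Summary metrics of one averaged EPSC train."""

    amplitudes_pa: np.ndarray
    decay_tau_ms: float | None
    ppr: float | None
    steady_state: float | None
    qc: QcResult


def average_trials(sweeps: list[SweepRecording], strict_count: bool = True
                   ) -> SweepRecording:
    """Pointwise mean of 3-7 same-condition sweeps.

    With ``strict_count=False`` trial counts outside 3-7 raise a warning
    instead of an error.  Sweeps must share sample rate, length, pulse
    onsets and condition.
    """
    if not sweeps:
        raise ValueError("no sweeps to average")
    n = len(sweeps)
    if not (3 <= n <= 7):
        msg = f"expected 3-7 trials per condition, got {n}"
        if strict_count:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    ref = sweeps[0]
    for s in sweeps[1:]:
        if s.sample_rate_hz != ref.sample_rate_hz:
            raise ValueError("sweeps have mismatched sample rates")
        if s.current_pa.size != ref.current_pa.size:
            raise ValueError("sweeps have mismatched lengths")
        if not np.array_equal(s.pulse_onsets_s, ref.pulse_onsets_s):
            raise ValueError("sweeps have mismatched pulse onsets")
        if s.condition != ref.condition:
            raise ValueError("sweeps have mismatched conditions")
    mean_trace = np.mean([s.current_pa for s in sweeps], axis=0)
    gts = [s.ground_truth_amplitudes for s in sweeps]
    gt = None
    if all(g is not None for g in gts):
        gt = np.mean(gts, axis=0)
    return SweepRecording(
        current_pa=mean_trace,
        sample_rate_hz=ref.sample_rate_hz,
        pulse_onsets_s=ref.pulse_onsets_s.copy(),
        condition=ref.condition,
        rs_log_mohm=ref.rs_log_mohm.copy(),
        ground_truth_amplitudes=gt,
    )


def _pulse_windows(sweep: SweepRecording, max_search_ms: float
                   ) -> list[tuple[int, int]]:
    fs = sweep.sample_rate_hz
    onsets = sweep.pulse_onsets_s
    windows = []
    for i, onset in enumerate(onsets):
        if i + 1 < onsets.size:
            span = min(onsets[i + 1] - onset, max_search_ms / 1000.0)
        else:
            span = max_search_ms / 1000.0
        i0 = int(round(onset * fs))
        i1 = int(round((onset + span) * fs))
        if i1 > sweep.current_pa.size:
            raise ValueError(
                f"search window of pulse {i} extends past the end of the trace"
            )
        windows.append((i0, i1))
    return windows


def measure_pulse_amplitudes(
    sweep: SweepRecording,
    baseline_mode: str = "window",
    baseline_window_ms: float = 1.0,
    max_search_ms: float = 100.0,
) -> np.ndarray:
    """Peak-to-trough amplitude of each pulse, as positive magnitudes.

    Baseline is the mean over the ``baseline_window_ms`` window ending at
    the pulse onset (``baseline_mode="sample"`` uses the single onset
    sample); the trough is the most negative sample between the onset and
    ``min(inter-pulse interval, max_search_ms)``.
    """
    if sweep.pulse_onsets_s.size == 0:
        raise ValueError("sweep has no pulse onsets")
    if baseline_mode not in ("window", "sample"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    fs = sweep.sample_rate_hz
    x = sweep.current_pa
    nb = max(1, int(round(baseline_window_ms / 1000.0 * fs)))
    amps = []
    for i0, i1 in _pulse_windows(sweep, max_search_ms):
        if baseline_mode == "window" and i0 > 0:
            base = x[max(0, i0 - nb): i0].mean()
        else:
            base = x[i0]
        amps.append(max(base - x[i0:i1].min(), 0.0))
    return np.asarray(amps)


def fit_decay_tau(
    sweep: SweepRecording,
    pulse_index: int = 0,
    max_search_ms: float = 100.0,
    noise_floor_pa: float = 1.0,
) -> float | None:
    """Single-exponential decay time constant (ms) of one pulse.

    Fits ``c + a*exp(-t/tau)`` from the peak sample to the end of the
    decay window by nonlinear least squares, initialized at the 1/e
    crossing time.  Returns ``None`` (flagged) for flat or non-decaying
    segments and for diverging fits.
    """
    windows = _pulse_windows(sweep, max_search_ms)
    if not (0 <= pulse_index < len(windows)):
        raise ValueError(f"pulse_index {pulse_index} out of range")
    i0, i1 = windows[pulse_index]
    x = sweep.current_pa
    peak_idx = i0 + int(np.argmin(x[i0:i1]))
    decay = x[peak_idx:i1]
    if decay.size < 5:
        return None
    c0 = decay[-1]
    a0 = decay[0] - c0  # negative for an inward EPSC
    if -a0 < noise_floor_pa:
        return None  # flat or non-decaying segment
    t_ms = np.arange(decay.size) / sweep.sample_rate_hz * 1000.0
    # 1/e crossing for the initial tau guess
    target = c0 + a0 / np.e
    above = np.nonzero(decay >= target)[0]
    tau0 = t_ms[above[0]] if above.size and above[0] > 0 else t_ms[-1] / 3.0
    tau0 = max(tau0, t_ms[1])

    def model(t, a, tau, c):
        return c + a * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(
            model, t_ms, decay, p0=[a0, tau0, c0],
            bounds=([-np.inf, 1e-6, -np.inf], [0.0, np.inf, np.inf]),
            maxfev=10_000, xtol=1e-10, ftol=1e-10,
        )
    except (RuntimeError, ValueError):
        return None
    tau = float(popt[1])
    return tau if tau > 0 else None


def normalize_train(
    test_amplitudes: np.ndarray,
    control_amplitudes: np.ndarray | None,
    scheme: str,
) -> NormalizedTrain:
    """Normalize a test train against its control under one scheme."""
    if scheme not in NORMALIZATION_SCHEMES:
        raise ValueError(
            f"unknown scheme {scheme!r}; expected one of {NORMALIZATION_SCHEMES}"
        )
    test = np.asarray(test_amplitudes, dtype=float)
    if scheme != "within_train":
        if control_amplitudes is None:
            raise ValueError(f"scheme {scheme!r} requires control amplitudes")
        control = np.asarray(control_amplitudes, dtype=float)

    def _div(num, den):
        num = np.atleast_1d(np.asarray(num, dtype=float))
        den = np.atleast_1d(np.asarray(den, dtype=float))
        bad = den == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
        return vals, np.broadcast_to(bad, vals.shape).copy()

    if scheme == "first_vs_first":
        vals, bad = _div(test[0], control[0])
    elif scheme == "train_vs_first_control":
        vals, bad = _div(test, control[0])
    elif scheme == "pointwise_vs_control":
        if test.size != control.size:
            raise ValueError("pointwise_vs_control requires equal train lengths")
        vals, bad = _div(test, control)
    elif scheme == "mean_vs_mean":
        vals, bad = _div(test.mean(), control.mean())
    else:  # within_train
        vals, bad = _div(test, test[0])
    return NormalizedTrain(scheme=scheme, values=vals, undefined=bad)


def paired_pulse_ratio(amplitudes: np.ndarray) -> float | None:
    """A2/A1; ``None`` (flagged) when A1 is zero."""
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 2:
        raise ValueError("paired-pulse ratio requires at least 2 pulses")
    if amps[0] == 0:
        return None
    return float(amps[1] / amps[0])


def steady_state_ratio(amplitudes: np.ndarray, n_last: int = 3) -> float:
    """Mean of the last ``n_last`` amplitudes relative to the first."""
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size <= n_last:
        raise ValueError(
            f"train of {amps.size} pulses is too short for n_last={n_last}"
        )
    if amps[0] == 0:
        raise ValueError("first amplitude is zero; steady-state ratio undefined")
    return float(amps[-n_last:].mean() / amps[0])


def qc_series_resistance(
    rs_log_mohm: np.ndarray,
    max_mohm: float = RS_MAX_MOHM,
    max_drift_fraction: float = RS_MAX_DRIFT,
) -> QcResult:
    """Exclusion rule: Rs above 30 MOhm or drifting more than 15 %."""
    rs = np.asarray(rs_log_mohm, dtype=float)
    if rs.size == 0:
        raise ValueError("empty series-resistance log")
    if np.any(rs <= 0):
        raise ValueError("series resistance must be positive")
    if np.any(rs > max_mohm):
        return QcResult(
            False,
            f"series resistance {rs.max():.1f} MOhm above {max_mohm:g} MOhm",
        )
    drift = np.max(np.abs(rs - rs[0])) / rs[0]
    if drift > max_drift_fraction:
        return QcResult(
            False,
            f"series resistance changed {100 * drift:.0f}% "
            f"(limit {100 * max_drift_fraction:g}%)",
        )
    return QcResult(True, None)


def quantify_train(avg_sweep: SweepRecording, n_last: int = 3,
                   **amp_kwargs) -> EpscTrainMetrics:
    """All train metrics of one averaged sweep (amplitudes, tau, PPR, ...)."""
    amps = measure_pulse_amplitudes(avg_sweep, **amp_kwargs)
    tau = fit_decay_tau(avg_sweep, 0)
    ppr = paired_pulse_ratio(amps) if amps.size >= 2 else None
    ss = steady_state_ratio(amps, n_last) if amps.size > n_last else None
    qc = qc_series_resistance(avg_sweep.rs_log_mohm)
    return EpscTrainMetrics(
        amplitudes_pa=amps, decay_tau_ms=tau, ppr=ppr, steady_state=ss, qc=qc
    )
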