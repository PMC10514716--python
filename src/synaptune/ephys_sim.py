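"""Synthetic voltage-clamp sweeps of optogenetically evoked EPSC trains.

Each sweep is a 10 kHz current trace held at a negative holding current
with inward (negative-going) AMPAR-like EPSCs evoked at the light-pulse
onsets.  Short-term depression follows a single-pool vesicle-depletion
recursion with release fraction ``U`` and recovery time constant
``tau_recovery``; a condition label applies a multiplicative gain to the
postsynaptic amplitude (emulating potentiation by synaptic zinc that a
chelator removes) without touching the presynaptic parameters, so
paired-pulse ratios and steady-state depression are condition-invariant
by construction.

The depletion recursion has a closed-form fixed point

    R_ss = (1 - e) / (1 - (1 - U) e),   e = exp(-dt / tau_recovery),

which downstream tests use as an independent oracle for the simulated
steady-state amplitude ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SynapseModel",
    "SweepRecording",
    "epsc_kernel",
    "depletion_resources",
    "steady_state_depletion",
    "simulate_epsc_train",
    "simulate_rs_log",
    "write_sweep",
    "read_sweep",
]


@dataclass(frozen=True)
class SynapseModel:
    """Generative parameters for one synaptic connection.

    ``base_amplitude_pa`` is the control-condition first-pulse peak;
    ``condition_gain`` maps a condition label to a multiplicative factor
    on the postsynaptic amplitude (e.g. ``{"control": 1.0, "zx1": 0.75}``
    for a ~25 % reduction after zinc chelation).  ``noise_sd_pa`` defaults
    to base_amplitude/20 (first-pulse SNR ~ 20).
    """

    base_amplitude_pa: float = 100.0
    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 15.0
    release_fraction: float = 0.5
    tau_recovery_ms: float = 200.0
    condition_gain: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1.0, "zx1": 0.75}
    )
    noise_sd_pa: float | None = None
    holding_current_pa: float = -50.0

    def __post_init__(self) -> None:
        if self.base_amplitude_pa <= 0:
            raise ValueError("base_amplitude_pa must be positive")
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise ValueError("tau_rise_ms must be smaller than tau_decay_ms")
        if not (0 < self.release_fraction <= 1):
            raise ValueError("release_fraction must lie in (0, 1]")
        if self.noise_sd_pa is None:
            object.__setattr__(self, "noise_sd_pa", self.base_amplitude_pa / 20.0)

    def with_noise(self, noise_sd_pa: float) -> "SynapseModel":
        return replace(self, noise_sd_pa=noise_sd_pa)


@dataclass
class SweepRecording:
    """One voltage-clamp trial (current trace plus acquisition metadata).

    EPSCs are inward at -70 mV, i.e. downward (negative) deflections from
    the holding current.  ``ground_truth_amplitudes`` carries the ideal
    noiseless per-pulse peak magnitudes when the sweep was simulated.
    """

    current_pa: np.ndarray
    sample_rate_hz: float
    pulse_onsets_s: np.ndarray
    condition: str
    rs_log_mohm: np.ndarray
    ground_truth_amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.current_pa = np.asarray(self.current_pa, dtype=float)
        self.pulse_onsets_s = np.asarray(self.pulse_onsets_s, dtype=float)
        self.rs_log_mohm = np.asarray(self.rs_log_mohm, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        duration = self.current_pa.size / self.sample_rate_hz
        if self.pulse_onsets_s.size and (
            self.pulse_onsets_s.min() < 0 or self.pulse_onsets_s.max() >= duration
        ):
            raise ValueError("pulse_onsets_s must lie within the trace duration")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.current_pa.size) / self.sample_rate_hz


def epsc_kernel(
    t_ms: np.ndarray | float,
    tau_rise_ms: float,
    tau_decay_ms: float,
    amplitude_pa: float = 1.0,
) -> np.ndarray:
    """Peak-normalized difference-of-exponentials EPSC waveform.

    Zero at onset, peaks at ``amplitude_pa`` at
    ``t* = tau_r*tau_d/(tau_d - tau_r) * ln(tau_d/tau_r)`` and decays with
    asymptotic time constant ``tau_decay_ms``.  Negative times map to 0.
    """
    if tau_rise_ms >= tau_decay_ms:
        raise ValueError("tau_rise_ms must be smaller than tau_decay_ms")
    if tau_rise_ms <= 0:
        raise ValueError("tau_rise_ms must be positive")
    t = np.asarray(t_ms, dtype=float)
    raw = np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms)
    t_peak = (
        tau_rise_ms * tau_decay_ms / (tau_decay_ms - tau_rise_ms)
        * np.log(tau_decay_ms / tau_rise_ms)
    )
    norm = np.exp(-t_peak / tau_decay_ms) - np.exp(-t_peak / tau_rise_ms)
    out = amplitude_pa * raw / norm
    return np.where(t < 0, 0.0, out)


def depletion_resources(
    pulse_onsets_s: Sequence[float], release_fraction: float, tau_recovery_s: float
) -> np.ndarray:
    """Available-resource fraction R_n at each pulse of a train.

    R_1 = 1;  R_{n+1} = R_n (1-U) e^{-dt/tau} + 1 - e^{-dt/tau}.
    """
    onsets = np.asarray(pulse_onsets_s, dtype=float)
    if onsets.size and np.any(np.diff(onsets) <= 0):
        raise ValueError("pulse onsets must be strictly increasing")
    r = np.ones(onsets.size)
    for i in range(1, onsets.size):
        e = np.exp(-(onsets[i] - onsets[i - 1]) / tau_recovery_s)
        r[i] = r[i - 1] * (1 - release_fraction) * e + 1 - e
    return r


def steady_state_depletion(dt_s: float, release_fraction: float,
                           tau_recovery_s: float) -> float:
    """Analytic fixed point of the depletion recursion at fixed interval."""
    e = np.exp(-dt_s / tau_recovery_s)
    return float((1 - e) / (1 - (1 - release_fraction) * e))


def simulate_epsc_train(
    model: SynapseModel,
    pulse_onsets_s: Sequence[float],
    condition: str = "control",
    seed: int | np.random.Generator = 0,
    sample_rate_hz: float = 10_000.0,
    tail_s: float = 0.3,
    rs_log_mohm: Sequence[float] | None = None,
) -> SweepRecording:
    """Simulate one voltage-clamp sweep of a light-evoked EPSC train.

    The trace is ``holding + sum of kernels`` scaled by the depletion
    recursion and the condition gain, plus white Gaussian noise.  The
    returned sweep carries the ideal noiseless per-pulse amplitudes as
    ground truth (positive magnitudes).
    """
    onsets = np.asarray(pulse_onsets_s, dtype=float)
    if onsets.size == 0:
        raise ValueError("pulse_onsets_s must contain at least one pulse")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("pulse onsets must be strictly increasing")
    if condition not in model.condition_gain:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of "
            f"{sorted(model.condition_gain)}"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    gain = model.condition_gain[condition]
    r = depletion_resources(onsets, model.release_fraction,
                            model.tau_recovery_ms / 1000.0)
    amps = model.base_amplitude_pa * gain * r

    duration_s = onsets[-1] + tail_s
    n = int(round(duration_s * sample_rate_hz))
    trace = np.full(n, model.holding_current_pa, dtype=float)
    # kernel support: 10 decay time constants
    k_len = int(round(10 * model.tau_decay_ms / 1000.0 * sample_rate_hz))
    k_t_ms = np.arange(k_len) / sample_rate_hz * 1000.0
    unit_kernel = epsc_kernel(k_t_ms, model.tau_rise_ms, model.tau_decay_ms, 1.0)
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * sample_rate_hz))
        i1 = min(i0 + k_len, n)
        trace[i0:i1] -= amp * unit_kernel[: i1 - i0]
    if model.noise_sd_pa and model.noise_sd_pa > 0:
        trace = trace + rng.normal(0.0, model.noise_sd_pa, n)

    if rs_log_mohm is None:
        rs_log_mohm = np.full(5, 20.0)
    return SweepRecording(
        current_pa=trace,
        sample_rate_hz=sample_rate_hz,
        pulse_onsets_s=onsets,
        condition=condition,
        rs_log_mohm=np.asarray(rs_log_mohm, dtype=float),
        ground_truth_amplitudes=amps,
    )


def simulate_rs_log(
    stable_value_mohm: float,
    drift_fraction: float,
    n_checks: int,
    seed: int | np.random.Generator | None = None,
    noise_sd_mohm: float = 0.0,
) -> np.ndarray:
    """Series-resistance log with a linear drift of given relative size.

    In noise-free mode the maximum relative change from the first entry
    equals ``drift_fraction`` exactly, so quality-control rules can be
    exercised with known outcomes.
    """
    if stable_value_mohm <= 0:
        raise ValueError("stable_value_mohm must be positive")
    if n_checks < 2:
        raise ValueError("n_checks must be at least 2")
    log = stable_value_mohm * (1.0 + drift_fraction * np.linspace(0, 1, n_checks))
    if noise_sd_mohm > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        log = log + rng.normal(0.0, noise_sd_mohm, n_checks)
    return log


def write_sweep(sweep: SweepRecording, prefix: str | Path) -> None:
    """Write a sweep as ``<prefix>.csv`` (time_s, current_pa) + JSON sidecar."""
    prefix = Path(prefix)
    data = np.column_stack([sweep.time_s, sweep.current_pa])
    np.savetxt(prefix.with_suffix(".csv"), data, delimiter=",",
               header="time_s,current_pa", comments="")
    meta = {
        "sample_rate_hz": sweep.sample_rate_hz,
        "pulse_onsets_s": sweep.pulse_onsets_s.tolist(),
        "condition": sweep.condition,
        "rs_log_mohm": sweep.rs_log_mohm.tolist(),
        "ground_truth_amplitudes": (
            None if sweep.ground_truth_amplitudes is None
            else np.asarray(sweep.ground_truth_amplitudes).tolist()
        ),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_sweep(prefix: str | Path) -> SweepRecording:
    """Read a sweep written by :func:`write_sweep`."""
    prefix = Path(prefix)
    data = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", skiprows=1)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    gt = meta.get("ground_truth_amplitudes")
    return SweepRecording(
        current_pa=data[:, 1],
        sample_rate_hz=meta["sample_rate_hz"],
        pulse_onsets_s=np.asarray(meta["pulse_onsets_s"]),
        condition=meta["condition"],
        rs_log_mohm=np.asarray(meta["rs_log_mohm"]),
        ground_truth_amplitudes=None if gt is None else np.asarray(gt),
    )
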