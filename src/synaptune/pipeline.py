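"""Seeded end-to-end experiments composing the simulators and analyses.

Two desk-scale tracks mirror the study designs the package quantifies:

* ``ephys`` — simulate a cohort of cells, each recorded in a control and
  a chelator condition (multiplicative amplitude gain), average trials,
  quantify EPSC trains, apply series-resistance QC, normalize under the
  requested schemes and run the paired group statistics.

* ``imaging`` — build a tone block, simulate a cohort of neurons before
  and after an "infusion" that scales the tuning bandwidth, extract
  tuning metrics (BF, threshold, Q20, d-prime) and test the paired Q20
  change with the signed-rank test.

A master seed spawns per-stage child seeds deterministically, so a
bundle is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .ephys import (
    NORMALIZATION_SCHEMES,
    average_trials,
    normalize_train,
    quantify_train,
)
from .ephys_sim import SynapseModel, simulate_epsc_train, simulate_rs_log
from .imaging import build_tuning_surface, quantify_tuning, select_top_fraction
from .imaging_sim import ReceptiveFieldModel, simulate_roi_traces
from .stats import holm_bonferroni, paired_compare
from .stimulus import build_tone_block

__all__ = [
    "ExperimentConfig",
    "run_ephys_experiment",
    "run_imaging_experiment",
    "run_experiment",
]


@dataclass
class ExperimentConfig:
    """Flat, serializable configuration of one experiment run."""

    track: str = "ephys"
    seed: int = 0
    alpha: float = 0.05
    # --- ephys track ---
    n_cells: int = 6
    n_trials: int = 4
    train_rate_hz: float = 10.0
    n_pulses: int = 10
    condition_gain: float = 0.75
    cell_amplitude_sd: float = 0.2
    noise_snr: float = 20.0
    n_qc_fail_cells: int = 0
    n_last_steady: int = 3
    # --- imaging track ---
    n_neurons: int = 40
    n_repeats: int = 5
    bandwidth_gain: float = 1.25
    z_thresh: float = 0.6
    min_consec: int = 2
    imaging_noise_sd: float = 0.12
    neuron_amplitude_sd: float = 0.6
    top_fraction: float = 0.20

    def __post_init__(self) -> None:
        if self.track not in ("ephys", "imaging"):
            raise ValueError(f"unknown track {self.track!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict) or any(isinstance(v, (dict, list))
                                          for v in d.values()):
            raise ValueError("config must be a flat key: value mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)


def _manifest(config: ExperimentConfig) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True)
    return {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "package_version": __version__,
    }


def _log(msg: str, verbose: bool) -> None:
    if verbose:
        print(msg, file=sys.stderr)


def run_ephys_experiment(config: ExperimentConfig, out_dir: str | Path | None
                         = None, verbose: bool = False) -> dict:
    """Simulate and analyze a paired control-vs-chelator EPSC cohort.

    Returns a bundle with per-cell metrics, normalized trains under every
    scheme, group statistics (Holm-corrected per-pulse comparisons) and a
    manifest.  QC-failing cells are excluded from the group statistics
    and listed under ``excluded``.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_cells)
    onsets = 0.1 + np.arange(config.n_pulses) / config.train_rate_hz
    conditions = ("control", "zx1")

    metric_rows, norm_rows, excluded = [], [], []
    amp_by_cell: dict[int, dict[str, np.ndarray]] = {}
    for i in range(config.n_cells):
        rng = np.random.default_rng(children[i])
        base = 100.0 * rng.lognormal(0.0, config.cell_amplitude_sd)
        model = SynapseModel(
            base_amplitude_pa=base,
            noise_sd_pa=base / config.noise_snr,
            condition_gain={"control": 1.0, "zx1": config.condition_gain},
        )
        qc_fail = i >= config.n_cells - config.n_qc_fail_cells
        rs_log = simulate_rs_log(20.0, 0.20 if qc_fail else 0.0, 5)
        amps = {}
        for cond in conditions:
            sweeps = [
                simulate_epsc_train(model, onsets, cond, rng,
                                    rs_log_mohm=rs_log)
                for _ in range(config.n_trials)
            ]
            avg = average_trials(sweeps, strict_count=False)
            m = quantify_train(avg, n_last=config.n_last_steady)
            amps[cond] = m.amplitudes_pa
            metric_rows.append({
                "cell": i, "condition": cond,
                "a1_pa": m.amplitudes_pa[0],
                "ppr": m.ppr, "steady_state": m.steady_state,
                "decay_tau_ms": m.decay_tau_ms,
                "qc_pass": m.qc.passed, "qc_reason": m.qc.reason,
            })
            if not m.qc.passed and cond == conditions[0]:
                excluded.append({"cell": i, "reason": m.qc.reason})
                _log(f"cell {i} excluded: {m.qc.reason}", verbose)
        if all(r["qc_pass"] for r in metric_rows[-2:]):
            amp_by_cell[i] = amps
        for scheme in NORMALIZATION_SCHEMES:
            nt = normalize_train(amps["zx1"], amps["control"], scheme)
            for j, v in enumerate(np.atleast_1d(nt.values)):
                norm_rows.append({"cell": i, "scheme": scheme, "pulse": j,
                                  "value": v})
        _log(f"cell {i} done", verbose)

    metrics = pd.DataFrame(metric_rows)
    normalized = pd.DataFrame(norm_rows)

    kept = sorted(amp_by_cell)
    a1_control = np.array([amp_by_cell[i]["control"][0] for i in kept])
    a1_zx1 = np.array([amp_by_cell[i]["zx1"][0] for i in kept])
    stats_rows = []
    first = paired_compare(a1_control, a1_zx1, alpha=config.alpha)
    stats_rows.append({"comparison": "first_epsc", "test": first.test_name,
                       "statistic": first.statistic, "p": first.p_value,
                       "n": first.n})
    pulse_ps = []
    for p_idx in range(config.n_pulses):
        c = np.array([amp_by_cell[i]["control"][p_idx] for i in kept])
        z = np.array([amp_by_cell[i]["zx1"][p_idx] for i in kept])
        res = paired_compare(c, z, alpha=config.alpha)
        pulse_ps.append(res.p_value)
        stats_rows.append({"comparison": f"pulse_{p_idx + 1}",
                           "test": res.test_name,
                           "statistic": res.statistic, "p": res.p_value,
                           "n": res.n})
    reject = holm_bonferroni(pulse_ps, alpha=config.alpha)
    for row, rej in zip(stats_rows[1:], reject):
        row["corrected_reject"] = bool(rej)
    stats_rows[0]["corrected_reject"] = bool(
        stats_rows[0]["p"] < config.alpha
    )
    stats = pd.DataFrame(stats_rows)

    bundle = {
        "metrics": metrics,
        "normalized": normalized,
        "stats": stats,
        "excluded": excluded,
        "median_first_vs_first": float(np.median(a1_zx1 / a1_control))
        if kept else float("nan"),
        "manifest": _manifest(config),
    }
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def run_imaging_experiment(config: ExperimentConfig,
                           out_dir: str | Path | None = None,
                           verbose: bool = False) -> dict:
    """Simulate and analyze a paired before/after-infusion tuning cohort.

    The treated condition scales each neuron's tuning bandwidth by
    ``config.bandwidth_gain`` (>1 widens, <1 sharpens).  The headline
    statistic is the Wilcoxon signed-rank test on the paired Q20 change
    across neurons with a defined bandwidth in both conditions.
    """
    ss = np.random.SeedSequence(config.seed)
    block_child, *neuron_children = ss.spawn(config.n_neurons + 1)
    block_seed = int(block_child.generate_state(1)[0] % (2 ** 31))
    block = build_tone_block(5000.0, 40000.0, 0.125,
                             [40.0, 50.0, 60.0, 70.0, 80.0], seed=block_seed)
    freqs = block.frequencies
    conditions = ("control", "treated")

    rows = []
    q20 = {c: np.full(config.n_neurons, np.nan) for c in conditions}
    dp = np.full(config.n_neurons, np.nan)
    resp_both = np.zeros(config.n_neurons, dtype=bool)
    for i in range(config.n_neurons):
        rng = np.random.default_rng(neuron_children[i])
        bf = float(freqs[rng.integers(7, freqs.size - 7)])
        thr = float(rng.choice([40.0, 50.0]))
        peak = 0.5 * rng.lognormal(0.0, config.neuron_amplitude_sd)
        model = ReceptiveFieldModel(
            bf_hz=bf, threshold_db=thr, peak_dff=peak,
            noise_sd=config.imaging_noise_sd,
            condition_bandwidth_gain={"control": 1.0,
                                      "treated": config.bandwidth_gain},
        )
        responsive = []
        for cond in conditions:
            trace, _ = simulate_roi_traces(model, block,
                                           n_repeats=config.n_repeats,
                                           condition=cond, seed=rng)
            surface = build_tuning_surface(trace, z_thresh=config.z_thresh,
                                           min_consec=config.min_consec)
            tm = quantify_tuning(surface)
            rows.append({"neuron": i, "condition": cond, "bf_hz": tm.bf_hz,
                         "threshold_db": tm.threshold_db,
                         "q20_oct": tm.q20_oct, "dprime": tm.dprime,
                         "responsive": tm.is_sound_responsive})
            responsive.append(tm.is_sound_responsive)
            if tm.q20_oct is not None:
                q20[cond][i] = tm.q20_oct
            if cond == "control" and tm.dprime is not None:
                dp[i] = tm.dprime
        resp_both[i] = all(responsive)
        _log(f"neuron {i} done", verbose)

    table = pd.DataFrame(rows)
    paired = resp_both & np.isfinite(q20["control"]) & np.isfinite(
        q20["treated"])
    dq = q20["treated"][paired] - q20["control"][paired]
    if dq.size >= 3 and np.any(dq != 0):
        w = sps.wilcoxon(dq, zero_method="wilcox", correction=True,
                         method="auto")
        signed_rank = {"test": "wilcoxon_signed_rank",
                       "statistic": float(w.statistic),
                       "p": float(w.pvalue), "n": int(dq.size)}
    else:
        signed_rank = {"test": "wilcoxon_signed_rank",
                       "statistic": float("nan"), "p": 1.0,
                       "n": int(dq.size)}
    gated = (paired_compare(q20["treated"][paired], q20["control"][paired],
                            alpha=config.alpha)
             if dq.size >= 3 else None)

    # top-fraction bandwidth subset, ranked by control-condition d-prime
    eligible = np.nonzero(paired & np.isfinite(dp))[0]
    top_ids = eligible[select_top_fraction(dp[eligible],
                                           config.top_fraction)] \
        if eligible.size else np.array([], dtype=int)

    cdf = {c: np.sort(q20[c][paired]).tolist() for c in conditions}
    paired_idx = np.nonzero(paired)[0]
    dq_top = dq[np.isin(paired_idx, top_ids)]
    bundle = {
        "table": table,
        "delta_q20": dq,
        "median_delta_q20": float(np.median(dq)) if dq.size else float("nan"),
        "median_delta_q20_top": float(np.median(dq_top))
        if dq_top.size else float("nan"),
        "signed_rank": signed_rank,
        "gated_compare": gated,
        "top_fraction_ids": top_ids,
        "q20_cdf": cdf,
        "n_paired": int(dq.size),
        "manifest": _manifest(config),
    }
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def run_experiment(config: ExperimentConfig,
                   out_dir: str | Path | None = None,
                   verbose: bool = False) -> dict:
    """Dispatch on ``config.track``."""
    if config.track == "ephys":
        return run_ephys_experiment(config, out_dir, verbose)
    return run_imaging_experiment(config, out_dir, verbose)


def _write_bundle(bundle: dict, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for key, val in bundle.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out_dir / f"{key}.csv", index=False)
    summary = {}
    for key, val in bundle.items():
        if isinstance(val, pd.DataFrame):
            continue
        if isinstance(val, np.ndarray):
            val = val.tolist()
        if hasattr(val, "__dict__") and not isinstance(val, (dict, list)):
            val = {k: v for k, v in vars(val).items()
                   if isinstance(v, (int, float, str, bool, type(None)))}
        summary[key] = val
    (out_dir / "results.json").write_text(json.dumps(summary, indent=2,
                                                     default=str))
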