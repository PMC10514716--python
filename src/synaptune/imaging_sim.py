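"""Synthetic calcium-imaging data with known receptive-field ground truth.

Two generators are provided:

* :func:`simulate_roi_traces` — ROI fluorescence at 5 Hz during repeated
  tone blocks.  The underlying frequency-intensity receptive field is a
  rectangular band in log-frequency per level row (wider at higher
  levels), so the true best frequency, threshold and Q20 bandwidth are
  exact by construction.  A condition label applies a multiplicative
  gain to the bandwidth, emulating tuning widening or sharpening by a
  zinc chelator.  Responsive tones inject a GCaMP-like difference-of-
  exponentials transient onto a flat baseline.

* :func:`simulate_widefield_movie` — a 20 Hz, 200x150-pixel epifluor-
  escence movie with Gaussian sound-responsive blobs (emulating the
  low-frequency regions of A1 and AAF) whose time course follows the
  mapping-tone onsets.

Both return the exact ground truth their detectors should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .stimulus import StimulusBlock

__all__ = [
    "ReceptiveFieldModel",
    "RoiTrace",
    "WidefieldMovie",
    "gcamp_kernel",
    "simulate_roi_traces",
    "simulate_widefield_movie",
]

# grid frequency closest to the geometric middle of the 5-40 kHz span
_DEFAULT_BF = 5000.0 * 2.0 ** 1.5


def gcamp_kernel(t_s: np.ndarray, tau_rise_s: float = 0.1,
                 tau_decay_s: float = 0.4) -> np.ndarray:
    """Peak-normalized difference-of-exponentials calcium transient.

    The default time constants put the peak ~0.19 s after onset, well
    inside the 1-s quantification window used by the tuning analysis.
    """
    if tau_rise_s >= tau_decay_s:
        raise ValueError("tau_rise_s must be smaller than tau_decay_s")
    t = np.asarray(t_s, dtype=float)
    raw = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    t_peak = (tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)
              * np.log(tau_decay_s / tau_rise_s))
    norm = np.exp(-t_peak / tau_decay_s) - np.exp(-t_peak / tau_rise_s)
    return np.where(t < 0, 0.0, raw / norm)


@dataclass(frozen=True)
class ReceptiveFieldModel:
    """Ground-truth frequency-intensity receptive field of one neuron.

    A tone (f, l) is responsive iff ``l >= threshold_db`` and
    ``|log2(f/bf_hz)| <= bandwidth(l) * gain(condition) / 2``, with the
    per-level bandwidth a V-shape widening by ``widen_oct_per_10db``
    octaves per 10 dB above threshold.  Within the responsive band the
    transient amplitude tapers mildly away from the best frequency and
    grows mildly with level, so the (bf, max level) cell is the unique
    response maximum.
    """

    bf_hz: float = _DEFAULT_BF
    threshold_db: float = 50.0
    bw_at_threshold_oct: float = 0.5
    widen_oct_per_10db: float = 0.25
    bandwidth_octaves: Mapping[float, float] | None = None
    peak_dff: float = 0.5
    gcamp_tau_rise_s: float = 0.1
    gcamp_tau_decay_s: float = 0.4
    noise_sd: float = 0.12
    repeat_jitter_sd: float = 0.2
    condition_bandwidth_gain: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1.0, "zx1_100": 1.25, "zx1_300": 0.8}
    )
    level_gain_per_10db: float = 0.05
    freq_taper_per_octave: float = 0.15

    def __post_init__(self) -> None:
        if self.peak_dff < 0:
            raise ValueError("peak_dff must be non-negative")
        if self.bw_at_threshold_oct < 0:
            raise ValueError("bandwidth must be non-negative")

    def bandwidth_at(self, level_db: float) -> float:
        if self.bandwidth_octaves is not None:
            return float(self.bandwidth_octaves[level_db])
        return max(
            0.0,
            self.bw_at_threshold_oct
            + self.widen_oct_per_10db * (level_db - self.threshold_db) / 10.0,
        )

    def ground_truth(self, freqs_hz: np.ndarray, levels_db: np.ndarray,
                     condition: str = "control") -> dict:
        """Responsive mask and closed-form BF/threshold/Q20 on a tone grid.

        Returns a dict with ``mask`` and ``amp`` (levels x frequencies),
        plus ``bf_hz``, ``threshold_db`` and ``q20_oct`` computed exactly
        from the mask (``None`` where undefined, e.g. when threshold+20 dB
        is outside the tested levels).
        """
        freqs = np.asarray(freqs_hz, dtype=float)
        levels = np.asarray(levels_db, dtype=float)
        gain = self.condition_bandwidth_gain[condition]
        dist = np.abs(np.log2(freqs / self.bf_hz))  # octaves from BF
        mask = np.zeros((levels.size, freqs.size), dtype=bool)
        for i, l in enumerate(levels):
            if l < self.threshold_db:
                continue
            half = self.bandwidth_at(l) * gain / 2.0
            mask[i] = dist <= half + 1e-12
        level_factor = 1.0 - self.level_gain_per_10db * (levels.max() - levels) / 10.0
        freq_factor = 1.0 - self.freq_taper_per_octave * dist
        amp = self.peak_dff * np.outer(level_factor, np.clip(freq_factor, 0.05, None))
        amp = np.where(mask, amp, 0.0)

        if self.peak_dff == 0 or not mask.any():
            return {"mask": np.zeros_like(mask), "amp": np.zeros_like(amp),
                    "bf_hz": None, "threshold_db": None, "q20_oct": None}
        flat = np.argmax(amp)  # row-major: ties resolve to the lower frequency
        bf = float(freqs[flat % freqs.size])
        thr = float(levels[mask.any(axis=1)].min())
        q20 = None
        target = thr + 20.0
        hit = np.nonzero(np.isclose(levels, target))[0]
        if hit.size:
            row = mask[hit[0]]
            fr = freqs[row]
            if fr.size:
                q20 = float(np.log2(fr.max() / fr.min()))
        return {"mask": mask, "amp": amp, "bf_hz": bf, "threshold_db": thr,
                "q20_oct": q20}


@dataclass
class RoiTrace:
    """Fluorescence of one ROI over repeated tone blocks.

    ``values`` has shape (n_repeats, n_frames); ``alignment[r, s]`` is
    the onset frame of catalogue stimulus ``s`` in repeat ``r`` (stimulus
    catalogue index = level_index * n_freqs + freq_index over the sorted
    grids in ``freqs_hz`` / ``levels_db``).
    """

    values: np.ndarray
    frame_rate_hz: float
    alignment: np.ndarray
    freqs_hz: np.ndarray
    levels_db: np.ndarray
    condition: str = "control"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.alignment = np.atleast_2d(np.asarray(self.alignment, dtype=int))
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.alignment.max(initial=-1) >= self.values.shape[1]:
            raise ValueError("alignment frame outside the trace")

    @property
    def n_repeats(self) -> int:
        return self.values.shape[0]


def simulate_roi_traces(
    model: ReceptiveFieldModel,
    block: StimulusBlock,
    n_repeats: int = 5,
    condition: str = "control",
    seed: int | np.random.Generator = 0,
    frame_rate_hz: float = 5.0,
    baseline_f: float = 100.0,
) -> tuple[RoiTrace, dict]:
    """Simulate one neuron's ROI fluorescence over repeated tone blocks.

    The presentation order is re-drawn per repeat (derived from the
    seed); onset slots follow the block timing.  Returns the trace and
    the generator's exact ground truth (responsive mask, amplitude
    matrix, true BF/threshold/Q20).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    if condition not in model.condition_bandwidth_gain:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of "
            f"{sorted(model.condition_bandwidth_gain)}"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    freqs = block.frequencies
    levels = block.levels
    gt = model.ground_truth(freqs, levels, condition)
    amp_flat = gt["amp"].ravel()  # catalogue order: level-major

    # map each block presentation slot to its catalogue stimulus index
    f_idx = {f: i for i, f in enumerate(freqs)}
    l_idx = {l: i for i, l in enumerate(levels)}
    slot_stim = np.array(
        [l_idx[s.level_db] * freqs.size + f_idx[s.frequency_hz]
         for s in block.stimuli]
    )
    slot_frames = np.round(block.onsets * frame_rate_hz).astype(int)

    n_frames = int(round((block.onsets[-1] + block.duration_s + block.isi_s)
                         * frame_rate_hz))
    k_len = int(round(6 * model.gcamp_tau_decay_s * frame_rate_hz)) + 1
    kernel = gcamp_kernel(np.arange(k_len) / frame_rate_hz,
                          model.gcamp_tau_rise_s, model.gcamp_tau_decay_s)

    n_stim = amp_flat.size
    values = np.empty((n_repeats, n_frames))
    alignment = np.empty((n_repeats, n_stim), dtype=int)
    for r in range(n_repeats):
        perm = rng.permutation(n_stim)  # stimulus shown in each slot
        alignment[r, perm] = slot_frames
        amps = amp_flat[perm]
        if model.repeat_jitter_sd > 0:
            jitter = rng.lognormal(0.0, model.repeat_jitter_sd, n_stim)
            amps = amps * jitter
        impulses = np.zeros(n_frames)
        np.add.at(impulses, slot_frames, amps)
        signal = np.convolve(impulses, kernel)[:n_frames]
        if model.noise_sd > 0:
            signal = signal + rng.normal(0.0, model.noise_sd, n_frames)
        values[r] = baseline_f * (1.0 + signal)

    trace = RoiTrace(values=values, frame_rate_hz=frame_rate_hz,
                     alignment=alignment, freqs_hz=freqs, levels_db=levels,
                     condition=condition)
    return trace, gt


@dataclass
class WidefieldMovie:
    """Wide-field epifluorescence movie plus stimulus timing.

    ``frames`` has shape (n_frames, height, width); default geometry is
    150 x 200 pixels at 20 Hz.
    """

    frames: np.ndarray
    frame_rate_hz: float
    stim_onsets_s: np.ndarray
    stim_duration_s: float = 0.5
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.stim_onsets_s = np.atleast_1d(np.asarray(self.stim_onsets_s,
                                                      dtype=float))
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, height, width) stack")
        if np.any(self.frames < 0):
            raise ValueError("pixel values must be non-negative")


def simulate_widefield_movie(
    region_specs: Sequence[dict],
    stim_onsets_s: Sequence[float],
    seed: int | np.random.Generator = 0,
    shape: tuple[int, int] = (150, 200),
    frame_rate_hz: float = 20.0,
    stim_duration_s: float = 0.5,
    baseline: float = 100.0,
    noise_sd: float = 0.5,
    tau_rise_s: float = 0.05,
    tau_decay_s: float = 0.5,
    tail_s: float = 2.0,
) -> WidefieldMovie:
    """Simulate a wide-field movie with Gaussian sound-responsive blobs.

    Each region spec is ``{"center": (row, col), "radius_px": r,
    "amplitude": peak dF/F}``.  The blob time course is a calcium-like
    transient triggered at each mapping-tone onset.
    """
    if not region_specs:
        raise ValueError("at least one region spec is required")
    h, w = shape
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rows, cols = np.mgrid[0:h, 0:w]
    field2d = np.zeros((h, w))
    centers = []
    for spec in region_specs:
        r0, c0 = spec["center"]
        if not (0 <= r0 < h and 0 <= c0 < w):
            raise ValueError(f"region center {spec['center']} outside the frame")
        rad = float(spec["radius_px"])
        amp = float(spec["amplitude"])
        field2d += amp * np.exp(-((rows - r0) ** 2 + (cols - c0) ** 2)
                                / (2.0 * rad ** 2))
        centers.append((float(r0), float(c0)))

    onsets = np.atleast_1d(np.asarray(stim_onsets_s, dtype=float))
    n_frames = int(round((onsets.max() + stim_duration_s + tail_s)
                         * frame_rate_hz))
    k_len = int(round(6 * tau_decay_s * frame_rate_hz)) + 1
    kernel = gcamp_kernel(np.arange(k_len) / frame_rate_hz, tau_rise_s,
                          tau_decay_s)
    impulses = np.zeros(n_frames)
    onset_frames = np.round(onsets * frame_rate_hz).astype(int)
    np.add.at(impulses, onset_frames, 1.0)
    s_t = np.convolve(impulses, kernel)[:n_frames]

    frames = baseline * (1.0 + s_t[:, None, None] * field2d[None])
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
        frames = np.clip(frames, 0.0, None)
    gt = {"centers": centers,
          "radii_px": [float(s["radius_px"]) for s in region_specs],
          "amplitudes": [float(s["amplitude"]) for s in region_specs]}
    return WidefieldMovie(frames=frames, frame_rate_hz=frame_rate_hz,
                          stim_onsets_s=onsets,
                          stim_duration_s=stim_duration_s, ground_truth=gt)


def write_roi_trace(trace: RoiTrace, prefix, ground_truth: dict | None = None
                    ) -> None:
    """Write a trace as ``<prefix>.csv`` (frames x repeats) + JSON sidecar."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    header = ",".join(f"repeat_{r}" for r in range(trace.n_repeats))
    np.savetxt(prefix.with_suffix(".csv"), trace.values.T, delimiter=",",
               header=header, comments="")
    meta = {
        "frame_rate_hz": trace.frame_rate_hz,
        "alignment": trace.alignment.tolist(),
        "freqs_hz": trace.freqs_hz.tolist(),
        "levels_db": trace.levels_db.tolist(),
        "condition": trace.condition,
    }
    if ground_truth is not None:
        meta["ground_truth"] = {
            "mask": np.asarray(ground_truth["mask"]).astype(int).tolist(),
            "bf_hz": ground_truth["bf_hz"],
            "threshold_db": ground_truth["threshold_db"],
            "q20_oct": ground_truth["q20_oct"],
        }
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def read_roi_trace(prefix) -> tuple[RoiTrace, dict | None]:
    """Read a trace written by :func:`write_roi_trace`."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    values = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",",
                        skiprows=1, ndmin=2).T
    meta = json.loads(prefix.with_suffix(".json").read_text())
    trace = RoiTrace(
        values=values,
        frame_rate_hz=meta["frame_rate_hz"],
        alignment=np.asarray(meta["alignment"]),
        freqs_hz=np.asarray(meta["freqs_hz"]),
        levels_db=np.asarray(meta["levels_db"]),
        condition=meta["condition"],
    )
    gt = meta.get("ground_truth")
    if gt is not None:
        gt = dict(gt, mask=np.asarray(gt["mask"], dtype=bool))
    return trace, gt


def write_movie(movie: WidefieldMovie, prefix) -> None:
    """Write a movie as a ``.npy`` stack with a JSON header."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), movie.frames)
    meta = {
        "frame_rate_hz": movie.frame_rate_hz,
        "stim_onsets_s": movie.stim_onsets_s.tolist(),
        "stim_duration_s": movie.stim_duration_s,
        "ground_truth": movie.ground_truth,
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def read_movie(prefix) -> WidefieldMovie:
    """Read a movie written by :func:`write_movie`."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    frames = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return WidefieldMovie(
        frames=frames,
        frame_rate_hz=meta["frame_rate_hz"],
        stim_onsets_s=np.asarray(meta["stim_onsets_s"]),
        stim_duration_s=meta["stim_duration_s"],
        ground_truth=meta.get("ground_truth"),
    )


def write_movie_pgm(movie: WidefieldMovie, out_dir) -> None:
    """Write a movie as one 16-bit PGM image per frame plus a JSON header."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scale = 65535.0 / max(movie.frames.max(), 1e-12)
    for i, frame in enumerate(movie.frames):
        img = np.round(frame * scale).astype(np.uint16)
        path = out_dir / f"frame_{i:05d}.pgm"
        with open(path, "wb") as fh:
            fh.write(f"P5\n{img.shape[1]} {img.shape[0]}\n65535\n".encode())
            fh.write(img.astype(">u2").tobytes())
    meta = {
        "frame_rate_hz": movie.frame_rate_hz,
        "stim_onsets_s": movie.stim_onsets_s.tolist(),
        "stim_duration_s": movie.stim_duration_s,
        "scale": scale,
        "ground_truth": movie.ground_truth,
    }
    (out_dir / "movie.json").write_text(json.dumps(meta))


def read_movie_pgm(in_dir) -> WidefieldMovie:
    """Read a movie written by :func:`write_movie_pgm`."""
    import json
    from pathlib import Path

    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "movie.json").read_text())
    frames = []
    for path in sorted(in_dir.glob("frame_*.pgm")):
        with open(path, "rb") as fh:
            magic = fh.readline().strip()
            if magic != b"P5":
                raise ValueError(f"{path} is not a binary PGM file")
            width, height = map(int, fh.readline().split())
            fh.readline()  # maxval
            img = np.frombuffer(fh.read(), dtype=">u2").reshape(height, width)
        frames.append(img.astype(float) / meta["scale"])
    return WidefieldMovie(
        frames=np.stack(frames),
        frame_rate_hz=meta["frame_rate_hz"],
        stim_onsets_s=np.asarray(meta["stim_onsets_s"]),
        stim_duration_s=meta["stim_duration_s"],
        ground_truth=meta.get("ground_truth"),
    )
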