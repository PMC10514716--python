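"""Sound-evoked calcium-response quantification.

Two analysis tracks:

**Wide-field mapping.**  Each pixel of a 20 Hz movie is converted to
dF/F against the mean fluorescence of the 1 s preceding each tone onset;
every frame is low-pass filtered with a 2-D Butterworth filter, and the
response map is the temporal average of the 10 consecutive frames
(0.5 s) beginning at the tone offset.  Sound-responsive regions are the
8-connected components above a z-threshold of the map.

**ROI tuning.**  Per tone (frequency, level): the repeat-aligned dF/F
responses are averaged, the averaged response is converted to a Z score
(subtract the trace mean, divide by the trace standard deviation), and
the tone counts as a response when the Z trace exceeds 0.6 for at least
two consecutive frames within 1 s of onset.  Responses are quantified as
the peak dF/F in that window.  Best frequency (BF) is the frequency of
the largest response at any level; threshold is the lowest level with a
response; Q20 is log2 of the ratio of the highest to the lowest
responsive frequency 20 dB above threshold; d-prime discriminates evoked
peaks from matched-duration baseline peaks and ranks neurons, of which
the top 20 % enter bandwidth analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import butterworth
from skimage.measure import label, regionprops

from .imaging_sim import RoiTrace, WidefieldMovie

__all__ = [
    "ResponseMap",
    "Region",
    "TuningSurface",
    "TuningMetrics",
    "compute_dff",
    "zscore_trace",
    "detect_response",
    "widefield_map",
    "detect_regions",
    "build_tuning_surface",
    "best_frequency",
    "response_threshold",
    "q20_bandwidth",
    "dprime",
    "select_top_fraction",
    "quantify_tuning",
]


@dataclass
class Region:
    centroid: tuple[float, float]
    area_px: int


@dataclass
class ResponseMap:
    dff_image: np.ndarray
    filtered: bool
    regions: list[Region] | None = None


@dataclass
class TuningSurface:
    """Per-(level, frequency) detection results for one neuron.

    ``peak_z`` is the detection statistic, ``peak_dff`` the response
    magnitude (peak dF/F in the 1-s window); rows follow ``levels_db``,
    columns ``freqs_hz``.  ``evoked_peaks`` / ``baseline_peaks`` keep the
    per-repeat window peaks used by the d-prime computation.
    """

    peak_z: np.ndarray
    peak_dff: np.ndarray
    responsive: np.ndarray
    freqs_hz: np.ndarray
    levels_db: np.ndarray
    repeats_used: int
    evoked_peaks: np.ndarray | None = None
    baseline_peaks: np.ndarray | None = None


@dataclass
class TuningMetrics:
    bf_hz: float | None
    threshold_db: float | None
    q20_oct: float | None
    dprime: float | None
    is_sound_responsive: bool
    flags: list[str] = field(default_factory=list)


def compute_dff(trace: np.ndarray, onset_frame: int, frame_rate_hz: float,
                pre_s: float = 1.0) -> np.ndarray:
    """dF/F of a trace against the mean of the ``pre_s`` window before onset."""
    trace = np.asarray(trace, dtype=float)
    n_pre = int(round(pre_s * frame_rate_hz))
    if onset_frame - n_pre < 0:
        raise ValueError(
            f"need {n_pre} pre-onset frames, onset at frame {onset_frame}"
        )
    f0 = trace[onset_frame - n_pre: onset_frame].mean()
    if f0 <= 0:
        raise ValueError("non-positive baseline fluorescence")
    return (trace - f0) / f0


def zscore_trace(trace: np.ndarray, population_sd: bool = True) -> np.ndarray:
    """Standardize a trace by its own mean and standard deviation.

    Uses the population convention (divide by N) by default; pass
    ``population_sd=False`` for the sample convention.  A constant trace
    is unscorable and raises ``ValueError``.
    """
    x = np.asarray(trace, dtype=float)
    if x.size < 2:
        raise ValueError("trace must have at least 2 samples")
    sd = x.std(ddof=0 if population_sd else 1)
    if sd == 0:
        raise ValueError("zero standard deviation; trace is unscorable")
    return (x - x.mean()) / sd


def _consecutive_exceed(above: np.ndarray, min_consec: int) -> np.ndarray:
    """Rows of a boolean matrix with a run of >= min_consec True values."""
    above = np.atleast_2d(above)
    run = above[:, : above.shape[1] - min_consec + 1].copy()
    for k in range(1, min_consec):
        run &= above[:, k: above.shape[1] - min_consec + 1 + k]
    return run.any(axis=1)


def detect_response(z: np.ndarray, onset_frame: int, frame_rate_hz: float,
                    z_thresh: float = 0.6, min_consec: int = 2,
                    window_s: float = 1.0) -> tuple[bool, float]:
    """Detect a sound-evoked response in a Z-scored trace.

    A response requires at least ``min_consec`` consecutive frames above
    ``z_thresh`` within the half-open window [onset, onset + window_s);
    the returned peak is the window maximum (NaN when not responsive).
    """
    z = np.asarray(z, dtype=float)
    n_win = int(round(window_s * frame_rate_hz))
    if onset_frame < 0 or onset_frame + n_win > z.size:
        raise ValueError("detection window truncated by the trace bounds")
    win = z[onset_frame: onset_frame + n_win]
    responsive = bool(_consecutive_exceed(win > z_thresh, min_consec)[0])
    return responsive, float(win.max()) if responsive else float("nan")


def widefield_map(movie: WidefieldMovie, pre_s: float = 1.0,
                  n_avg_frames: int = 10, cutoff_ratio: float = 0.1,
                  order: int = 2, apply_filter: bool = True) -> ResponseMap:
    """Wide-field dF/F response map.

    Per tone onset: pixelwise F from the 1 s pre-onset mean, dF/F frames
    low-pass filtered (2-D Butterworth), then the ``n_avg_frames``
    consecutive frames beginning at the tone offset are averaged.  At
    20 Hz and a 0.5 s window that is exactly 10 frames.  Maps from all
    onsets are averaged.
    """
    fr = movie.frame_rate_hz
    n_pre = int(round(pre_s * fr))
    maps = []
    for onset in movie.stim_onsets_s:
        i_on = int(round(onset * fr))
        if i_on - n_pre < 0:
            raise ValueError("insufficient pre-onset frames for baseline")
        i_off = int(round((onset + movie.stim_duration_s) * fr))
        if i_off + n_avg_frames > movie.frames.shape[0]:
            raise ValueError(
                f"fewer than {n_avg_frames} frames after the tone offset"
            )
        f0 = movie.frames[i_on - n_pre: i_on].mean(axis=0)
        f0 = np.where(f0 <= 0, np.nan, f0)
        dff = (movie.frames[i_off: i_off + n_avg_frames] - f0) / f0
        if apply_filter:
            dff = np.stack([
                butterworth(frame, cutoff_frequency_ratio=cutoff_ratio,
                            high_pass=False, order=order)
                for frame in dff
            ])
        maps.append(dff.mean(axis=0))
    return ResponseMap(dff_image=np.mean(maps, axis=0), filtered=apply_filter)


def detect_regions(rmap: ResponseMap, z_thresh: float = 2.0,
                   min_area_px: int = 10) -> list[Region]:
    """Connected components above mean + z_thresh * sd of the map.

    8-connected components with at least ``min_area_px`` pixels, sorted
    by decreasing area.  The regions are also stored on the map.
    """
    img = rmap.dff_image
    thr = np.nanmean(img) + z_thresh * np.nanstd(img)
    mask = img > thr
    labeled = label(mask, connectivity=2)
    regions = [
        Region(centroid=tuple(p.centroid), area_px=int(p.area))
        for p in regionprops(labeled)
        if p.area >= min_area_px
    ]
    regions.sort(key=lambda r: r.area_px, reverse=True)
    rmap.regions = regions
    return regions


def build_tuning_surface(
    roi: RoiTrace,
    z_thresh: float = 0.6,
    min_consec: int = 2,
    window_s: float = 1.0,
    pre_s: float = 1.0,
    post_s: float = 2.0,
    population_sd: bool = True,
    zscore_scope: str = "trace",
) -> TuningSurface:
    """Frequency-intensity tuning surface of one ROI.

    Per stimulus: repeat-aligned segments spanning [onset - pre_s,
    onset + post_s) are converted to dF/F (per-repeat 1-s pre baseline)
    and averaged over repeats.  The averaged response is Z-scored with
    the mean and standard deviation of the entire averaged trace
    (``zscore_scope="trace"``, the default) so that the 0.6-Z threshold
    is commensurate across stimuli; ``zscore_scope="segment"``
    standardizes each stimulus segment by itself instead.  The 0.6-Z /
    2-consecutive-frame criterion is applied within the 1-s post-onset
    window.  An entirely constant trace is unscorable and counts as
    non-responsive.
    """
    fr = roi.frame_rate_hz
    n_pre = int(round(pre_s * fr))
    n_post = int(round(post_s * fr))
    n_win = int(round(window_s * fr))
    if n_win > n_post:
        raise ValueError("post_s must cover the detection window")
    rel = np.arange(-n_pre, n_post)
    idx = roi.alignment[:, :, None] + rel[None, None, :]
    if idx.min() < 0 or idx.max() >= roi.values.shape[1]:
        raise ValueError("segment window extends outside the recorded trace")
    raw = np.take_along_axis(
        roi.values[:, None, :], idx, axis=2
    )  # (repeats, stimuli, frames)
    f0 = raw[:, :, :n_pre].mean(axis=2)
    if np.any(f0 <= 0):
        raise ValueError("non-positive baseline fluorescence")
    dff = raw / f0[:, :, None] - 1.0
    avg = dff.mean(axis=0)  # (stimuli, frames)

    ddof = 0 if population_sd else 1
    if zscore_scope == "trace":
        sd = np.full(avg.shape[0], avg.std(ddof=ddof))
        mean = np.full((avg.shape[0], 1), avg.mean())
    elif zscore_scope == "segment":
        sd = avg.std(axis=1, ddof=ddof)
        mean = avg.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown zscore_scope {zscore_scope!r}")
    scorable = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (avg - mean) / sd[:, None]
    zwin = z[:, n_pre: n_pre + n_win]
    responsive = scorable & _consecutive_exceed(zwin > z_thresh, min_consec)
    peak_z = np.full(avg.shape[0], np.nan)
    peak_z[scorable] = zwin[scorable].max(axis=1)
    peak_dff = avg[:, n_pre: n_pre + n_win].max(axis=1)

    n_l, n_f = roi.levels_db.size, roi.freqs_hz.size
    shape = (n_l, n_f)
    return TuningSurface(
        peak_z=peak_z.reshape(shape),
        peak_dff=peak_dff.reshape(shape),
        responsive=responsive.reshape(shape),
        freqs_hz=roi.freqs_hz,
        levels_db=roi.levels_db,
        repeats_used=roi.n_repeats,
        evoked_peaks=dff[:, :, n_pre: n_pre + n_win].max(axis=2).T.reshape(
            n_l, n_f, -1
        ),
        baseline_peaks=dff[:, :, :n_pre].max(axis=2).T.reshape(n_l, n_f, -1),
    )


def _best_cell(surface: TuningSurface) -> tuple[int, int] | None:
    """(level, frequency) index of the largest responsive peak dF/F.

    Exact ties break toward the lower frequency (then the lower level).
    """
    if not surface.responsive.any():
        return None
    vals = np.where(surface.responsive, surface.peak_dff, -np.inf)
    best = vals.max()
    lv, fv = np.nonzero(vals == best)
    k = np.argmin(fv)
    return int(lv[k]), int(fv[k])


def best_frequency(surface: TuningSurface) -> float | None:
    """Frequency of the largest response at any level (BF)."""
    cell = _best_cell(surface)
    return None if cell is None else float(surface.freqs_hz[cell[1]])


def response_threshold(surface: TuningSurface) -> float | None:
    """Lowest sound level with any detected response."""
    rows = surface.responsive.any(axis=1)
    if not rows.any():
        return None
    return float(surface.levels_db[rows].min())


def q20_bandwidth(surface: TuningSurface) -> float | None:
    """Tuning bandwidth (octaves) 20 dB above threshold.

    ``log2(f_max/f_min)`` over the responsive frequencies in the single
    level row at threshold + 20 dB; 0 when exactly one frequency is
    responsive there; ``None`` (neuron excluded from bandwidth analyses)
    when that level was not tested or carries no response.
    """
    thr = response_threshold(surface)
    if thr is None:
        return None
    hit = np.nonzero(np.isclose(surface.levels_db, thr + 20.0))[0]
    if hit.size == 0:
        return None
    fr = surface.freqs_hz[surface.responsive[hit[0]]]
    if fr.size == 0:
        return None
    return float(np.log2(fr.max() / fr.min()))


def dprime(surface: TuningSurface) -> float | None:
    """Discriminability of evoked vs. baseline peaks at the BF stimulus.

    d' = (mean evoked peak dF/F - mean baseline peak) / sqrt((var_e +
    var_b) / 2) over repeats, with sample variances; ``None`` when the
    pooled variance is zero or fewer than 2 repeats are available.
    """
    cell = _best_cell(surface)
    if cell is None or surface.evoked_peaks is None:
        return None
    ev = surface.evoked_peaks[cell[0], cell[1]]
    ba = surface.baseline_peaks[cell[0], cell[1]]
    if ev.size < 2:
        return None
    pooled = (ev.var(ddof=1) + ba.var(ddof=1)) / 2.0
    # guard against pure float rounding on deterministic repeats
    if np.sqrt(pooled) < 1e-9:
        return None
    return float((ev.mean() - ba.mean()) / math.sqrt(pooled))


def select_top_fraction(dprimes: np.ndarray, fraction: float = 0.20
                        ) -> np.ndarray:
    """Indices of the top fraction of neurons ranked by d-prime.

    Keeps ``ceil(fraction * n)`` neurons (at least 1), ranking by
    descending d-prime with ties at the cutoff broken by input order
    (stable sort).  Empty input yields an empty selection.
    """
    d = np.asarray(dprimes, dtype=float)
    if d.size == 0:
        return np.array([], dtype=int)
    order = np.argsort(-d, kind="stable")
    keep = max(1, math.ceil(fraction * d.size))
    return order[:keep]


def quantify_tuning(surface: TuningSurface) -> TuningMetrics:
    """BF, threshold, Q20 and d-prime of one neuron's tuning surface."""
    flags = []
    responsive = bool(surface.responsive.any())
    bf = best_frequency(surface)
    thr = response_threshold(surface)
    q20 = q20_bandwidth(surface)
    if responsive and q20 is None:
        flags.append("q20_undefined")
    d = dprime(surface)
    if responsive and d is None:
        flags.append("dprime_undefined")
    return TuningMetrics(bf_hz=bf, threshold_db=thr, q20_oct=q20, dprime=d,
                         is_sound_responsive=responsive, flags=flags)
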