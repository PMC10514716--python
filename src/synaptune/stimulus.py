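"""Tone-block construction for auditory receptive-field mapping.

A mapping session presents every (frequency, level) combination of a
logarithmic tone grid exactly once per block, in a seeded pseudorandom
order, with a fixed inter-stimulus interval.  The default grid spans
5-40 kHz in 1/8-octave steps at five sound levels (40-80 dB SPL), i.e.
25 frequencies x 5 levels = 125 unique tones per block.

Blocks serialize to a delimited-text table plus a JSON sidecar so that
the synthetic-trace generator and the tuning analysis can share one
stimulus description.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ToneStimulus",
    "StimulusBlock",
    "frequency_grid",
    "build_tone_block",
    "write_block",
    "read_block",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class ToneStimulus:
    """A single pure-tone presentation."""

    frequency_hz: float
    level_db: float
    onset_s: float
    duration_s: float = 0.5
    ramp_s: float = 0.02

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError(f"frequency_hz must be positive, got {self.frequency_hz}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if not (0 <= self.ramp_s <= self.duration_s / 2):
            raise ValueError(
                f"ramp_s must lie in [0, duration_s/2], got {self.ramp_s}"
            )


@dataclass
class StimulusBlock:
    """An ordered sequence of tone presentations covering a full grid once.

    Attributes
    ----------
    stimuli : list of ToneStimulus
        Presentation order (already permuted).
    isi_s : float
        Silent gap between tone offset and the next onset.
    seed : int
        Seed that produced the presentation order.
    start_s : float
        Onset time of the first presentation (silence before it provides
        the pre-stimulus baseline used by the imaging analysis).
    grid : dict
        Construction parameters (kept for the JSON sidecar round trip).
    """

    stimuli: list[ToneStimulus]
    isi_s: float
    seed: int
    start_s: float = 3.0
    grid: dict = field(default_factory=dict)

    @property
    def n_unique(self) -> int:
        return len({(s.frequency_hz, s.level_db) for s in self.stimuli})

    @property
    def frequencies(self) -> np.ndarray:
        return np.array(sorted({s.frequency_hz for s in self.stimuli}))

    @property
    def levels(self) -> np.ndarray:
        return np.array(sorted({s.level_db for s in self.stimuli}))

    @property
    def onsets(self) -> np.ndarray:
        return np.array([s.onset_s for s in self.stimuli])

    @property
    def duration_s(self) -> float:
        return self.stimuli[0].duration_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self.stimuli)),
                "frequency_hz": [s.frequency_hz for s in self.stimuli],
                "level_db": [s.level_db for s in self.stimuli],
                "onset_s": [s.onset_s for s in self.stimuli],
                "duration_s": [s.duration_s for s in self.stimuli],
                "ramp_s": [s.ramp_s for s in self.stimuli],
            }
        )


def frequency_grid(f_min_hz: float, f_max_hz: float, octave_step: float) -> np.ndarray:
    """Logarithmic frequency grid ``f_min * 2**(k*octave_step)``.

    When ``log2(f_max/f_min)`` is an integer multiple of the step (within
    floating tolerance) the grid lands exactly on ``f_max``; otherwise the
    largest grid frequency below ``f_max`` ends the grid.
    """
    if f_min_hz <= 0:
        raise ValueError(f"f_min_hz must be positive, got {f_min_hz}")
    if f_max_hz <= 0:
        raise ValueError(f"f_max_hz must be positive, got {f_max_hz}")
    if octave_step <= 0:
        raise ValueError(f"octave_step must be positive, got {octave_step}")
    if f_max_hz < f_min_hz:
        raise ValueError("f_max_hz must be >= f_min_hz")
    span = math.log2(f_max_hz / f_min_hz)
    k_exact = span / octave_step
    k = round(k_exact)
    if abs(k_exact - k) > 1e-6 * max(1.0, abs(k_exact)):
        k = math.floor(k_exact + _REL_TOL)
    return f_min_hz * 2.0 ** (np.arange(k + 1) * octave_step)


def build_tone_block(
    f_min_hz: float,
    f_max_hz: float,
    octave_step: float,
    levels_db: Sequence[float],
    duration_s: float = 0.5,
    ramp_s: float = 0.02,
    isi_s: float = 3.0,
    seed: int = 0,
    start_s: float = 3.0,
) -> StimulusBlock:
    """Build one pseudorandom tone block covering the full grid once.

    Every (frequency, level) pair appears exactly once; the presentation
    order is a seeded uniform permutation; onsets are equally spaced by
    ``duration_s + isi_s`` starting at ``start_s``.
    """
    levels = list(levels_db)
    if not levels:
        raise ValueError("levels_db must be non-empty")
    freqs = frequency_grid(f_min_hz, f_max_hz, octave_step)
    pairs = [(f, l) for f in freqs for l in levels]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    period = duration_s + isi_s
    stimuli = [
        ToneStimulus(
            frequency_hz=float(pairs[j][0]),
            level_db=float(pairs[j][1]),
            onset_s=start_s + i * period,
            duration_s=duration_s,
            ramp_s=ramp_s,
        )
        for i, j in enumerate(order)
    ]
    grid = {
        "f_min_hz": float(f_min_hz),
        "f_max_hz": float(f_max_hz),
        "octave_step": float(octave_step),
        "levels_db": [float(l) for l in levels],
        "duration_s": float(duration_s),
        "ramp_s": float(ramp_s),
    }
    return StimulusBlock(stimuli=stimuli, isi_s=float(isi_s), seed=int(seed),
                         start_s=float(start_s), grid=grid)


def write_block(block: StimulusBlock, table_path: str | Path,
                meta_path: str | Path | None = None) -> None:
    """Write a block as a CSV table plus a JSON sidecar."""
    table_path = Path(table_path)
    if meta_path is None:
        meta_path = table_path.with_suffix(".json")
    # %.17g round-trips float64 exactly
    block.to_frame().to_csv(table_path, index=False, float_format="%.17g")
    meta = {
        "isi_s": block.isi_s,
        "seed": block.seed,
        "start_s": block.start_s,
        "grid": block.grid,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def read_block(table_path: str | Path,
               meta_path: str | Path | None = None) -> StimulusBlock:
    """Read a block written by :func:`write_block`."""
    table_path = Path(table_path)
    if meta_path is None:
        meta_path = table_path.with_suffix(".json")
    df = pd.read_csv(table_path, float_precision="round_trip")
    meta = json.loads(Path(meta_path).read_text())
    stimuli = [
        ToneStimulus(
            frequency_hz=row.frequency_hz,
            level_db=row.level_db,
            onset_s=row.onset_s,
            duration_s=row.duration_s,
            ramp_s=row.ramp_s,
        )
        for row in df.itertuples()
    ]
    return StimulusBlock(
        stimuli=stimuli,
        isi_s=meta["isi_s"],
        seed=meta["seed"],
        start_s=meta.get("start_s", stimuli[0].onset_s if stimuli else 0.0),
        grid=meta.get("grid", {}),
    )
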