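"""Frequency response areas, characteristic frequencies and the tonotopic
calibration of the recording probe.

The 32-channel linear probe samples the dorso-ventral (low-to-high frequency)
axis of the central inferior colliculus at 50 μm pitch. Presenting pure tones
over a frequency × level grid yields a frequency response area (FRA) per
recording site; the frequency that evokes activity at the lowest level is the
site's characteristic frequency (CF). Regressing log2(CF) on recording depth
gives each animal's tonotopic slope in octaves/mm — the converter used later
to express spatial spread of excitation in octaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class RecordingGeometry:
    """Linear silicon-probe geometry; electrode 1 is the most dorsal site."""

    n_electrodes: int = 32
    pitch_mm: float = 0.050
    depth_of_first_electrode_mm: float = 0.0

    def __post_init__(self):
        if self.pitch_mm <= 0 or self.n_electrodes < 1:
            raise ValueError("invalid probe geometry")

    def depths_mm(self) -> np.ndarray:
        """Depth of each electrode (mm), increasing ventrally from electrode 1."""
        return self.depth_of_first_electrode_mm + np.arange(self.n_electrodes) * self.pitch_mm


@dataclass
class FrequencyResponseArea:
    """Mean firing rate per (frequency, level) cell plus a spontaneous estimate.

    ``rate_hz`` has shape (n_freqs, n_levels). The spontaneous rate and its
    per-trial SD come from pre-stimulus spans of the same recording.
    """

    freqs_khz: np.ndarray
    levels_db: np.ndarray
    rate_hz: np.ndarray
    n_trials: int
    spont_rate_hz: float
    spont_sd_hz: float
    electrode: int = 0
    animal_id: str = ""

    def __post_init__(self):
        self.freqs_khz = np.asarray(self.freqs_khz, dtype=float)
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        self.rate_hz = np.asarray(self.rate_hz, dtype=float)
        if np.any(np.diff(self.freqs_khz) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if self.rate_hz.shape != (self.freqs_khz.size, self.levels_db.size):
            raise ValueError("rate grid shape does not match the stimulus grid")
        if np.any(self.rate_hz < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class TuningResult:
    cf_khz: float
    threshold_db: float
    responsive: bool
    electrode: int = 0


@dataclass
class TonotopicFit:
    """Per-animal linear fit of log2(CF) against recording depth."""

    slope_oct_per_mm: float
    intercept_oct: float
    pearson_r: float
    n_points: int
    animal_id: str = ""
    valid: bool = True


def build_fra(
    spikes: pd.DataFrame,
    freqs_khz,
    levels_db,
    n_trials: int,
    *,
    stim_window_ms: tuple[float, float] = (0.0, 100.0),
    pre_span_ms: tuple[float, float] = (-50.0, 0.0),
    electrode: int | None = None,
    animal_id: str = "",
) -> FrequencyResponseArea:
    """Construct an FRA from one electrode's slice of an acoustic spike table.

    The acoustic spike table encodes tone frequency (kHz) in ``emitter_set``
    and sound level (dB SPL) in ``intensity``. Counts are taken in the tone
    window and divided by the full trial count ``n_trials`` (trials without
    spikes leave no rows). Spontaneous rate is estimated from the pre-stimulus
    span of *all* trials, giving both a mean and a per-trial SD.
    """
    freqs = np.sort(np.asarray(freqs_khz, dtype=float))
    levels = np.asarray(levels_db, dtype=float)
    if electrode is not None:
        spikes = spikes[spikes["electrode"] == electrode]
    else:
        electrode = int(spikes["electrode"].iloc[0]) if len(spikes) else 0

    t = spikes["t_ms"].to_numpy()
    w0, w1 = stim_window_ms
    in_win = spikes[(t >= w0) & (t < w1)]
    stim_s = (w1 - w0) * 1e-3

    rate = np.zeros((freqs.size, levels.size))
    if len(in_win):
        f_vals = in_win["emitter_set"].astype(float).to_numpy()
        l_vals = in_win["intensity"].to_numpy()
        fi, f_ok = _match_grid(f_vals, freqs)
        li, l_ok = _match_grid(l_vals, levels)
        # rows off the grid (e.g. the zero-level baseline condition) feed
        # only the spontaneous estimate below
        ok = f_ok & l_ok
        np.add.at(rate, (fi[ok], li[ok]), 1.0)
    rate /= n_trials * stim_s

    p0, p1 = pre_span_ms
    pre = spikes[(t >= p0) & (t < p1)]
    pre_s = (p1 - p0) * 1e-3
    # per-trial pre-stimulus rates over every presented stimulus
    n_pre_trials = max(len(spikes.groupby(["emitter_set", "intensity"]).size()), 1) * n_trials
    per_trial = np.zeros(n_pre_trials)
    if len(pre):
        counts = pre.groupby(["emitter_set", "intensity", "trial"]).size().to_numpy()
        per_trial[: counts.size] = counts
    spont_rates = per_trial / pre_s
    return FrequencyResponseArea(
        freqs_khz=freqs,
        levels_db=levels,
        rate_hz=rate,
        n_trials=n_trials,
        spont_rate_hz=float(spont_rates.mean()),
        spont_sd_hz=float(spont_rates.std(ddof=1)) if spont_rates.size > 1 else 0.0,
        electrode=electrode,
        animal_id=animal_id,
    )


def _match_grid(values: np.ndarray, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest grid index per value and a mask of values on the grid."""
    idx = np.searchsorted(grid, values)
    idx = np.clip(idx, 0, grid.size - 1)
    left = np.clip(idx - 1, 0, grid.size - 1)
    use_left = np.abs(values - grid[left]) < np.abs(values - grid[idx])
    idx = np.where(use_left, left, idx)
    rel = np.abs(values - grid[idx]) / np.maximum(np.abs(grid[idx]), 1e-12)
    return idx, rel <= 1e-3


def characteristic_frequency(
    fra: FrequencyResponseArea, *, z: float = 3.0
) -> TuningResult:
    """CF = frequency responsive at the lowest sound level.

    A cell is responsive when its mean rate exceeds the spontaneous rate by
    ``z`` spontaneous SDs. If several frequencies are responsive at the
    lowest responsive level, the one with the highest rate wins
    (deterministic tie-break).
    """
    crit = fra.spont_rate_hz + z * fra.spont_sd_hz
    responsive = fra.rate_hz > crit
    order = np.argsort(fra.levels_db)
    for li in order:
        col = responsive[:, li]
        if col.any():
            cand = np.flatnonzero(col)
            best = cand[np.argmax(fra.rate_hz[cand, li])]
            return TuningResult(
                cf_khz=float(fra.freqs_khz[best]),
                threshold_db=float(fra.levels_db[li]),
                responsive=True,
                electrode=fra.electrode,
            )
    return TuningResult(cf_khz=np.nan, threshold_db=np.nan, responsive=False,
                        electrode=fra.electrode)


def fit_tonotopic_slope(
    results,
    geometry: RecordingGeometry,
    *,
    animal_id: str = "",
) -> TonotopicFit:
    """Least-squares fit of log2(CF) on electrode depth, in octaves/mm.

    A positive slope means CF increases with depth (ventrally), the expected
    orientation of the ICC map. Needs at least 3 responsive electrodes.
    """
    depths = geometry.depths_mm()
    pts = [
        (depths[r.electrode - 1], np.log2(r.cf_khz))
        for r in results
        if r.responsive and np.isfinite(r.cf_khz)
    ]
    if len(pts) < 3:
        return TonotopicFit(np.nan, np.nan, np.nan, len(pts), animal_id, valid=False)
    x, y = map(np.asarray, zip(*pts))
    if np.allclose(x, x[0]):
        return TonotopicFit(np.nan, np.nan, np.nan, len(pts), animal_id, valid=False)
    if np.allclose(y, y[0]):
        # constant CF: zero slope, correlation undefined
        return TonotopicFit(0.0, float(y[0]), 0.0, len(pts), animal_id)
    res = stats.linregress(x, y)
    return TonotopicFit(
        slope_oct_per_mm=float(res.slope),
        intercept_oct=float(res.intercept),
        pearson_r=float(res.rvalue),
        n_points=len(pts),
        animal_id=animal_id,
    )


def cohort_slope_summary(fits) -> tuple[float, float]:
    """Median and median absolute deviation of valid per-animal slopes.

    Deaf animals are excluded from fitting upstream and later assigned this
    hearing-cohort median. The MAD is raw (no normal-consistency factor).
    """
    slopes = np.asarray([f.slope_oct_per_mm for f in fits if f.valid], dtype=float)
    if slopes.size == 0:
        raise ValueError("no valid tonotopic fits to summarize")
    med = float(np.median(slopes))
    return med, float(np.median(np.abs(slopes - med)))


def tune_all_electrodes(
    spikes: pd.DataFrame,
    geometry: RecordingGeometry,
    *,
    freqs_khz,
    levels_db,
    n_trials: int,
    z: float = 3.0,
) -> list[TuningResult]:
    """FRA → CF for every electrode of one animal's acoustic spike table."""
    groups = {el: sub for el, sub in spikes.groupby("electrode")}
    empty = spikes.iloc[0:0]
    out = []
    for el in range(1, geometry.n_electrodes + 1):
        fra = build_fra(
            groups.get(el, empty), freqs_khz, levels_db, n_trials, electrode=el
        )
        out.append(characteristic_frequency(fra, z=z))
    return out
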