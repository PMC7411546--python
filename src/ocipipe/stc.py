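"""Cumulative d′ spatial tuning curves: the statistical core of the pipeline.

For each stimulation run, window spike counts are sorted into a response
matrix over (recording electrode × stimulus intensity), with the first
intensity being the zero/no-stimulation baseline. The cumulative
discrimination index d′ accumulates, over increasing intensity, the
standardized increment in firing between adjacent intensity steps

    Δd′_i = (μ_i − μ_{i−1}) / sqrt((σ_i² + σ_{i−1}²) / 2)

so that a response one pooled SD above baseline has d′ = 1. Spatial tuning
curves (STCs) are iso-contours of cumulative d′ over the electrode ×
intensity plane; the interpolated intensity at which an electrode first
reaches d′ = 1 is its activation threshold, and the electrode with the
lowest threshold is the best electrode (BE). Spread of excitation at a
criterion d′ is the electrode span with d′ ≥ 1 at the intensity where the
BE reaches the criterion, bridging sub-threshold gaps with the
outermost-electrode rule so multi-peaked STCs are not underestimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import ResponseWindow
from .tuning import RecordingGeometry

#: default iso-contour levels: the integer levels of the STC display plus the
#: half-integer spread criteria
DEFAULT_CONTOUR_LEVELS = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass
class ResponseMatrix:
    """Trial-wise window spike counts per (electrode, intensity) cell."""

    counts: np.ndarray  # shape (n_electrodes, n_intensities, n_trials)
    intensities: np.ndarray
    electrodes: np.ndarray  # 1-based ids, ascending (1 = most dorsal)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.electrodes = np.asarray(self.electrodes, dtype=int)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (electrodes, intensities, trials)")
        if self.counts.shape[:2] != (self.electrodes.size, self.intensities.size):
            raise ValueError("counts shape inconsistent with axes")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        if self.intensities[0] != 0:
            raise ValueError("first intensity must be the zero-intensity baseline")
        if np.any(np.diff(self.intensities) <= 0):
            raise ValueError("intensities must be strictly increasing")

    @property
    def means(self) -> np.ndarray:
        return self.counts.mean(axis=2)

    @property
    def sds(self) -> np.ndarray:
        """Per-cell SD of window counts (n − 1 denominator)."""
        return self.counts.std(axis=2, ddof=1)

    @classmethod
    def from_counts(cls, counts, intensities, electrodes=None) -> "ResponseMatrix":
        counts = np.asarray(counts, dtype=float)
        if electrodes is None:
            electrodes = np.arange(1, counts.shape[0] + 1)
        return cls(counts, np.asarray(intensities, dtype=float), electrodes)


@dataclass
class DPrimeMatrix:
    """Cumulative d′ per (electrode, intensity); step increments retained.

    ``cumulative`` keeps raw values (suppression can drive it negative);
    ``floored`` clips at 0 and is what thresholds and contours are read from,
    since activation thresholds are excitation-defined.
    """

    increments: np.ndarray  # (E, K-1)
    cumulative: np.ndarray  # (E, K), raw
    floored: np.ndarray  # (E, K), clipped at 0
    intensities: np.ndarray
    electrodes: np.ndarray


@dataclass
class SpatialTuningCurve:
    """Thresholds, best electrode and activation summary of one STC."""

    thresholds: np.ndarray  # per electrode; NaN where d' never reaches 1
    best_electrode: int | None
    max_dprime: float
    n_active: int
    dp: DPrimeMatrix
    contours: dict = field(default_factory=dict)

    @property
    def be_threshold(self) -> float:
        if self.best_electrode is None:
            return float("nan")
        return float(self.thresholds[np.flatnonzero(self.dp.electrodes == self.best_electrode)[0]])


@dataclass
class SpreadResult:
    """Spread of excitation at one criterion d′ at the best electrode."""

    criterion_dprime: float
    achieved: bool
    criterion_intensity: float
    dorsal_electrode: int | None
    ventral_electrode: int | None
    span_mm: float
    span_octaves: float = float("nan")


def build_response_matrix(
    spikes: pd.DataFrame,
    ladder,
    win: ResponseWindow,
    *,
    n_electrodes: int = 32,
) -> ResponseMatrix:
    """Sort window spike counts of one stimulation run into a response matrix.

    ``ladder`` supplies the intensity axis (must start at 0, the baseline
    condition) and the trial count per step; trials absent from the table
    (no spikes) count as zero. Row order in ``spikes`` is irrelevant.
    """
    intensities = np.asarray(ladder.intensities, dtype=float)
    if intensities.size < 2:
        raise ValueError("need at least two intensity steps (baseline + one)")
    if intensities[0] != 0:
        raise ValueError("ladder must include the zero-intensity baseline first")
    n_trials = ladder.n_trials_per_step
    counts = np.zeros((n_electrodes, intensities.size, n_trials))
    t = spikes["t_ms"].to_numpy()
    sel = spikes[(t >= win.start_ms) & (t < win.end_ms)]
    if len(sel):
        el = sel["electrode"].to_numpy() - 1
        trial = sel["trial"].to_numpy()
        ii = np.searchsorted(intensities, sel["intensity"].to_numpy())
        ii = np.clip(ii, 0, intensities.size - 1)
        down = np.clip(ii - 1, 0, intensities.size - 1)
        closer = np.abs(sel["intensity"].to_numpy() - intensities[down]) < np.abs(
            sel["intensity"].to_numpy() - intensities[ii]
        )
        ii = np.where(closer, down, ii)
        if np.any(~np.isclose(sel["intensity"].to_numpy(), intensities[ii], rtol=1e-6, atol=1e-9)):
            bad = sel["intensity"].to_numpy()[
                ~np.isclose(sel["intensity"].to_numpy(), intensities[ii], rtol=1e-6, atol=1e-9)
            ][0]
            raise ValueError(f"intensity {bad} not on the stimulus ladder")
        if np.any(el < 0) or np.any(el >= n_electrodes):
            raise ValueError("electrode index outside the probe")
        if np.any(trial < 0) or np.any(trial >= n_trials):
            raise ValueError("trial index exceeds the ladder's trials per step")
        np.add.at(counts, (el, ii, trial), 1.0)
    return ResponseMatrix.from_counts(counts, intensities)


def cumulative_dprime(
    rm: ResponseMatrix,
    *,
    variance_floor: float = 0.5,
    max_increment: float = 5.0,
) -> DPrimeMatrix:
    """Cumulative d′ over increasing intensity, starting at the baseline.

    The pooled SD of adjacent steps is floored at ``variance_floor`` (half a
    spike per window by default) so zero-variance cells cannot produce
    infinite increments, and each increment is clipped to
    ``±max_increment``. d′ is exactly 0 at the zero-intensity step.
    """
    if rm.intensities.size < 2:
        raise ValueError("need at least two intensity steps")
    mu = rm.means
    sd = rm.sds
    pooled = np.sqrt((sd[:, 1:] ** 2 + sd[:, :-1] ** 2) / 2.0)
    pooled = np.maximum(pooled, variance_floor)
    inc = (mu[:, 1:] - mu[:, :-1]) / pooled
    inc = np.clip(inc, -max_increment, max_increment)
    cum = np.concatenate([np.zeros((mu.shape[0], 1)), np.cumsum(inc, axis=1)], axis=1)
    return DPrimeMatrix(
        increments=inc,
        cumulative=cum,
        floored=np.clip(cum, 0.0, None),
        intensities=rm.intensities,
        electrodes=rm.electrodes,
    )


def _first_crossing(intensities: np.ndarray, d: np.ndarray, level: float) -> float:
    """Interpolated intensity at which ``d`` first reaches ``level`` (NaN if never)."""
    above = d >= level
    if not above.any():
        return float("nan")
    i = int(np.argmax(above))
    if i == 0:
        return float(intensities[0])
    d0, d1 = d[i - 1], d[i]
    if d1 == d0:
        return float(intensities[i])
    frac = (level - d0) / (d1 - d0)
    return float(intensities[i - 1] + frac * (intensities[i] - intensities[i - 1]))


def iso_contours(dp: DPrimeMatrix, levels=DEFAULT_CONTOUR_LEVELS) -> dict:
    """Iso-contour polylines of floored cumulative d′ on the intensity ×
    electrode grid, as ``{level: [array(n, 2), ...]}`` with columns
    (intensity, electrode index)."""
    from contourpy import contour_generator

    cg = contour_generator(
        x=dp.intensities, y=dp.electrodes.astype(float), z=dp.floored
    )
    out = {}
    for level in levels:
        out[float(level)] = [np.asarray(line) for line in cg.lines(float(level))]
    return out


def build_stc(dp: DPrimeMatrix, *, levels=DEFAULT_CONTOUR_LEVELS,
              with_contours: bool = False) -> SpatialTuningCurve:
    """Thresholds (d′ = 1 crossings), best electrode and activation counts.

    BE ties are broken deterministically: lowest threshold, then higher
    maximum d′, then the more dorsal (lower) electrode index. A valid STC in
    which no electrode reaches d′ = 1 has no BE (flagged by ``None``).
    """
    thresholds = np.array(
        [_first_crossing(dp.intensities, dp.floored[e], 1.0)
         for e in range(dp.electrodes.size)]
    )
    max_d = dp.floored.max(axis=1)
    n_active = int(np.count_nonzero(max_d >= 1.0))
    best = None
    if np.isfinite(thresholds).any():
        tmin = np.nanmin(thresholds)
        cand = np.flatnonzero(np.isclose(thresholds, tmin, rtol=0, atol=1e-12))
        cand = cand[max_d[cand] == max_d[cand].max()]
        best = int(dp.electrodes[cand[0]])
    stc = SpatialTuningCurve(
        thresholds=thresholds,
        best_electrode=best,
        max_dprime=float(dp.floored.max()),
        n_active=n_active,
        dp=dp,
    )
    if with_contours:
        stc.contours = iso_contours(dp, levels)
    return stc


def count_active_electrodes(dp: DPrimeMatrix, *, level: float = 1.0) -> int:
    """Electrodes whose cumulative d′ reaches ``level`` at any intensity."""
    return int(np.count_nonzero(dp.floored.max(axis=1) >= level))


def spread_of_excitation(
    stc: SpatialTuningCurve,
    *,
    criterion_dprime: float = 2.0,
    geometry: RecordingGeometry = RecordingGeometry(),
    activation_level: float = 1.0,
) -> SpreadResult:
    """Spread of excitation at the intensity where the BE reaches a criterion.

    The criterion intensity is interpolated on the BE's cumulative-d′ curve;
    electrodes whose interpolated d′ at that intensity is ≥ 1 form the
    responsive set. The span runs from the dorsal-most to the ventral-most
    responsive electrode (sub-threshold gaps are bridged, avoiding
    underestimation of multi-peaked STCs) times the electrode pitch.
    """
    dp = stc.dp
    if stc.best_electrode is None:
        return SpreadResult(criterion_dprime, False, float("nan"), None, None, float("nan"))
    be_row = np.flatnonzero(dp.electrodes == stc.best_electrode)[0]
    ic = _first_crossing(dp.intensities, dp.floored[be_row], criterion_dprime)
    if not np.isfinite(ic):
        return SpreadResult(criterion_dprime, False, float("nan"), None, None, float("nan"))
    d_at = np.array(
        [np.interp(ic, dp.intensities, dp.floored[e]) for e in range(dp.electrodes.size)]
    )
    resp = np.flatnonzero(d_at >= activation_level)
    dorsal = int(dp.electrodes[resp.min()])
    ventral = int(dp.electrodes[resp.max()])
    span_mm = (ventral - dorsal) * geometry.pitch_mm
    return SpreadResult(criterion_dprime, True, ic, dorsal, ventral, float(span_mm))


def emitter_qualifies(stc: SpatialTuningCurve, *, min_electrodes: int = 3,
                      min_dprime: float = 1.5) -> bool:
    """One emitter's STC qualifies if enough electrodes reach threshold and
    the response is strong enough."""
    n_thresholded = int(np.count_nonzero(np.isfinite(stc.thresholds)))
    return n_thresholded >= min_electrodes and stc.max_dprime >= min_dprime


def qualify_stc(stcs, *, min_emitters: int = 2, min_electrodes: int = 3,
                min_dprime: float = 1.5) -> bool:
    """Implant inclusion rule for the tonotopy analysis.

    An implant enters the place-code analysis only if STCs from at least
    ``min_emitters`` different emitters each reached threshold on at least
    ``min_electrodes`` electrodes with a maximum d′ of ``min_dprime`` or more.
    """
    n_good = sum(
        emitter_qualifies(s, min_electrodes=min_electrodes, min_dprime=min_dprime)
        for s in stcs
    )
    return n_good >= min_emitters


def export_stc_csv(stc: SpatialTuningCurve, path) -> None:
    """Long-format CSV of (electrode, intensity, cumulative_dprime)."""
    dp = stc.dp
    rows = [
        {
            "electrode": int(dp.electrodes[e]),
            "intensity": float(dp.intensities[k]),
            "cumulative_dprime": float(dp.cumulative[e, k]),
            "floored_dprime": float(dp.floored[e, k]),
        }
        for e in range(dp.electrodes.size)
        for k in range(dp.intensities.size)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
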