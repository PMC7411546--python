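"""Tonotopic place-code analysis and unit conversions.

To compare stimulation sites across implants that differ in insertion route,
depth and emitter pitch, emitter positions are normalized to the apical-most
emitter on each implant that evoked a response, and each spatial tuning
curve's best electrode (BE) is expressed relative to the BE of that reference
emitter. Regressing the relative BE (electrodes) on the relative emitter
position (mm along the cochlea) quantifies the tonotopic place code: how far
the focus of midbrain activation shifts per millimeter of stimulus location.

Spatial spans in the midbrain are converted to spectral spans (octaves) via
each animal's tonotopic slope; deaf animals, which cannot be mapped
acoustically, use the hearing-cohort median slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .tuning import RecordingGeometry, TonotopicFit

#: Spread of excitation in octaves at criterion d' = 1.5/2/2.5/3: published
#: reference values from a prior acoustic/fiber/electrical-implant study in
#: the same preparation, reprinted for plotting comparison curves only —
#: not recomputed by this package.
REFERENCE_SPREAD_OCTAVES = {
    "acoustic": {1.5: 0.89, 2.0: 1.42, 2.5: 1.73, 3.0: 2.23},
    "fiber": {1.5: 1.07, 2.0: 1.89, 2.5: 2.96, 3.0: 3.57},
    "eCI_monopolar": {1.5: 2.06, 2.0: 4.92, 2.5: 6.91, 3.0: 7.29},
    "eCI_bipolar": {1.5: 0.67, 2.0: 3.90, 2.5: 5.89, 3.0: 6.96},
}


@dataclass
class PlaceCodePoint:
    """One responsive emitter, relative to the apical-most responsive emitter.

    ``emitter_position_mm`` grows toward the cochlear base; the BE shift is
    positive toward ventral (higher-frequency) recording sites. The reference
    emitter maps to (0, 0); negative shifts can occur when a more basal
    emitter yields a more dorsal BE.
    """

    emitter_position_mm: float
    relative_be_electrodes: float
    animal_id: str = ""
    emitter_mode: str = "single"


@dataclass
class PlaceCodeFit:
    slope_electrodes_per_mm: float
    pearson_r: float
    p_value: float
    n_points: int
    intercept_electrodes: float = 0.0


def normalize_be_positions(
    stcs_by_emitter: Mapping[int, "object"],
    layout,
    *,
    animal_id: str = "",
    mode: str = "single",
) -> list[PlaceCodePoint]:
    """Build place-code points from per-emitter STCs of one implant.

    ``stcs_by_emitter`` maps emitter index (0-based on the implant, 0 = most
    basal) to its :class:`~ocipipe.stc.SpatialTuningCurve`. Emitters without
    a best electrode are unresponsive and dropped; if none is responsive the
    list is empty. The apical-most responsive emitter is the reference.
    """
    positions = layout.positions_mm()
    resp = {
        e: s for e, s in stcs_by_emitter.items() if s.best_electrode is not None
    }
    if not resp:
        return []
    ref = max(resp, key=lambda e: positions[e])
    ref_place = positions[ref]
    ref_be = resp[ref].best_electrode
    return [
        PlaceCodePoint(
            emitter_position_mm=float(ref_place - positions[e]),
            relative_be_electrodes=float(s.best_electrode - ref_be),
            animal_id=animal_id,
            emitter_mode=mode,
        )
        for e, s in sorted(resp.items())
    ]


def fit_place_code(points) -> PlaceCodeFit:
    """Least-squares slope of relative BE on emitter position, with Pearson r
    and its two-sided p-value."""
    points = list(points)
    if len(points) < 3:
        raise ValueError("place-code fit needs at least 3 points")
    x = np.array([p.emitter_position_mm for p in points])
    y = np.array([p.relative_be_electrodes for p in points])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: all emitters at the same place")
    res = stats.linregress(x, y)
    return PlaceCodeFit(
        slope_electrodes_per_mm=float(res.slope),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_points=len(points),
        intercept_electrodes=float(res.intercept),
    )


def spatial_to_spectral(span_mm: float, fit) -> float:
    """Convert a spatial span in the ICC (mm) to octaves via a tonotopic slope.

    ``fit`` is a :class:`~ocipipe.tuning.TonotopicFit` or a plain slope in
    octaves/mm (e.g. the hearing-cohort median assigned to deaf animals).
    """
    if isinstance(fit, TonotopicFit):
        if not fit.valid:
            raise ValueError(
                "invalid tonotopic fit; pass the hearing-cohort median slope instead"
            )
        slope = fit.slope_oct_per_mm
    else:
        slope = float(fit)
    if not np.isfinite(slope) or slope <= 0:
        raise ValueError("tonotopic slope must be a positive, finite octaves/mm value")
    if span_mm < 0:
        raise ValueError("span must be non-negative")
    return float(span_mm * slope)


def spectral_to_spatial(span_octaves: float, fit) -> float:
    """Inverse of :func:`spatial_to_spectral` (octaves → mm)."""
    if isinstance(fit, TonotopicFit):
        fit = fit.slope_oct_per_mm
    return float(span_octaves) / float(fit)


def electrodes_to_um(shift_electrodes: float, geometry: RecordingGeometry = RecordingGeometry()) -> float:
    """Convert a BE shift in electrodes to μm along the probe."""
    return float(shift_electrodes) * geometry.pitch_mm * 1e3


def coverage_stats(layout, model) -> tuple[float, float]:
    """Implant span (mm) and percent of cochlear length covered (1 decimal)."""
    span = (layout.n_emitters - 1) * layout.pitch_mm
    percent = round(100.0 * span / model.length_mm, 1)
    return float(span), float(percent)


def pulse_energy(power_mw: float, duration_ms: float) -> float:
    """Optical pulse energy in μJ (mW × ms)."""
    if power_mw < 0 or duration_ms < 0:
        raise ValueError("power and duration must be non-negative")
    return float(power_mw) * float(duration_ms)
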