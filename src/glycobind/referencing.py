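"""Background correction of raw sensorgrams.

SPR instruments record, besides the active ligand spot, *interspot*
regions of the sensor surface that see the analyte flow but carry no
immobilized ligand; subtracting the interspot trace removes drift and
bulk refractive-index offsets. A *blank* (zero-concentration) injection
on the active spot captures whatever systematic signal survives the
interspot subtraction. Double referencing applies both corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError, ValidationError
from .models import Sensorgram, SensorgramSeries

__all__ = [
    "ReferencedSet",
    "double_reference",
    "double_reference_series",
    "zero_baseline",
]


def _check_same_grid(a: Sensorgram, b: Sensorgram, what: str) -> None:
    # exact match required: resampling would silently smooth kinetics
    if a.time.shape != b.time.shape or not np.array_equal(a.time, b.time):
        raise GridMismatchError(f"{what} time grid differs from the raw trace")


@dataclass
class ReferencedSet:
    """A raw trace together with its reference channels and correction."""

    raw: Sensorgram
    interspot: Sensorgram
    blank: Sensorgram
    corrected: Sensorgram | None = None


def double_reference(raw: Sensorgram, interspot: Sensorgram,
                     blank: Sensorgram) -> Sensorgram:
    """Interspot- and blank-correct a raw sensorgram.

    corrected(t) = raw(t) - interspot(t) - blank(t), in one pass; the
    blank channel is expected to be interspot-corrected already.
    Metadata (concentration, schedule, label) is copied from ``raw``.
    """
    _check_same_grid(raw, interspot, "interspot")
    _check_same_grid(raw, blank, "blank")
    return Sensorgram(
        raw.time.copy(),
        raw.response - interspot.response - blank.response,
        raw.conc,
        raw.schedule,
        label=raw.label,
        conc_b=raw.conc_b,
    )


def double_reference_series(active: SensorgramSeries,
                            interspot: SensorgramSeries,
                            blank: Sensorgram) -> SensorgramSeries:
    """Double-reference every curve of a titration series.

    Curves are paired with interspot traces by position; the single blank
    injection is shared across all curves.
    """
    if len(active.curves) != len(interspot.curves):
        raise ValidationError("active and interspot series differ in curve count")
    corrected = [
        double_reference(raw, ref, blank)
        for raw, ref in zip(active.curves, interspot.curves)
    ]
    return SensorgramSeries(corrected, surface_label=active.surface_label)


def zero_baseline(s: Sensorgram, window_s: float) -> Sensorgram:
    """Zero a trace on its pre-injection baseline.

    Subtracts the mean response over the window ``[-window_s, 0)`` of
    pre-injection samples (carried with negative times). Requires at
    least two samples in the window.
    """
    if window_s <= 0:
        raise ValidationError("window_s must be > 0")
    mask = (s.time < 0) & (s.time >= -window_s)
    if int(mask.sum()) < 2:
        raise ValidationError(
            "zero_baseline needs >= 2 pre-injection samples in the window"
        )
    offset = float(s.response[mask].mean())
    return Sensorgram(
        s.time.copy(), s.response - offset, s.conc, s.schedule,
        label=s.label, conc_b=s.conc_b,
    )
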