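"""Delimited-text readers and writers for sensorgrams, ELISA curves,
energy series, and JSON fit reports.

All tables are comma-separated UTF-8 with "." decimals and a mandatory
header. Concentrations are always stored in molar; sensorgram files carry
the phase schedule in a leading ``#``-comment line so that a written
series round-trips without external metadata.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .elisa import DoseResponseCurve, DoseResponseMode
from .errors import ParseError, ValidationError
from .fitting import FitResult, ModelSelectionReport
from .models import PhaseSchedule, Sensorgram, SensorgramSeries
from .synthetic import FixtureSet, SensorgramChannels

__all__ = [
    "write_sensorgram_table",
    "read_sensorgram_table",
    "write_dose_response",
    "read_dose_response",
    "read_energy_series",
    "write_report",
    "write_fixture_table",
    "write_potency_table",
]

_SENSORGRAM_COLUMNS = ["curve_id", "conc_M", "time_s", "response_RU", "channel"]
_SCHEDULE_RE = re.compile(
    r"#\s*schedule:\s*t_assoc=([\d.eE+-]+)\s+t_dissoc=([\d.eE+-]+)\s+dt=([\d.eE+-]+)"
)

# concentration-unit factors to molar, for dose-response headers conc_<unit>
_UNIT_TO_M = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def _curve_rows(curve: Sensorgram, curve_id: str, channel: str) -> pd.DataFrame:
    return pd.DataFrame({
        "curve_id": curve_id,
        "conc_M": curve.conc,
        "time_s": curve.time,
        "response_RU": curve.response,
        "channel": channel,
    })


def write_sensorgram_table(path, data: SensorgramChannels | SensorgramSeries) -> None:
    """Write a series (or full channel set) as a long-format CSV."""
    if isinstance(data, SensorgramSeries):
        active, interspot, blank = data, None, None
    else:
        active, interspot, blank = data.active, data.interspot, data.blank
    frames = []
    for i, c in enumerate(active.curves):
        cid = c.label or f"c{i}"
        frames.append(_curve_rows(c, cid, "active"))
    if interspot is not None:
        for i, c in enumerate(interspot.curves):
            cid = c.label or f"c{i}"
            frames.append(_curve_rows(c, cid, "interspot"))
    if blank is not None:
        frames.append(_curve_rows(blank, "blank", "blank"))
    table = pd.concat(frames, ignore_index=True)
    sched = active.schedule
    with open(path, "w", encoding="utf-8") as fh:
        if sched is not None:
            fh.write(
                f"# schedule: t_assoc={sched.t_assoc!r} "
                f"t_dissoc={sched.t_dissoc!r} dt={sched.dt!r}\n"
            )
        table.to_csv(fh, index=False, float_format="%.17g")


def _numeric_column(raw: pd.Series, name: str, header_lines: int) -> np.ndarray:
    # numpy's parser round-trips full float precision (pandas to_numeric
    # does not); fall back to per-cell conversion only to localize errors
    if not raw.isna().any():
        try:
            return raw.to_numpy(dtype=float)
        except (TypeError, ValueError):
            pass
    for row, val in enumerate(raw.to_numpy()):
        where = f"column {name!r} at line {row + header_lines + 2}"
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise ParseError(f"missing value in {where}")
        try:
            float(val)
        except (TypeError, ValueError):
            raise ParseError(f"non-numeric value {val!r} in {where}") from None
    raise ParseError(f"cannot convert column {name!r} to numbers")


def read_sensorgram_table(path, schedule: PhaseSchedule | None = None,
                          ) -> SensorgramChannels:
    """Read a sensorgram CSV written by :func:`write_sensorgram_table`.

    Returns the active series plus interspot/blank channels when present
    (``interspot``/``blank`` are ``None`` otherwise — callers needing only
    the titration use ``.active``). The schedule is taken from the file's
    comment line unless overridden.
    """
    path = Path(path)
    try:
        text_head = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if not text_head.strip():
        raise ParseError(f"{path} is empty")
    header_lines = 0
    for line in text_head.splitlines():
        if not line.startswith("#"):
            break
        m = _SCHEDULE_RE.match(line)
        if m and schedule is None:
            schedule = PhaseSchedule(*(float(g) for g in m.groups()))
        header_lines += 1
    try:
        raw = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _SENSORGRAM_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    raw = raw.reset_index(drop=True)
    conc = _numeric_column(raw["conc_M"], "conc_M", header_lines)
    time = _numeric_column(raw["time_s"], "time_s", header_lines)
    resp = _numeric_column(raw["response_RU"], "response_RU", header_lines)
    channel = raw["channel"].astype(str)
    curve_id = raw["curve_id"].astype(str)

    def build(channel_name: str) -> list[Sensorgram]:
        mask = (channel == channel_name).to_numpy()
        curves = []
        for cid in pd.unique(curve_id[mask]):
            sel = mask & (curve_id == cid).to_numpy()
            c_vals = np.unique(conc[sel])
            if c_vals.size != 1:
                raise ParseError(
                    f"{path}: curve {cid!r}/{channel_name} has inconsistent conc_M"
                )
            try:
                curves.append(Sensorgram(time[sel], resp[sel], float(c_vals[0]),
                                         schedule, label=str(cid)))
            except ValidationError as exc:
                raise ParseError(f"{path}: curve {cid!r}/{channel_name}: {exc}") from exc
        return curves

    active_curves = build("active")
    if not active_curves:
        raise ParseError(f"{path}: no active-channel rows")
    try:
        active = SensorgramSeries(active_curves)
        inter_curves = build("interspot")
        interspot = SensorgramSeries(inter_curves) if inter_curves else None
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    blanks = build("blank")
    blank = blanks[0] if blanks else None
    if blank is not None and (blank.time.shape != active.time.shape
                              or not np.array_equal(blank.time, active.time)):
        raise ParseError(f"{path}: blank channel grid differs from active grid")
    return SensorgramChannels(active=active, interspot=interspot, blank=blank)


def write_dose_response(path, curve: DoseResponseCurve) -> None:
    unit = curve.conc_unit
    if unit not in _UNIT_TO_M:
        raise ValidationError(f"unknown concentration unit {unit!r}")
    pd.DataFrame({f"conc_{unit}": curve.conc, "signal": curve.signal}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_dose_response(path, mode: DoseResponseMode | str) -> DoseResponseCurve:
    """Read a two-column dose-response CSV; the header names the unit
    (``conc_uM`` etc.) and concentrations stay in that unit."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    conc_cols = [c for c in raw.columns if c.startswith("conc")]
    if not conc_cols or "signal" not in raw.columns:
        raise ParseError(f"{path}: expected columns conc_<unit> and signal")
    conc_col = conc_cols[0]
    unit = conc_col.split("_", 1)[1] if "_" in conc_col else "M"
    if unit not in _UNIT_TO_M:
        raise ParseError(f"{path}: unknown concentration unit {unit!r}")
    conc = _numeric_column(raw[conc_col], conc_col, 0)
    signal = _numeric_column(raw["signal"], "signal", 0)
    try:
        return DoseResponseCurve(conc, signal, mode, conc_unit=unit)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_energy_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an interaction-energy trajectory (time_ps, energy_kJ_mol)."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    for col in ("time_ps", "energy_kJ_mol"):
        if col not in raw.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    t = _numeric_column(raw["time_ps"], "time_ps", 0)
    e = _numeric_column(raw["energy_kJ_mol"], "energy_kJ_mol", 0)
    return t, e


def write_report(path, result: FitResult | ModelSelectionReport | dict,
                 include_curves: bool = False) -> None:
    """Serialize a fit or model-selection report as versioned JSON."""
    if isinstance(result, FitResult):
        payload = result.to_dict(include_curves=include_curves)
    elif isinstance(result, ModelSelectionReport):
        payload = result.to_dict()
    else:
        payload = result
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_fixture_table(path, fixtures: FixtureSet) -> None:
    fixtures.to_frame().to_csv(path, index=False)


def write_potency_table(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)
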