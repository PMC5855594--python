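"""Synthetic sensorgram and ELISA data with the structure the fits assume.

The generator emulates a parallel-injection SPR titration: one noise-free
kinetic trace per analyte concentration plus the systematic components the
referencing step removes (linear baseline drift, a square bulk
refractive-index pulse during the injection) and additive Gaussian noise.
An interspot channel (drift + bulk + independent noise, no binding) and a
blank injection (zero-concentration curve, same noise law, already
interspot-corrected) are generated alongside. ELISA curves are one-site
saturation or four-parameter-logistic inhibition responses plus noise.

``table_fixtures`` transcribes the reported central values of the
galectin-3 neo-glycoprotein ligand series (ELISA potencies and SPR rate
constants) used throughout the tests as parameter regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elisa import DoseResponseCurve, DoseResponseMode
from .errors import ValidationError
from .models import (
    KineticParams,
    ModelKind,
    PhaseSchedule,
    Sensorgram,
    SensorgramSeries,
    simulate,
)

__all__ = [
    "NoiseSpec",
    "SensorgramChannels",
    "FixtureEntry",
    "FixtureSet",
    "SPR_NOISE_SD",
    "ELISA_NOISE_SD",
    "DIRECT_SETUP_LADDER",
    "REVERSED_SETUP_LADDER",
    "serial_dilution",
    "generate_sensorgram_series",
    "generate_saturation_curve",
    "generate_inhibition_curve",
    "table_fixtures",
]

#: Default additive Gaussian noise amplitudes: 0.5 RU for sensorgrams,
#: 0.02 absorbance units for ELISA signals.
SPR_NOISE_SD = 0.5
ELISA_NOISE_SD = 0.02


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model of the generator.

    ``sd`` is the Gaussian noise amplitude (RU or absorbance units),
    ``drift`` a linear baseline drift (RU/s), ``bulk`` a square-pulse
    offset during the injection (RU). A fixed ``seed`` makes the output
    byte-identical across runs.
    """

    sd: float = SPR_NOISE_SD
    drift: float = 0.0
    bulk: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("noise sd must be >= 0")


@dataclass
class SensorgramChannels:
    """Generator output: active series, interspot series, blank injection."""

    active: SensorgramSeries
    interspot: SensorgramSeries
    blank: Sensorgram


def serial_dilution(top: float, factor: float, n: int) -> list[float]:
    """Descending concentration ladder [top, top/factor, ...] of length n."""
    if not top > 0:
        raise ValidationError("top must be > 0")
    if not factor > 1:
        raise ValidationError("factor must be > 1")
    if n < 1:
        raise ValidationError("n must be >= 1")
    return [top / factor ** i for i in range(n)]


#: Analyte ladders of the two experimental orientations: sub-nanomolar
#: neo-glycoprotein dilutions over immobilized lectin, and the 16-250 nM
#: lectin range of the reversed setup (also used for the ASF standard).
DIRECT_SETUP_LADDER = serial_dilution(250e-12, 2.0, 5)
REVERSED_SETUP_LADDER = serial_dilution(250e-9, 2.0, 5)


def generate_sensorgram_series(params: KineticParams, concs: list[float],
                               sched: PhaseSchedule,
                               noise: NoiseSpec = NoiseSpec(),
                               conc_b: list[float] | None = None,
                               ) -> SensorgramChannels:
    """Generate a noisy titration series with paired reference channels.

    Each active curve is model trace + drift*t + bulk (during association)
    + Gaussian noise; the interspot curve sees the same systematics and
    independent noise but no binding; the blank is a zero-concentration
    injection under the same noise law, provided interspot-corrected (its
    systematic components already removed).
    """
    if len(concs) < 1:
        raise ValidationError("need at least one concentration")
    kind = ModelKind(params.kind)
    conc_b = conc_b if conc_b is not None else [0.0] * len(concs)
    if len(conc_b) != len(concs):
        raise ValidationError("conc_b must match concs in length")
    rng = np.random.default_rng(noise.seed)
    t = sched.time_grid()
    systematic = noise.drift * t + noise.bulk * (t <= sched.t_assoc)
    active, inter = [], []
    for i, (c, cb) in enumerate(zip(concs, conc_b)):
        clean = simulate(params, c, sched, conc_b=cb)
        label = f"c{i}"
        active.append(Sensorgram(
            t, clean.response + systematic + rng.normal(0.0, noise.sd, t.size),
            c, sched, label=label, conc_b=cb,
        ))
        inter.append(Sensorgram(
            t, systematic + rng.normal(0.0, noise.sd, t.size),
            c, sched, label=label, conc_b=cb,
        ))
    blank = Sensorgram(t, rng.normal(0.0, noise.sd, t.size), 0.0, sched, label="blank")
    return SensorgramChannels(
        active=SensorgramSeries(active, surface_label=kind.value),
        interspot=SensorgramSeries(inter, surface_label="interspot"),
        blank=blank,
    )


def generate_saturation_curve(kd: float, smax: float, background: float,
                              concs: list[float],
                              noise: NoiseSpec = NoiseSpec(sd=ELISA_NOISE_SD),
                              ) -> DoseResponseCurve:
    """One-site saturation binding curve plus seeded Gaussian noise."""
    if not kd > 0:
        raise ValidationError("kd must be > 0")
    c = np.asarray(concs, dtype=float)
    rng = np.random.default_rng(noise.seed)
    signal = background + smax * c / (kd + c) + rng.normal(0.0, noise.sd, c.size)
    return DoseResponseCurve(c, signal, DoseResponseMode.SATURATION)


def generate_inhibition_curve(ic50: float, top: float, bottom: float,
                              hill: float, concs: list[float],
                              noise: NoiseSpec = NoiseSpec(sd=ELISA_NOISE_SD),
                              ) -> DoseResponseCurve:
    """Four-parameter logistic inhibition curve plus seeded Gaussian noise."""
    if not ic50 > 0:
        raise ValidationError("ic50 must be > 0")
    c = np.asarray(concs, dtype=float)
    if np.any(c <= 0):
        raise ValidationError("inhibition concentrations must be > 0")
    rng = np.random.default_rng(noise.seed)
    signal = (bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)
              + rng.normal(0.0, noise.sd, c.size))
    return DoseResponseCurve(c, signal, DoseResponseMode.INHIBITION)


# ---------------------------------------------------------------------------
# reported parameter fixtures

@dataclass(frozen=True)
class FixtureEntry:
    """Reported central values for one compound of the ligand series.

    SPR fields (``ka``, ``kd``, ``kd_eq``) are None where the interaction
    was too weak to resolve kinetics. ``provenance`` names the assay each
    field came from.
    """

    label: str
    glycan: str
    mw_kda: float | None = None
    m: float | None = None
    ic50_glycan_uM: float | None = None
    ic50_neo_nM: float | None = None
    rp: float | None = None
    rp_per_glycan: float | None = None
    elisa_kd_nM: float | None = None
    ka: float | None = None
    kd: float | None = None
    kd_eq: float | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class FixtureSet:
    """All reported central values of the ligand series, keyed by label."""

    entries: dict[str, FixtureEntry]

    def __getitem__(self, label: str) -> FixtureEntry:
        return self.entries[label]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries.values():
            rows.append({
                "label": e.label, "glycan": e.glycan, "mw_kda": e.mw_kda,
                "m": e.m, "ic50_glycan_uM": e.ic50_glycan_uM,
                "ic50_neo_nM": e.ic50_neo_nM, "rp": e.rp,
                "rp_per_glycan": e.rp_per_glycan, "elisa_kd_nM": e.elisa_kd_nM,
                "ka_M1s1": e.ka, "kd_s1": e.kd, "KD_M": e.kd_eq,
            })
        return pd.DataFrame(rows)


_ELISA_SRC = "reported competitive/direct ELISA potency table"
_SPR_SRC = "reported SPR kinetics, immobilized-lectin orientation"


def _entry(label, glycan, mw, m, ic50_g, ic50_n, rp, rpm, ekd,
           ka=None, kd=None, kd_eq=None) -> FixtureEntry:
    prov = {f: _ELISA_SRC for f in
            ("mw_kda", "m", "ic50_glycan_uM", "ic50_neo_nM", "rp",
             "rp_per_glycan", "elisa_kd_nM")}
    if ka is not None:
        prov.update({f: _SPR_SRC for f in ("ka", "kd", "kd_eq")})
    return FixtureEntry(label, glycan, mw, m, ic50_g, ic50_n, rp, rpm, ekd,
                        ka, kd, kd_eq, prov)


def table_fixtures() -> FixtureSet:
    """Reported central values of the neo-glycoprotein series.

    ELISA: IC50 of the monovalent glycan (µM) and of the neo-glycoprotein
    (nM), glycans per carrier m, relative potencies, and apparent Kd (nM).
    SPR: ka (M^-1 s^-1), kd (s^-1), KD (M) for the immobilized-lectin
    orientation; the disaccharide conjugates gave no measurable kinetics.
    Lactose is the monovalent positive control, asialofetuin (ASF) the
    multivalent standard ligand.
    """
    entries = {
        "9": _entry("9", "LacdiNAc", 76.4, 17, 42.0, 2026.0, 20.7, 1.2, 6290.0),
        "10": _entry("10", "LacNAc", 78.2, 18, 36.0, 344.0, 104.7, 5.8, 4780.0),
        "11": _entry("11", "LacdiNAc-LacNAc", 87.4, 21, 7.0, 11.0, 642.9, 30.6,
                     30.0, ka=5.9e6, kd=8.5e-5, kd_eq=1.4e-11),
        "12": _entry("12", "LacNAc-LacNAc", 84.7, 19, 13.0, 31.0, 419.4, 22.1,
                     300.0, ka=6.2e6, kd=4.2e-4, kd_eq=6.8e-11),
        "13": _entry("13", "LacdiNAc-LacNAc-LacNAc", 86.6, 16, 6.20, 37.0,
                     169.9, 10.6, 76.0, ka=5.8e6, kd=1.5e-4, kd_eq=2.6e-11),
        "14": _entry("14", "LacNAc-LacNAc-LacNAc", 86.6, 17, 20.1, 76.0,
                     263.4, 15.5, 350.0, ka=7.8e6, kd=5.1e-4, kd_eq=6.5e-11),
        "15": _entry("15", "LacNAc type 1-LacNAc-LacNAc", 85.9, 17, 12.5,
                     212.0, 58.9, 3.5, 700.0, ka=4.9e6, kd=1.3e-3, kd_eq=2.7e-10),
        "16": _entry("16", "Galili-LacNAc-LacNAc", 89.6, 18, 8.4, 65.0,
                     128.2, 7.1, 290.0, ka=9.3e6, kd=6.3e-4, kd_eq=6.8e-11),
        "ASF": FixtureEntry(
            "ASF", "asialofetuin standard", ka=4.8e4, kd=4.0e-4, kd_eq=8.3e-9,
            provenance={f: _SPR_SRC for f in ("ka", "kd", "kd_eq")},
        ),
        "lactose": FixtureEntry(
            "lactose", "lactose control", ic50_glycan_uM=137.0,
            provenance={"ic50_glycan_uM": _ELISA_SRC},
        ),
    }
    return FixtureSet(entries)
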