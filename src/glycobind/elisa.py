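"""ELISA dose-response fitting and multivalency (cluster glycoside) metrics.

Two assay designs are covered. In the direct (saturation) design, the
lectin is titrated over an immobilized neo-glycoprotein and the bound
fraction follows one-site specific binding, giving an apparent Kd. In the
competitive design, a soluble glycan or neo-glycoprotein inhibits lectin
binding to an immobilized reference glycoprotein and the signal follows a
four-parameter logistic in the inhibitor concentration, giving an IC50.

Multivalent presentation of m glycans on a carrier protein is quantified
by the relative potency rp = IC50(monovalent glycan)/IC50(neo-glycoprotein)
(both in one common unit) and by rp/m, the potency gain per presented
glycan; rp/m > 1 indicates a cluster glycoside effect.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .errors import ValidationError

__all__ = [
    "DoseResponseMode",
    "DoseResponseCurve",
    "SaturationFit",
    "InhibitionFit",
    "PotencyRecord",
    "fit_saturation",
    "fit_inhibition",
    "relative_potency",
]


class DoseResponseMode(str, enum.Enum):
    SATURATION = "saturation"
    INHIBITION = "inhibition"


@dataclass
class DoseResponseCurve:
    """Concentration-signal pairs from one ELISA titration.

    Concentrations are in the unit named by ``conc_unit`` (molar by
    default); the signal is absorbance at 450 nm in arbitrary units.
    """

    conc: np.ndarray
    signal: np.ndarray
    mode: DoseResponseMode
    conc_unit: str = "M"
    label: str = ""

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.mode = DoseResponseMode(self.mode)
        if self.conc.ndim != 1 or self.conc.shape != self.signal.shape:
            raise ValidationError("conc and signal must be 1-d arrays of equal length")
        if self.conc.size < 5:
            raise ValidationError("dose-response fitting needs >= 5 points")
        if np.any(self.conc < 0):
            raise ValidationError("concentrations must be >= 0")
        if np.unique(self.conc).size != self.conc.size:
            raise ValidationError("concentrations must be pairwise distinct")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal must be finite")


def _one_site(c, kd, smax, background):
    return background + smax * c / (kd + c)


def _logistic4(c, ic50, top, bottom, hill):
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


@dataclass
class SaturationFit:
    """One-site specific-binding fit S(c) = bg + Smax c / (Kd + c)."""

    kd: float
    smax: float
    background: float
    stderr: dict[str, float]
    rss: float
    n: int
    warnings: list[str] = field(default_factory=list)

    def predict(self, c):
        return _one_site(np.asarray(c, dtype=float), self.kd, self.smax, self.background)


@dataclass
class InhibitionFit:
    """Four-parameter logistic fit of a sigmoidal inhibition curve.

    ``ic50`` is reported in the concentration unit of the input curve.
    """

    ic50: float
    top: float
    bottom: float
    hill: float
    stderr: dict[str, float]
    rss: float
    n: int
    warnings: list[str] = field(default_factory=list)

    def predict(self, c):
        return _logistic4(np.asarray(c, dtype=float), self.ic50, self.top,
                          self.bottom, self.hill)


def _se(result, name) -> float:
    err = result.params[name].stderr
    return float(err) if err is not None else float("nan")


def fit_saturation(curve: DoseResponseCurve) -> SaturationFit:
    """Fit an apparent dissociation constant to a saturation binding curve.

    Nonlinear least squares on the one-site model; an ill-conditioning
    warning is attached when the fitted Kd falls more than 100-fold
    outside the sampled concentration range (no curvature in the data).
    """
    if curve.mode is not DoseResponseMode.SATURATION:
        raise ValidationError("curve.mode must be saturation")
    c, y = curve.conc, curve.signal
    model = Model(_one_site)
    span = float(y.max() - y.min())
    pos = c[c > 0]
    kd0 = float(np.median(pos)) if pos.size else 1.0
    params = model.make_params(
        kd=dict(value=kd0, min=1e-30),
        smax=dict(value=max(span, 1e-12), min=0.0),
        background=float(y.min()),
    )
    out = model.fit(y, params, c=c)
    fit = SaturationFit(
        kd=float(out.params["kd"].value),
        smax=float(out.params["smax"].value),
        background=float(out.params["background"].value),
        stderr={n: _se(out, n) for n in ("kd", "smax", "background")},
        rss=float(np.sum(out.residual ** 2)),
        n=c.size,
    )
    cmax = float(pos.max()) if pos.size else 0.0
    cmin = float(pos.min()) if pos.size else 0.0
    if cmax and (fit.kd > 100.0 * cmax or fit.kd < cmin / 100.0):
        fit.warnings.append(
            f"ill-conditioned: fitted Kd {fit.kd:.3g} lies >100x outside the "
            f"sampled range [{cmin:.3g}, {cmax:.3g}]"
        )
    return fit


def fit_inhibition(curve: DoseResponseCurve) -> InhibitionFit:
    """Fit an IC50 to a sigmoidal competitive-inhibition curve.

    Four-parameter logistic with the Hill slope free within [0.3, 5]; a
    poor-fit warning with RSS diagnostics is attached when the model
    leaves most of the signal variance unexplained (non-monotone data
    beyond noise).
    """
    if curve.mode is not DoseResponseMode.INHIBITION:
        raise ValidationError("curve.mode must be inhibition")
    if np.any(curve.conc <= 0):
        raise ValidationError("inhibition fitting needs strictly positive concentrations")
    c, y = curve.conc, curve.signal
    model = Model(_logistic4)
    # midpoint guess: concentration where the signal crosses half-range
    half = 0.5 * (y.max() + y.min())
    order = np.argsort(c)
    crossing = c[order][np.argmin(np.abs(y[order] - half))]
    params = model.make_params(
        ic50=dict(value=float(crossing), min=c.min() / 1e6, max=c.max() * 1e6),
        top=float(y.max()),
        bottom=float(y.min()),
        hill=dict(value=1.0, min=0.3, max=5.0),
    )
    out = model.fit(y, params, c=c)
    rss = float(np.sum(out.residual ** 2))
    fit = InhibitionFit(
        ic50=float(out.params["ic50"].value),
        top=float(out.params["top"].value),
        bottom=float(out.params["bottom"].value),
        hill=float(out.params["hill"].value),
        stderr={n: _se(out, n) for n in ("ic50", "top", "bottom", "hill")},
        rss=rss,
        n=c.size,
    )
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss > 0 and rss > 0.5 * tss:
        fit.warnings.append(
            f"poor fit: RSS {rss:.3g} explains <50% of signal variance "
            f"(TSS {tss:.3g}); data may be non-monotone beyond noise"
        )
    return fit


@dataclass(frozen=True)
class PotencyRecord:
    """Multivalency metrics of one neo-glycoprotein.

    ``rp`` is the IC50 ratio monovalent-glycan / neo-glycoprotein after
    converting both to nanomolar; ``rp_per_glycan`` divides by the average
    number of glycans per carrier molecule.
    """

    ic50_glycan_uM: float
    ic50_neo_nM: float
    m: float
    rp: float
    rp_per_glycan: float


def relative_potency(ic50_glycan_uM: float, ic50_neo_nM: float,
                     m: float) -> PotencyRecord:
    """Relative inhibitory potency of a multivalent conjugate.

    Both IC50 values are brought to nanomolar before the ratio is taken,
    so the result is invariant to the common unit chosen.
    """
    if not (ic50_glycan_uM > 0 and ic50_neo_nM > 0 and m > 0):
        raise ValidationError("relative_potency needs positive inputs")
    rp = (ic50_glycan_uM * 1000.0) / ic50_neo_nM
    return PotencyRecord(
        ic50_glycan_uM=ic50_glycan_uM,
        ic50_neo_nM=ic50_neo_nM,
        m=m,
        rp=rp,
        rp_per_glycan=rp / m,
    )
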