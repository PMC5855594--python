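"""Kinetic binding models and forward simulation of SPR sensorgrams.

A surface plasmon resonance (SPR) experiment immobilizes one binding
partner (the *ligand*, here galectin-3 or a neo-glycoprotein) on a sensor
surface and flows the other (the *analyte*) over it. The instrument reports
a response R(t) in relative units (RU), proportional to bound mass. An
injection of analyte at concentration C drives the association phase; a
subsequent buffer wash drives dissociation.

Four interaction schemes are supported:

``langmuir_1to1``
    Single-step reversible binding A + L <-> AL with rate constants ka
    (M^-1 s^-1) and kd (s^-1). Closed form; KD = kd/ka.
``heterogeneous_ligand``
    Two independent immobilized site classes, each with its own rates and
    capacity; the response is the sum of two 1:1 terms.
``bivalent_analyte``
    The analyte first attaches through one site (forming AL), then may
    bridge a second ligand (AL2). Numerically integrated.
``heterogeneous_analyte``
    Two analyte species compete for one shared surface capacity.
    Numerically integrated.

Units are fixed package-wide: time in seconds, concentration in molar,
response in RU, ka in M^-1 s^-1, kd in s^-1.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, UnsupportedModelError, ValidationError

__all__ = [
    "ModelKind",
    "KineticParams",
    "PhaseSchedule",
    "Sensorgram",
    "SensorgramSeries",
    "Affinity",
    "simulate",
    "simulate_langmuir",
    "simulate_heterogeneous_ligand",
    "simulate_bivalent_analyte",
    "simulate_heterogeneous_analyte",
    "equilibrium_response",
    "kd_from_rates",
    "response_at",
]

#: Tolerances for the adaptive integration (LSODA: Adams/BDF with
#: automatic stiffness switching, needed for fast-on/fast-off corners of
#: the bounds) of the ODE model kinds; chosen to out-resolve the 1e-6
#: closed-form comparison tolerance.
ODE_RTOL = 1e-8
ODE_ATOL = 1e-10


class ModelKind(str, enum.Enum):
    """Interaction scheme used to describe a sensorgram series."""

    LANGMUIR_1TO1 = "langmuir_1to1"
    HETEROGENEOUS_LIGAND = "heterogeneous_ligand"
    BIVALENT_ANALYTE = "bivalent_analyte"
    HETEROGENEOUS_ANALYTE = "heterogeneous_analyte"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class KineticParams:
    """Rate and capacity parameters of one kinetic model.

    Parameters
    ----------
    kind
        Interaction scheme.
    ka1, kd1
        Association (M^-1 s^-1) and dissociation (s^-1) rate constants of
        the first (or only) binding event.
    rmax1
        Surface capacity of the first site class (RU). For the bivalent
        and heterogeneous-analyte kinds this is the total shared capacity.
    ka2, kd2, rmax2
        Second-event parameters. For ``heterogeneous_ligand`` these are the
        rates and capacity of the second site class. For
        ``bivalent_analyte`` ka2 is the second-attachment rate in response
        units (RU^-1 s^-1) and rmax2 is unused. For
        ``heterogeneous_analyte`` they are the rates of the second analyte
        species (shared capacity rmax1). Ignored for ``langmuir_1to1``.
    """

    kind: ModelKind
    ka1: float
    kd1: float
    rmax1: float
    ka2: float | None = None
    kd2: float | None = None
    rmax2: float | None = None

    def __post_init__(self) -> None:
        kind = ModelKind(self.kind)
        object.__setattr__(self, "kind", kind)
        _require(math.isfinite(self.ka1) and self.ka1 > 0, "ka1 must be > 0")
        _require(math.isfinite(self.kd1) and self.kd1 > 0, "kd1 must be > 0")
        _require(math.isfinite(self.rmax1) and self.rmax1 >= 0, "rmax1 must be >= 0")
        if kind is ModelKind.LANGMUIR_1TO1:
            return
        if kind is ModelKind.BIVALENT_ANALYTE:
            _require(self.ka2 is not None and self.ka2 >= 0, "bivalent analyte needs ka2 >= 0")
            _require(self.kd2 is not None and self.kd2 > 0, "bivalent analyte needs kd2 > 0")
            return
        _require(self.ka2 is not None and self.ka2 > 0, f"{kind.value} needs ka2 > 0")
        _require(self.kd2 is not None and self.kd2 > 0, f"{kind.value} needs kd2 > 0")
        if kind is ModelKind.HETEROGENEOUS_LIGAND:
            _require(
                self.rmax2 is not None and self.rmax2 >= 0,
                "heterogeneous ligand needs rmax2 >= 0",
            )


@dataclass(frozen=True)
class PhaseSchedule:
    """Injection timing: association window, dissociation window, sampling.

    All times in seconds. The time grid starts at injection (t = 0) and
    runs to ``t_assoc + t_dissoc`` with spacing ``dt``.
    """

    t_assoc: float = 120.0
    t_dissoc: float = 600.0
    dt: float = 0.5

    def __post_init__(self) -> None:
        _require(self.t_assoc > 0, "t_assoc must be > 0")
        _require(self.t_dissoc >= 0, "t_dissoc must be >= 0")
        _require(self.dt > 0, "dt must be > 0")
        _require(self.dt < self.t_assoc, "dt must be smaller than t_assoc")

    def time_grid(self) -> np.ndarray:
        n = int(round((self.t_assoc + self.t_dissoc) / self.dt))
        return np.arange(n + 1) * self.dt


@dataclass
class Sensorgram:
    """One SPR trace: response versus time at a single analyte concentration.

    ``conc_b`` carries the concentration of the second analyte species for
    the heterogeneous-analyte scheme and is zero otherwise. Pre-injection
    samples, when present (baseline zeroing), carry negative times.
    """

    time: np.ndarray
    response: np.ndarray
    conc: float
    schedule: PhaseSchedule | None = None
    label: str = ""
    conc_b: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        _require(self.time.ndim == 1 and self.time.size >= 2, "time must be a 1-d array")
        _require(self.response.shape == self.time.shape, "time/response length mismatch")
        _require(bool(np.all(np.diff(self.time) > 0)), "time must be strictly increasing")
        _require(bool(np.all(np.isfinite(self.response))), "response must be finite")
        _require(self.conc >= 0, "conc must be >= 0")
        _require(self.conc_b >= 0, "conc_b must be >= 0")


@dataclass
class SensorgramSeries:
    """Sensorgrams sharing one ligand surface; the unit of global fitting."""

    curves: list[Sensorgram]
    surface_label: str = ""

    def __post_init__(self) -> None:
        _require(len(self.curves) >= 1, "series needs at least one curve")
        t0 = self.curves[0].time
        for c in self.curves[1:]:
            if c.time.shape != t0.shape or not np.allclose(c.time, t0, rtol=0, atol=1e-12):
                raise ValidationError("all curves in a series must share one time grid")
        concs = [(c.conc, c.conc_b) for c in self.curves]
        _require(len(set(concs)) == len(concs), "concentrations must be pairwise distinct")

    @property
    def concentrations(self) -> list[float]:
        return [c.conc for c in self.curves]

    @property
    def time(self) -> np.ndarray:
        return self.curves[0].time

    @property
    def schedule(self) -> PhaseSchedule | None:
        return self.curves[0].schedule


# ---------------------------------------------------------------------------
# closed forms

def _one_site(t: np.ndarray, t_assoc: float, ka: float, kd: float,
              rmax: float, conc: float) -> np.ndarray:
    """1:1 Langmuir closed form on an arbitrary (sorted, >= 0) time array.

    Association: R(t) = Req (1 - exp(-(ka C + kd) t)) with
    Req = ka C Rmax / (ka C + kd); dissociation decays from R(t_assoc)
    with rate kd.
    """
    kobs = ka * conc + kd
    req = ka * conc * rmax / kobs
    r = np.where(
        t <= t_assoc,
        req * -np.expm1(-kobs * np.minimum(t, t_assoc)),
        (req * -np.expm1(-kobs * t_assoc)) * np.exp(-kd * np.maximum(t - t_assoc, 0.0)),
    )
    return r


# ---------------------------------------------------------------------------
# ODE right-hand sides (two-phase integration: conc during association,
# zero during dissociation)

def _bivalent_rhs(t, y, ka1, kd1, ka2, kd2, rmax, conc):
    r1, r2 = y
    free = rmax - r1 - r2
    # statistical factor 2: two equivalent ways to make the first contact,
    # two equivalent bonds to break in the last detachment
    dr1 = 2.0 * ka1 * conc * free - kd1 * r1 - ka2 * r1 * free + 2.0 * kd2 * r2
    dr2 = ka2 * r1 * free - 2.0 * kd2 * r2
    return [dr1, dr2]


def _hetero_analyte_rhs(t, y, ka1, kd1, ka2, kd2, rmax, conc_a, conc_b):
    r1, r2 = y
    free = rmax - r1 - r2
    return [ka1 * conc_a * free - kd1 * r1, ka2 * conc_b * free - kd2 * r2]


def _integrate_two_phase(rhs, args_assoc, args_dissoc, t: np.ndarray,
                         t_assoc: float, params: KineticParams) -> np.ndarray:
    y0 = [0.0, 0.0]
    assoc_mask = t <= t_assoc
    out = np.empty((2, t.size))
    sol1 = solve_ivp(
        rhs, (0.0, t_assoc), y0, args=args_assoc, method="LSODA",
        rtol=ODE_RTOL, atol=ODE_ATOL, dense_output=True,
    )
    if not sol1.success:
        raise IntegrationError(f"association integration failed for {params}")
    if assoc_mask.any():
        out[:, assoc_mask] = sol1.sol(t[assoc_mask])
    if (~assoc_mask).any():
        y_assoc = sol1.sol(t_assoc)
        sol2 = solve_ivp(
            rhs, (t_assoc, float(t[-1])), y_assoc, args=args_dissoc, method="LSODA",
            rtol=ODE_RTOL, atol=ODE_ATOL, dense_output=True,
        )
        if not sol2.success:
            raise IntegrationError(f"dissociation integration failed for {params}")
        out[:, ~assoc_mask] = sol2.sol(t[~assoc_mask])
    return out


# ---------------------------------------------------------------------------
# public simulation API

def response_at(params: KineticParams, conc: float, t: np.ndarray,
                t_assoc: float, conc_b: float = 0.0) -> np.ndarray:
    """Noise-free model response on an arbitrary non-negative time array.

    This is the computational core shared by the forward simulators and the
    global fitter; ``t`` need not be the regular grid of a schedule.
    """
    t = np.asarray(t, dtype=float)
    kind = params.kind
    if kind is ModelKind.LANGMUIR_1TO1:
        return _one_site(t, t_assoc, params.ka1, params.kd1, params.rmax1, conc)
    if kind is ModelKind.HETEROGENEOUS_LIGAND:
        return (
            _one_site(t, t_assoc, params.ka1, params.kd1, params.rmax1, conc)
            + _one_site(t, t_assoc, params.ka2, params.kd2, params.rmax2, conc)
        )
    if kind is ModelKind.BIVALENT_ANALYTE:
        base = (params.ka1, params.kd1, params.ka2, params.kd2, params.rmax1)
        y = _integrate_two_phase(
            _bivalent_rhs, base + (conc,), base + (0.0,), t, t_assoc, params
        )
        return y[0] + y[1]
    if kind is ModelKind.HETEROGENEOUS_ANALYTE:
        base = (params.ka1, params.kd1, params.ka2, params.kd2, params.rmax1)
        y = _integrate_two_phase(
            _hetero_analyte_rhs, base + (conc, conc_b), base + (0.0, 0.0),
            t, t_assoc, params,
        )
        return y[0] + y[1]
    raise UnsupportedModelError(f"unknown model kind {kind!r}")


def _check_conc(conc: float) -> None:
    _require(math.isfinite(conc) and conc >= 0, "conc must be >= 0")


def simulate_langmuir(params: KineticParams, conc: float,
                      sched: PhaseSchedule) -> Sensorgram:
    """Simulate a noise-free 1:1 Langmuir sensorgram.

    The analyte A and immobilized ligand L form the complex AL directly;
    the association phase follows the mono-exponential closed form and the
    dissociation phase a single-exponential decay from R(t_assoc).
    """
    _require(params.kind is ModelKind.LANGMUIR_1TO1, "params.kind must be langmuir_1to1")
    _check_conc(conc)
    t = sched.time_grid()
    r = response_at(params, conc, t, sched.t_assoc)
    return Sensorgram(t, r, conc, sched, label="langmuir_1to1")


def simulate_heterogeneous_ligand(params: KineticParams, conc: float,
                                  sched: PhaseSchedule) -> Sensorgram:
    """Simulate two independent immobilized site classes (sum of 1:1 terms)."""
    _require(
        params.kind is ModelKind.HETEROGENEOUS_LIGAND,
        "params.kind must be heterogeneous_ligand",
    )
    _check_conc(conc)
    t = sched.time_grid()
    r = response_at(params, conc, t, sched.t_assoc)
    return Sensorgram(t, r, conc, sched, label="heterogeneous_ligand")


def simulate_bivalent_analyte(params: KineticParams, conc: float,
                              sched: PhaseSchedule) -> Sensorgram:
    """Simulate sequential two-point attachment of a bivalent analyte.

    State R1 counts singly attached analyte, R2 doubly attached; the
    surface capacity rmax1 is shared and the reported response is R1 + R2.
    """
    _require(params.kind is ModelKind.BIVALENT_ANALYTE, "params.kind must be bivalent_analyte")
    _check_conc(conc)
    t = sched.time_grid()
    r = response_at(params, conc, t, sched.t_assoc)
    return Sensorgram(t, r, conc, sched, label="bivalent_analyte")


def simulate_heterogeneous_analyte(params: KineticParams, conc_a: float,
                                   conc_b: float, sched: PhaseSchedule) -> Sensorgram:
    """Simulate two analyte species competing for one shared capacity."""
    _require(
        params.kind is ModelKind.HETEROGENEOUS_ANALYTE,
        "params.kind must be heterogeneous_analyte",
    )
    _check_conc(conc_a)
    _check_conc(conc_b)
    t = sched.time_grid()
    r = response_at(params, conc_a, t, sched.t_assoc, conc_b=conc_b)
    return Sensorgram(t, r, conc_a, sched, label="heterogeneous_analyte", conc_b=conc_b)


def simulate(params: KineticParams, conc: float, sched: PhaseSchedule,
             conc_b: float = 0.0) -> Sensorgram:
    """Dispatch to the simulator matching ``params.kind``."""
    kind = params.kind
    if kind is ModelKind.LANGMUIR_1TO1:
        return simulate_langmuir(params, conc, sched)
    if kind is ModelKind.HETEROGENEOUS_LIGAND:
        return simulate_heterogeneous_ligand(params, conc, sched)
    if kind is ModelKind.BIVALENT_ANALYTE:
        return simulate_bivalent_analyte(params, conc, sched)
    return simulate_heterogeneous_analyte(params, conc, conc_b, sched)


def equilibrium_response(params: KineticParams, conc: float) -> float:
    """Steady-state response sum_i rmax_i * C / (C + kd_i/ka_i).

    Only defined for the closed-form kinds (1:1 and heterogeneous ligand).
    """
    if params.kind not in (ModelKind.LANGMUIR_1TO1, ModelKind.HETEROGENEOUS_LIGAND):
        raise UnsupportedModelError(
            f"equilibrium_response is undefined for {params.kind.value}"
        )
    if conc == math.inf:
        total = params.rmax1
        if params.kind is ModelKind.HETEROGENEOUS_LIGAND:
            total += params.rmax2
        return total
    _check_conc(conc)
    r = params.rmax1 * conc / (conc + params.kd1 / params.ka1)
    if params.kind is ModelKind.HETEROGENEOUS_LIGAND:
        r += params.rmax2 * conc / (conc + params.kd2 / params.ka2)
    return r


class Affinity(NamedTuple):
    """Equilibrium dissociation constant with optional propagated error."""

    value: float
    stderr: float | None


def kd_from_rates(ka: float, kd: float, se_ka: float | None = None,
                  se_kd: float | None = None) -> Affinity:
    """Equilibrium dissociation constant KD = kd/ka (M).

    When both standard errors are supplied the error is propagated to
    first order for a ratio of independent estimates:
    se_KD = KD * sqrt((se_ka/ka)^2 + (se_kd/kd)^2).
    """
    _require(ka > 0 and math.isfinite(ka), "ka must be > 0")
    _require(kd > 0 and math.isfinite(kd), "kd must be > 0")
    value = kd / ka
    stderr = None
    if se_ka is not None and se_kd is not None:
        _require(se_ka >= 0 and se_kd >= 0, "standard errors must be >= 0")
        stderr = value * math.sqrt((se_ka / ka) ** 2 + (se_kd / kd) ** 2)
    return Affinity(value, stderr)
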