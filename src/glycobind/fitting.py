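"""Global fitting of sensorgram series and kinetic model comparison.

All curves of a series share one immobilized surface, so the rate
constants and capacities are fitted *globally*: one parameter vector must
explain every concentration simultaneously, which is what makes ka and kd
separable from a single titration. The optimizer works on log10-scaled
rate constants (they span decades) with linear capacities, minimizing the
pooled sum of squared residuals with seeded multistart (Latin hypercube
plus a data-driven heuristic start). Candidate models are ranked by the
small-sample corrected Akaike information criterion (AICc) on the pooled
residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import ConvergenceError, ValidationError
from .models import (
    Affinity,
    KineticParams,
    ModelKind,
    SensorgramSeries,
    kd_from_rates,
    response_at,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "ModelSelectionReport",
    "global_fit",
    "compare_models",
    "fold_difference",
    "aicc",
]

#: JSON schema version of serialized fit reports.
REPORT_SCHEMA_VERSION = "1"


@dataclass
class FitOptions:
    """Tuning knobs of the global fit.

    ``n_starts`` Latin-hypercube starts are drawn over the bounds and run
    in addition to one heuristic start (dissociation-tail slope for kd, a
    coarse ka line search with the capacity solved linearly). Bounds cover
    the physically plausible biosensor range.
    """

    n_starts: int = 8
    seed: int = 0
    ka_bounds: tuple[float, float] = (1e2, 1e9)
    kd_bounds: tuple[float, float] = (1e-6, 1.0)
    ka2_bivalent_bounds: tuple[float, float] = (1e-8, 1e2)  # RU^-1 s^-1
    rmax_factor: float = 10.0  # rmax upper bound = factor * max |response|
    include_offsets: bool = False
    max_nfev: int | None = None


@dataclass
class FitResult:
    """Outcome of one global fit.

    ``kd_eq1`` (and ``kd_eq2`` for two-site kinds) hold KD = kd/ka of the
    point estimates with first-order propagated standard errors; they are
    recomputed from the estimates, never stored independently.
    """

    kind: ModelKind
    params: KineticParams
    stderr: dict[str, float]
    kd_eq1: Affinity
    kd_eq2: Affinity | None
    rss: float
    n_obs: int
    n_free: int
    aicc: float
    fitted: list[np.ndarray]
    offsets: list[float]
    success: bool
    message: str
    n_starts: int
    seed: int

    @property
    def dof(self) -> int:
        return self.n_obs - self.n_free

    def to_dict(self, include_curves: bool = False) -> dict:
        def _num(x):
            return None if x is None or (isinstance(x, float) and not math.isfinite(x)) else x

        p = self.params
        d = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "kind": self.kind.value,
            "estimates": {
                "ka1": p.ka1, "kd1": p.kd1, "rmax1": p.rmax1,
                "ka2": p.ka2, "kd2": p.kd2, "rmax2": p.rmax2,
            },
            "stderr": {k: _num(v) for k, v in self.stderr.items()},
            "KD1": self.kd_eq1.value,
            "KD1_stderr": _num(self.kd_eq1.stderr),
            "KD2": None if self.kd_eq2 is None else self.kd_eq2.value,
            "KD2_stderr": None if self.kd_eq2 is None else _num(self.kd_eq2.stderr),
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "aicc": self.aicc,
            "offsets": list(self.offsets),
            "success": self.success,
            "message": self.message,
            "n_starts": self.n_starts,
            "seed": self.seed,
        }
        if include_curves:
            d["fitted_curves"] = [f.tolist() for f in self.fitted]
        return d


@dataclass
class ModelSelectionReport:
    """Per-candidate fits, their AICc values, and the selected kind."""

    results: dict[ModelKind, FitResult]
    criterion: dict[ModelKind, float]
    selected: ModelKind
    rationale: str

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "candidates": {k.value: r.to_dict() for k, r in self.results.items()},
            "aicc": {k.value: v for k, v in self.criterion.items()},
            "selected": self.selected.value,
            "rationale": self.rationale,
        }


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for Gaussian least squares.

    ``k`` counts the mean-model parameters; the noise variance adds one.
    """
    k1 = k + 1
    if n - k1 - 1 <= 0:
        raise ValidationError("AICc undefined: too few observations")
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k1 + 2 * k1 * (k1 + 1) / (n - k1 - 1)


# ---------------------------------------------------------------------------
# parameter packing

_N_KINETIC = {
    ModelKind.LANGMUIR_1TO1: 3,
    ModelKind.HETEROGENEOUS_LIGAND: 6,
    ModelKind.BIVALENT_ANALYTE: 5,
    ModelKind.HETEROGENEOUS_ANALYTE: 5,
}


def _packed_bounds(kind: ModelKind, opts: FitOptions, rmax_upper: float,
                   n_curves: int, offset_limit: float):
    lka = tuple(math.log10(b) for b in opts.ka_bounds)
    lkd = tuple(math.log10(b) for b in opts.kd_bounds)
    lo = [lka[0], lkd[0], 0.0]
    hi = [lka[1], lkd[1], rmax_upper]
    if kind is ModelKind.HETEROGENEOUS_LIGAND:
        lo += [lka[0], lkd[0], 0.0]
        hi += [lka[1], lkd[1], rmax_upper]
    elif kind is ModelKind.BIVALENT_ANALYTE:
        lka2 = tuple(math.log10(b) for b in opts.ka2_bivalent_bounds)
        lo += [lka2[0], lkd[0]]
        hi += [lka2[1], lkd[1]]
    elif kind is ModelKind.HETEROGENEOUS_ANALYTE:
        lo += [lka[0], lkd[0]]
        hi += [lka[1], lkd[1]]
    if opts.include_offsets:
        lo += [-offset_limit] * n_curves
        hi += [offset_limit] * n_curves
    return np.array(lo), np.array(hi)


def _unpack(kind: ModelKind, x: np.ndarray) -> KineticParams:
    if kind is ModelKind.LANGMUIR_1TO1:
        return KineticParams(kind, 10 ** x[0], 10 ** x[1], x[2])
    if kind is ModelKind.HETEROGENEOUS_LIGAND:
        return KineticParams(kind, 10 ** x[0], 10 ** x[1], x[2],
                             10 ** x[3], 10 ** x[4], x[5])
    return KineticParams(kind, 10 ** x[0], 10 ** x[1], x[2],
                         10 ** x[3], 10 ** x[4])


def _pack(params: KineticParams) -> np.ndarray:
    x = [math.log10(params.ka1), math.log10(params.kd1), params.rmax1]
    if params.kind is ModelKind.HETEROGENEOUS_LIGAND:
        x += [math.log10(params.ka2), math.log10(params.kd2), params.rmax2]
    elif params.kind in (ModelKind.BIVALENT_ANALYTE, ModelKind.HETEROGENEOUS_ANALYTE):
        x += [math.log10(params.ka2), math.log10(params.kd2)]
    return np.array(x)


# ---------------------------------------------------------------------------
# heuristic start

def _heuristic_1to1(series: SensorgramSeries, t_assoc: float,
                    opts: FitOptions, rmax_upper: float):
    """Data-driven 1:1 start: kd from the dissociation tail of the
    highest-concentration curve, then a coarse log-spaced ka line search
    with the capacity solved by linear least squares (the 1:1 trace is
    linear in rmax for fixed rates)."""
    top = max(series.curves, key=lambda c: c.conc)
    mask = top.time > t_assoc
    kd0 = math.sqrt(opts.kd_bounds[0] * opts.kd_bounds[1])
    if mask.sum() >= 5:
        t_tail = top.time[mask]
        y_tail = top.response[mask]
        floor = max(1e-9, float(np.max(np.abs(y_tail))) * 1e-3)
        pos = y_tail > floor
        if pos.sum() >= 5:
            slope = np.polyfit(t_tail[pos], np.log(y_tail[pos]), 1)[0]
            if slope < 0:
                kd0 = float(np.clip(-slope, *opts.kd_bounds))
    best = None
    y_all = np.concatenate([c.response for c in series.curves])
    for ka in np.logspace(math.log10(opts.ka_bounds[0]) + 0.01,
                          math.log10(opts.ka_bounds[1]) - 0.01, 25):
        unit = KineticParams(ModelKind.LANGMUIR_1TO1, ka, kd0, 1.0)
        basis = np.concatenate(
            [response_at(unit, c.conc, c.time, t_assoc) for c in series.curves]
        )
        denom = float(basis @ basis)
        if denom <= 0:
            continue
        rmax = float(np.clip((basis @ y_all) / denom, 1e-6, rmax_upper))
        rss = float(np.sum((y_all - rmax * basis) ** 2))
        if best is None or rss < best[0]:
            best = (rss, ka, rmax)
    _, ka0, rmax0 = best
    return ka0, kd0, rmax0


def _heuristic_start(kind: ModelKind, series: SensorgramSeries, t_assoc: float,
                     opts: FitOptions, rmax_upper: float) -> np.ndarray:
    ka0, kd0, rmax0 = _heuristic_1to1(series, t_assoc, opts, rmax_upper)

    def clip_ka(v):
        return float(np.clip(v, *opts.ka_bounds))

    def clip_kd(v):
        return float(np.clip(v, *opts.kd_bounds))

    if kind is ModelKind.LANGMUIR_1TO1:
        x = [math.log10(ka0), math.log10(kd0), rmax0]
    elif kind is ModelKind.HETEROGENEOUS_LIGAND:
        x = [math.log10(ka0), math.log10(kd0), 0.6 * rmax0,
             math.log10(clip_ka(ka0 / 5)), math.log10(clip_kd(kd0 * 5)), 0.4 * rmax0]
    elif kind is ModelKind.BIVALENT_ANALYTE:
        ka2 = float(np.clip(1e-4, *opts.ka2_bivalent_bounds))
        x = [math.log10(clip_ka(ka0 / 2)), math.log10(kd0), rmax0,
             math.log10(ka2), math.log10(kd0)]
    else:  # heterogeneous analyte
        x = [math.log10(ka0), math.log10(kd0), rmax0,
             math.log10(clip_ka(ka0 / 3)), math.log10(clip_kd(kd0 * 3))]
    return np.array(x)


# ---------------------------------------------------------------------------
# the global fit

def global_fit(series: SensorgramSeries, kind: ModelKind | str,
               options: FitOptions | None = None,
               extra_starts: Sequence[np.ndarray] = ()) -> FitResult:
    """Fit one kinetic model to every curve of a series jointly.

    Rate constants and capacities are shared across curves; the summed
    squared residual over all samples of all curves is minimized with
    multistart trust-region least squares. Standard errors come from the
    Jacobian-based covariance at the optimum with the noise variance
    estimated as RSS/dof; a singular covariance yields NaN errors but the
    fit is still returned. Deterministic for a fixed ``options.seed``.
    """
    kind = ModelKind(kind)
    opts = options or FitOptions()
    if len({c.conc for c in series.curves}) < 2:
        raise ValidationError("global fit needs >= 2 distinct concentrations")
    sched = series.schedule
    if sched is None:
        raise ValidationError("series curves carry no phase schedule")
    t_assoc = sched.t_assoc
    n_assoc = int((series.time <= t_assoc).sum())
    if min(n_assoc, series.time.size - n_assoc) < 10:
        raise ValidationError("global fit needs >= 10 samples per phase")

    y_all = np.concatenate([c.response for c in series.curves])
    max_abs = float(np.max(np.abs(y_all))) or 1.0
    rmax_upper = opts.rmax_factor * max_abs
    n_curves = len(series.curves)
    lo, hi = _packed_bounds(kind, opts, rmax_upper, n_curves, max_abs)
    nk = _N_KINETIC[kind]

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _unpack(kind, x[:nk])
        parts = []
        for i, c in enumerate(series.curves):
            model = response_at(p, c.conc, c.time, t_assoc, conc_b=c.conc_b)
            if opts.include_offsets:
                model = model + x[nk + i]
            parts.append(model - c.response)
        return np.concatenate(parts)

    starts = [np.clip(_heuristic_start(kind, series, t_assoc, opts, rmax_upper),
                      lo[:nk], hi[:nk])]
    if opts.n_starts > 0:
        sampler = qmc.LatinHypercube(d=nk, seed=opts.seed)
        unit = sampler.random(opts.n_starts)
        starts += list(lo[:nk] + unit * (hi[:nk] - lo[:nk]))
    for xs in extra_starts:
        starts.append(np.clip(np.asarray(xs, dtype=float), lo[:nk], hi[:nk]))
    if opts.include_offsets:
        starts = [np.concatenate([s, np.zeros(n_curves)]) for s in starts]

    eps = 1e-12
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + eps * np.abs(lo), hi - eps * np.maximum(np.abs(hi), 1.0))
        res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                            x_scale="jac", max_nfev=opts.max_nfev)
        if best is None or res.cost < best.cost:
            best = res

    params = _unpack(kind, best.x[:nk])
    fitted = []
    for i, c in enumerate(series.curves):
        m = response_at(params, c.conc, c.time, t_assoc, conc_b=c.conc_b)
        if opts.include_offsets:
            m = m + best.x[nk + i]
        fitted.append(m)
    rss = float(2.0 * best.cost)
    n_obs = y_all.size
    n_free = best.x.size
    dof = n_obs - n_free

    # covariance in packed (log10 rates, linear capacities/offsets) space
    names = ["ka1", "kd1", "rmax1"]
    log_scaled = [True, True, False]
    if kind is ModelKind.HETEROGENEOUS_LIGAND:
        names += ["ka2", "kd2", "rmax2"]
        log_scaled += [True, True, False]
    elif kind in (ModelKind.BIVALENT_ANALYTE, ModelKind.HETEROGENEOUS_ANALYTE):
        names += ["ka2", "kd2"]
        log_scaled += [True, True]
    stderr: dict[str, float] = {}
    se_packed = np.full(n_free, np.nan)
    if dof > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.pinv(jtj) * (rss / dof)
            diag = np.diag(cov)
            if np.all(np.isfinite(diag)) and np.all(diag >= 0):
                se_packed = np.sqrt(diag)
        except np.linalg.LinAlgError:
            pass
    values = {"ka1": params.ka1, "kd1": params.kd1, "rmax1": params.rmax1,
              "ka2": params.ka2, "kd2": params.kd2, "rmax2": params.rmax2}
    for i, (name, is_log) in enumerate(zip(names, log_scaled)):
        se = se_packed[i]
        stderr[name] = float(math.log(10.0) * values[name] * se) if is_log else float(se)

    kd_eq1 = kd_from_rates(params.ka1, params.kd1,
                           se_ka=_finite_or_none(stderr.get("ka1")),
                           se_kd=_finite_or_none(stderr.get("kd1")))
    kd_eq2 = None
    if params.ka2 is not None and params.kd2 is not None and params.ka2 > 0:
        kd_eq2 = kd_from_rates(params.ka2, params.kd2,
                               se_ka=_finite_or_none(stderr.get("ka2")),
                               se_kd=_finite_or_none(stderr.get("kd2")))

    offsets = list(best.x[nk:]) if opts.include_offsets else []
    success = best.status > 0
    result = FitResult(
        kind=kind, params=params, stderr=stderr, kd_eq1=kd_eq1, kd_eq2=kd_eq2,
        rss=rss, n_obs=n_obs, n_free=n_free,
        aicc=aicc(rss, n_obs, n_free),
        fitted=fitted, offsets=offsets, success=success,
        message=str(best.message), n_starts=len(starts), seed=opts.seed,
    )
    if not success:
        raise ConvergenceError(
            f"global fit did not converge from any of {len(starts)} starts",
            best_result=result,
        )
    return result


def _finite_or_none(v):
    return v if v is not None and math.isfinite(v) and v >= 0 else None


def _nested_start_for(kind: ModelKind, base: FitResult,
                      opts: FitOptions) -> np.ndarray | None:
    """Start vector for a two-site kind seeded from a fitted 1:1 optimum
    (second site switched off), so the richer model can never end worse."""
    if kind is not ModelKind.HETEROGENEOUS_LIGAND:
        return None
    if base.kind is not ModelKind.LANGMUIR_1TO1:
        return None
    p = base.params
    mid_ka = math.sqrt(opts.ka_bounds[0] * opts.ka_bounds[1])
    mid_kd = math.sqrt(opts.kd_bounds[0] * opts.kd_bounds[1])
    return np.array([
        math.log10(p.ka1), math.log10(p.kd1), p.rmax1,
        math.log10(mid_ka), math.log10(mid_kd), 0.0,
    ])


def compare_models(series: SensorgramSeries,
                   kinds: Sequence[ModelKind | str],
                   options: FitOptions | None = None) -> ModelSelectionReport:
    """Fit every candidate kind and select the one minimizing AICc.

    Candidates are fitted in order of increasing parameter count, and each
    two-site candidate receives an extra start at the nested simpler
    optimum. Ties (AICc within 2 of the minimum) resolve to the candidate
    with the fewest parameters.
    """
    kinds = [ModelKind(k) for k in kinds]
    if len(kinds) < 1:
        raise ValidationError("compare_models needs >= 1 candidate kind")
    opts = options or FitOptions()
    order = sorted(kinds, key=lambda k: _N_KINETIC[k])
    results: dict[ModelKind, FitResult] = {}
    errors: list[str] = []
    for kind in order:
        extra = []
        for prev in results.values():
            xs = _nested_start_for(kind, prev, opts)
            if xs is not None:
                extra.append(xs)
        try:
            results[kind] = global_fit(series, kind, opts, extra_starts=extra)
        except ConvergenceError as exc:
            if exc.best_result is not None:
                results[kind] = exc.best_result
            else:
                errors.append(f"{kind.value}: {exc}")
        except Exception as exc:  # integrator failures etc.
            errors.append(f"{kind.value}: {exc}")
    if not results:
        raise ConvergenceError(
            "every candidate model failed: " + "; ".join(errors)
        )
    crit = {k: r.aicc for k, r in results.items()}
    best_val = min(crit.values())
    tied = [k for k, v in crit.items() if v - best_val < 2.0]
    selected = min(tied, key=lambda k: (results[k].n_free, crit[k]))
    if len(tied) > 1:
        rationale = (
            f"{selected.value} selected: within 2 AICc of the minimum "
            f"({best_val:.2f}) with the fewest parameters"
        )
    else:
        others = sorted(v for k, v in crit.items() if k is not selected)
        gap = f"; next candidate is {others[0] - best_val:.2f} AICc higher" if others else ""
        rationale = f"{selected.value} selected: minimal AICc ({best_val:.2f}){gap}"
    return ModelSelectionReport(results=results, criterion=crit,
                                selected=selected, rationale=rationale)


def fold_difference(kd_a: float, kd_b: float) -> float:
    """Affinity (or rate) fold difference kd_a / kd_b."""
    if not (kd_a > 0 and kd_b > 0):
        raise ValidationError("fold_difference needs positive inputs")
    return kd_a / kd_b
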