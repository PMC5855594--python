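"""Linear Interaction Energy (LIE) binding free-energy estimation.

LIE is an end-point method: the binding free energy is estimated from
mean ligand-environment interaction energies sampled in two simulations,
one with the ligand bound to the receptor and one with the ligand free in
solvent,

    dG_bind = alpha * (<V_LJ>_bound - <V_LJ>_free)
            + beta  * (<V_el>_bound - <V_el>_free)

with empirical scaling factors alpha (Lennard-Jones) and beta
(electrostatic). This module implements only the LIE arithmetic on
supplied energy averages or energy time series; running or parsing the
underlying molecular-dynamics simulations is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_BETA",
    "DEFAULT_TAIL_WINDOW_PS",
    "LieInput",
    "lie_free_energy",
    "tail_mean",
]

#: Default Lennard-Jones and electrostatic scaling factors.
DEFAULT_ALPHA = 0.181
DEFAULT_BETA = 0.3

#: Default averaging window (ps): the final 10 ns of a trajectory, where
#: the complex is assumed equilibrated.
DEFAULT_TAIL_WINDOW_PS = 10_000.0


@dataclass(frozen=True)
class LieInput:
    """Mean interaction energies (kJ/mol) and scaling factors."""

    vdw_bound: float
    vdw_free: float
    elec_bound: float
    elec_free: float
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        for name in ("vdw_bound", "vdw_free", "elec_bound", "elec_free"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("alpha and beta must be >= 0")


def lie_free_energy(inp: LieInput) -> float:
    """Binding free energy (kJ/mol) from mean interaction energies."""
    return (inp.alpha * (inp.vdw_bound - inp.vdw_free)
            + inp.beta * (inp.elec_bound - inp.elec_free))


def tail_mean(time_ps: np.ndarray, energy_kj_mol: np.ndarray,
              window_ps: float = DEFAULT_TAIL_WINDOW_PS) -> float:
    """Mean energy over the final ``window_ps`` of a trajectory.

    Samples with time > t_end - window_ps enter the average; the window
    must contain at least one sample.
    """
    t = np.asarray(time_ps, dtype=float)
    e = np.asarray(energy_kj_mol, dtype=float)
    if t.ndim != 1 or t.shape != e.shape or t.size == 0:
        raise ValidationError("time and energy must be 1-d arrays of equal length")
    if window_ps <= 0:
        raise ValidationError("window_ps must be > 0")
    mask = t > t[-1] - window_ps
    if not mask.any():
        raise ValidationError("averaging window contains no samples")
    return float(e[mask].mean())
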