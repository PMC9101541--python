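"""Free-energy bookkeeping for alchemical double-annihilation FEP.

In double annihilation the ligand is decoupled once in solvent (unbound)
and once in the binding site (bound); the binding free energy is

    ΔΔG = ΔG_unbound − ΔG_bound,      ΔG_binding = −ΔΔG.

Per-λ-window free energies are estimated from forward and backward
energy-difference samples with the simple-overlap-sampling (SOS)
estimator,

    ΔA_w = −kT · ln( ⟨exp(−ΔU_f / 2kT)⟩_fwd / ⟨exp(−ΔU_b / 2kT)⟩_bwd ),

summed over windows (log-sum-exp is used for numerical safety).  The
forward/backward discrepancy |ΔA_f + ΔA_b| (the backward run measures the
negative transformation) serves as a convergence diagnostic (hysteresis).
A binding ΔG converts to a dissociation constant through ΔG = RT ln Kd,
so a negative binding free energy yields Kd < 1 M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "PhysicalConstants",
    "FEPSeries",
    "fep_combine",
    "sos_estimate",
    "hysteresis",
    "delta_g_to_kd",
    "kd_band",
    "KCAL_TO_J",
]

#: Thermochemical calorie convention, pinned for exact tests.
KCAL_TO_J = 4184.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant and temperature for the ΔG ↔ K conversion."""

    R: float = 8.314  # J mol^-1 K^-1
    T: float = 298.0  # K

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kT_kcal(self) -> float:
        """RT in kcal/mol."""
        return self.R * self.T / KCAL_TO_J


@dataclass
class FEPSeries:
    """Per-window energy-difference samples along a λ schedule.

    ``samples[w]`` holds the ΔU draws (kcal/mol) of window w; ``direction``
    says whether the series runs the forward (λ 0→1) or backward (1→0)
    transformation; ``state`` marks the bound or unbound leg.
    """

    lambdas: np.ndarray  # sorted grid in [0, 1], default step 0.02
    samples: list[np.ndarray]  # one array of ΔU (kcal/mol) per window
    direction: str = "forward"  # forward | backward
    state: str = "bound"  # bound | unbound

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(self.lambdas < 0) or np.any(self.lambdas > 1):
            raise ValueError("lambda grid must lie within [0, 1]")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("lambda grid must be strictly increasing")
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        self.samples = [np.asarray(s, dtype=float) for s in self.samples]
        if any(s.size == 0 for s in self.samples):
            raise ValueError("every window must have at least one sample")

    @property
    def n_windows(self) -> int:
        return len(self.samples)


def fep_combine(dg_unbound: float, dg_bound: float) -> tuple[float, float]:
    """Double-annihilation combination: (ΔΔG, binding ΔG).

    ΔΔG = ΔG_unbound − ΔG_bound; the binding free energy is its negative.
    """
    if not (math.isfinite(dg_unbound) and math.isfinite(dg_bound)):
        raise ValueError("both free energies must be finite")
    ddg = dg_unbound - dg_bound
    return ddg, -ddg


def _half_exponential_log_mean(du: np.ndarray, kT: float) -> float:
    """log⟨exp(−ΔU / 2kT)⟩ via log-sum-exp."""
    return float(logsumexp(-du / (2.0 * kT)) - math.log(du.size))


def sos_estimate(
    fwd: FEPSeries,
    bwd: FEPSeries,
    constants: PhysicalConstants | None = None,
) -> tuple[np.ndarray, float]:
    """Simple-overlap-sampling free energy: per-window ΔA and the total.

    Requires matching λ grids and opposite directions.  Units: kcal/mol.
    """
    c = constants or PhysicalConstants()
    if fwd.n_windows != bwd.n_windows or not np.allclose(fwd.lambdas, bwd.lambdas):
        raise ValueError("forward and backward series must share the same λ grid")
    if fwd.direction == bwd.direction:
        raise ValueError("series must have opposite directions")
    kT = c.kT_kcal
    per_window = np.array(
        [
            -kT
            * (
                _half_exponential_log_mean(f, kT)
                - _half_exponential_log_mean(b, kT)
            )
            for f, b in zip(fwd.samples, bwd.samples)
        ]
    )
    return per_window, float(per_window.sum())


def hysteresis(dA_fwd: float, dA_bwd: float) -> float:
    """|ΔA_forward + ΔA_backward| — the forward/backward closure error."""
    if not (math.isfinite(dA_fwd) and math.isfinite(dA_bwd)):
        raise ValueError("both free energies must be finite")
    return abs(dA_fwd + dA_bwd)


#: Qualitative affinity bands by Kd decade.
_BANDS = [
    (1e-9, "sub-nM"),
    (1e-6, "nM"),
    (1e-3, "µM"),
    (1.0, "mM"),
]


def kd_band(kd: float) -> str:
    """Qualitative band (sub-nM / nM / µM / mM / weak) for a Kd in mol/L."""
    for upper, label in _BANDS:
        if kd < upper:
            return label
    return "weak"


def delta_g_to_kd(
    binding_dg: float, constants: PhysicalConstants | None = None
) -> tuple[float, str]:
    """Dissociation constant (mol/L) from a binding ΔG in kcal/mol.

    Kd = exp(ΔG·4184 / RT); a negative binding free energy gives Kd < 1 M.
    Returns the constant and its qualitative affinity band.
    """
    c = constants or PhysicalConstants()
    if not math.isfinite(binding_dg):
        raise ValueError("binding free energy must be finite")
    kd = math.exp(binding_dg * KCAL_TO_J / (c.R * c.T))
    return kd, kd_band(kd)
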