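"""Biexponential organ pharmacokinetics for radiopharmaceutical therapy.

The activity of a radiopharmaceutical in an organ after injection is modeled
as the difference of two exponentials — a slow washout term and a fast uptake
term — each additionally decaying with the physical decay constant of the
radionuclide:

    A(t) = A1 * exp(-(lambda1 + lambda_phys) * t)
         - A2 * exp(-(lambda2 + lambda_phys) * t)

with all rates in 1/h and activities in MBq.  The effective half-life of the
organ is governed by the washout term, T_eff = ln2 / (lambda1 + lambda_phys),
and the time-integrated activity (TIA) is the integral of A(t) over [0, inf),
which has the closed form

    TIA = A1 * T_eff / ln2  -  A2 / (lambda2 + lambda_phys).

All times are hours; the Lu-177 physical half-life of 6.65 d is converted to
159.6 h once and stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate

LN2 = math.log(2.0)

HOURS_PER_DAY = 24.0
#: Physical half-life of Lu-177 in days.
LU177_HALF_LIFE_DAYS = 6.65
#: Physical half-life of Lu-177 in hours (6.65 d * 24 h/d).
LU177_HALF_LIFE_HOURS = LU177_HALF_LIFE_DAYS * HOURS_PER_DAY  # 159.6 h

#: Organs with post-therapy dosimetry.
ORGANS = ("left_kidney", "right_kidney", "liver", "spleen")

#: Organs segmented on pretherapy PET (adds the urinary bladder).
PET_ORGANS = ORGANS + ("urinary_bladder",)


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


class DivergentIntegralError(DomainError):
    """The TIA integral does not converge for the given rates."""


@dataclass(frozen=True)
class PhysicalDecay:
    """Physical decay of the radionuclide.

    Parameters
    ----------
    half_life_hours : float
        Physical half-life in hours; must be positive.
    """

    half_life_hours: float = LU177_HALF_LIFE_HOURS

    def __post_init__(self) -> None:
        if not self.half_life_hours > 0:
            raise DomainError(
                f"half_life_hours must be positive, got {self.half_life_hours}"
            )

    @property
    def lambda_phys(self) -> float:
        """Physical decay constant in 1/h (= ln2 / half-life)."""
        return LN2 / self.half_life_hours

    @classmethod
    def lu177(cls) -> "PhysicalDecay":
        """The Lu-177 default (6.65 d = 159.6 h)."""
        return cls(LU177_HALF_LIFE_HOURS)


@dataclass(frozen=True)
class BiexponentialParams:
    """Parameters of the biexponential time-activity model.

    ``A1_MBq`` and ``lambda1_bio`` describe the washout term whose effective
    rate sets the organ effective half-life; ``A2_MBq`` and ``lambda2_bio``
    describe the uptake term, conventionally fixed to population values
    during fitting.
    """

    A1_MBq: float
    lambda1_bio: float
    A2_MBq: float = 0.0
    lambda2_bio: float = 0.0

    def __post_init__(self) -> None:
        if not self.A1_MBq > 0:
            raise DomainError(f"A1_MBq must be > 0, got {self.A1_MBq}")
        if self.A2_MBq < 0:
            raise DomainError(f"A2_MBq must be >= 0, got {self.A2_MBq}")
        if self.lambda1_bio < 0:
            raise DomainError(f"lambda1_bio must be >= 0, got {self.lambda1_bio}")
        if self.lambda2_bio < 0:
            raise DomainError(f"lambda2_bio must be >= 0, got {self.lambda2_bio}")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled organ activity for one patient cycle.

    ``times_hours`` must be strictly increasing and non-negative;
    ``activities_MBq`` non-negative.  A curve may carry a single sample (a
    single-time-point measurement); multi-time-point fitting separately
    requires at least 3.
    """

    patient_id: str
    cycle: int
    organ: str
    times_hours: tuple[float, ...]
    activities_MBq: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_hours, dtype=float)
        a = np.asarray(self.activities_MBq, dtype=float)
        if t.size == 0:
            raise DomainError("curve needs at least one sample")
        if t.size != a.size:
            raise DomainError("times and activities must have equal length")
        if np.any(t < 0):
            raise DomainError("sample times must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise DomainError("sample times must be strictly increasing")
        if np.any(a < 0):
            raise DomainError("activities must be >= 0")
        if self.cycle < 1:
            raise DomainError(f"cycle must be a positive integer, got {self.cycle}")
        if self.organ not in ORGANS:
            raise DomainError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
        # normalise to tuples so the dataclass stays hashable/frozen
        object.__setattr__(self, "times_hours", tuple(float(x) for x in t))
        object.__setattr__(self, "activities_MBq", tuple(float(x) for x in a))

    @property
    def n_samples(self) -> int:
        return len(self.times_hours)


@dataclass
class KineticsEstimate:
    """Fitted kinetics with derived effective half-life and TIA."""

    params: BiexponentialParams
    teff_hours: float
    tia_MBq_h: float
    residuals_MBq: tuple[float, ...] = field(default_factory=tuple)
    converged: bool = True
    sse: float = float("nan")
    n_points: int = 0


def evaluate_biexponential(
    params: BiexponentialParams,
    decay: PhysicalDecay,
    t: float | Sequence[float] | np.ndarray,
) -> float | np.ndarray:
    """Evaluate the signed biexponential model at time(s) ``t`` (hours).

    The returned value may be negative for small ``t`` when the uptake
    amplitude exceeds the washout amplitude; clamping to physical
    non-negativity is the caller's decision (the synthetic generator clamps,
    the fitting objective does not).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("time must be >= 0")
    lp = decay.lambda_phys
    out = params.A1_MBq * np.exp(-(params.lambda1_bio + lp) * t_arr) - (
        params.A2_MBq * np.exp(-(params.lambda2_bio + lp) * t_arr)
    )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def teff_from_rates(lambda1_bio: float, decay: PhysicalDecay) -> float:
    """Effective half-life ln2 / (lambda1_bio + lambda_phys), in hours."""
    rate = lambda1_bio + decay.lambda_phys
    if not rate > 0:
        raise DomainError(f"effective rate must be positive, got {rate}")
    return LN2 / rate


def closed_form_tia(params: BiexponentialParams, decay: PhysicalDecay) -> float:
    """Analytic time-integrated activity over [0, inf), in MBq*h.

    TIA = A1 * T_eff / ln2 - A2 / (lambda2 + lambda_phys).  Both effective
    rates must be positive for the integral to converge.
    """
    lp = decay.lambda_phys
    rate1 = params.lambda1_bio + lp
    rate2 = params.lambda2_bio + lp
    if rate1 <= 0 or rate2 <= 0:
        raise DivergentIntegralError(
            f"effective rates must be positive for a convergent TIA "
            f"(got {rate1}, {rate2})"
        )
    teff = LN2 / rate1
    return params.A1_MBq * teff / LN2 - params.A2_MBq / rate2


def numeric_tia(
    params: BiexponentialParams,
    decay: PhysicalDecay,
    rel_tol: float = 1e-9,
) -> float:
    """TIA by adaptive quadrature of the model on [0, inf).

    Independent numerical check of :func:`closed_form_tia`; uses
    ``scipy.integrate.quad`` with its semi-infinite transform.  Raises if the
    quadrature's own error estimate exceeds ``rel_tol`` relative to the
    result.
    """
    lp = decay.lambda_phys
    if params.lambda1_bio + lp <= 0 or params.lambda2_bio + lp <= 0:
        raise DivergentIntegralError("effective rates must be positive")

    def integrand(t: float) -> float:
        return params.A1_MBq * math.exp(-(params.lambda1_bio + lp) * t) - (
            params.A2_MBq * math.exp(-(params.lambda2_bio + lp) * t)
        )

    value, abserr = integrate.quad(
        integrand, 0.0, np.inf, epsabs=0.0, epsrel=min(rel_tol, 1e-8), limit=200
    )
    if value != 0.0 and abs(abserr / value) > max(rel_tol, 1e-12):
        raise ArithmeticError(
            f"quadrature did not reach rel_tol={rel_tol}: "
            f"value={value}, abserr={abserr}"
        )
    return value
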