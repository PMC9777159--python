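"""One-compartment IV-infusion pharmacokinetics with developmental covariates.

The structural model is the standard one-compartment model with zero-order
(infusion) input and first-order elimination, parameterized by clearance CL
and volume of distribution V.  Typical values are scaled allometrically by
current weight (exponent 1 on V, 0.75 on CL) and, for CL, by a maturation
function of postnatal and gestational age:

    V_i  = theta1 * (CW/2680)        * exp(eta_V)
    CL_i = theta2 * (CW/2680)^0.75
                  * (PNA/12)^theta3 * (GA/36.5)^theta4 * exp(eta_CL)

with CW in grams, PNA in days, GA in weeks; 2680 g, 12 d and 36.5 wk are the
population median covariates.  Between-subject variability is log-normal
(exponential eta model) and residual error is proportional.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import CovariateRecord

#: Reference (median) covariates of the model.
REF_CW_G = 2680.0
REF_PNA_DAYS = 12.0
REF_GA_WEEKS = 36.5


@dataclass(frozen=True)
class DoseEvent:
    """A single intravenous infusion.

    Parameters
    ----------
    amount_mg : float
        Dose amount in mg. Must be positive.
    start_h : float
        Infusion start, hours since the subject's first dose.
    duration_h : float
        Infusion duration in hours; all administrations are infusions, so
        this must be strictly positive (bolus is not modelled).
    """

    amount_mg: float
    start_h: float
    duration_h: float

    def __post_init__(self) -> None:
        if not self.amount_mg > 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount_mg}")
        if not self.duration_h > 0:
            raise ValueError(f"infusion duration must be > 0, got {self.duration_h}")
        if self.start_h < 0:
            raise ValueError(f"dose start must be >= 0, got {self.start_h}")

    @property
    def rate_mg_h(self) -> float:
        return self.amount_mg / self.duration_h


@dataclass(frozen=True)
class IndividualParams:
    """Subject-specific clearance (L/h) and volume (L)."""

    cl_L_h: float
    v_L: float

    def __post_init__(self) -> None:
        if not (self.cl_L_h > 0 and np.isfinite(self.cl_L_h)):
            raise ValueError(f"CL must be finite and > 0, got {self.cl_L_h}")
        if not (self.v_L > 0 and np.isfinite(self.v_L)):
            raise ValueError(f"V must be finite and > 0, got {self.v_L}")

    @property
    def ke_per_h(self) -> float:
        """First-order elimination rate constant CL/V (1/h)."""
        return self.cl_L_h / self.v_L


@dataclass(frozen=True)
class PopModel:
    """Population model: fixed effects, IIV covariance, residual error.

    ``theta1`` is the typical V (L) at the reference weight; ``theta2`` the
    typical CL (L/h) at the reference covariates; ``theta3``/``theta4`` the
    PNA/GA maturation exponents.  ``omega`` is the 2x2 covariance matrix of
    (eta_CL, eta_V); ``sigma_prop`` the proportional residual SD.
    """

    theta1: float
    theta2: float
    theta3: float
    theta4: float
    omega: np.ndarray
    sigma_prop: float
    ref_cw_g: float = REF_CW_G
    ref_pna_days: float = REF_PNA_DAYS
    ref_ga_weeks: float = REF_GA_WEEKS

    def __post_init__(self) -> None:
        if not (self.theta1 > 0 and self.theta2 > 0):
            raise ValueError("theta1 and theta2 must be positive")
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (2, 2):
            raise ValueError(f"omega must be 2x2, got shape {om.shape}")
        if not np.allclose(om, om.T):
            raise ValueError("omega must be symmetric")
        if np.linalg.eigvalsh(om).min() < -1e-12:
            raise ValueError("omega must be positive semidefinite")
        if self.sigma_prop < 0:
            raise ValueError("sigma_prop must be >= 0")
        object.__setattr__(self, "omega", om)

    @property
    def omega_cl_sd(self) -> float:
        return float(np.sqrt(self.omega[0, 0]))

    @property
    def omega_v_sd(self) -> float:
        return float(np.sqrt(self.omega[1, 1]))


def final_model() -> PopModel:
    """The published final population model for meropenem in neonates.

    Between-subject %CV values (CL 50.8%, V 17.5%) are interpreted as
    100*sqrt(omega^2), the usual reporting convention for exponential
    eta models; residual proportional SD is 28.8%.
    """
    return PopModel(
        theta1=1.63,
        theta2=0.503,
        theta3=0.209,
        theta4=2.14,
        omega=np.diag([0.508**2, 0.175**2]),
        sigma_prop=0.288,
    )


def individual_params(
    model: PopModel,
    cov: "CovariateRecord",
    eta: Sequence[float] = (0.0, 0.0),
) -> IndividualParams:
    """Individual CL and V from covariates and random effects (eta_CL, eta_V)."""
    cw, pna, ga = cov.cw_g, cov.pna_days, cov.ga_weeks
    if not (cw > 0 and pna > 0 and ga > 0):
        raise ValueError("covariates must be strictly positive")
    eta_cl, eta_v = float(eta[0]), float(eta[1])
    v = model.theta1 * (cw / model.ref_cw_g) * np.exp(eta_v)
    cl = (
        model.theta2
        * (cw / model.ref_cw_g) ** 0.75
        * (pna / model.ref_pna_days) ** model.theta3
        * (ga / model.ref_ga_weeks) ** model.theta4
        * np.exp(eta_cl)
    )
    return IndividualParams(cl_L_h=float(cl), v_L=float(v))


def typical_params(model: PopModel, cov: "CovariateRecord") -> IndividualParams:
    """Population-typical CL and V (zero random effects)."""
    return individual_params(model, cov, (0.0, 0.0))


def concentration(
    t_h: float | np.ndarray,
    doses: Sequence[DoseEvent],
    p: IndividualParams,
) -> float | np.ndarray:
    """Plasma concentration (mg/L) at time(s) ``t_h`` by superposition.

    Each infusion contributes (R0/CL)(1 - e^{-ke s}) while running and
    decays mono-exponentially afterwards; contributions are additive
    (linear kinetics). Times before the first dose return 0.
    """
    t = np.asarray(t_h, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    cl, ke = p.cl_L_h, p.ke_per_h
    out = np.zeros_like(t)
    for d in doses:
        s = t - d.start_h
        r0 = d.rate_mg_h
        during = (s > 0) & (s <= d.duration_h)
        after = s > d.duration_h
        out[during] += (r0 / cl) * (1.0 - np.exp(-ke * s[during]))
        out[after] += (
            (r0 / cl)
            * (1.0 - np.exp(-ke * d.duration_h))
            * np.exp(-ke * (s[after] - d.duration_h))
        )
    return float(out[0]) if scalar else out


def steady_state_profile(
    dose_mg: float,
    interval_h: float,
    infusion_h: float,
    p: IndividualParams,
) -> Callable[[float | np.ndarray], float | np.ndarray]:
    """Steady-state concentration over one dosing interval.

    Returns a vectorized function of time since the start of a
    steady-state infusion (wrapped modulo the interval).  Uses the
    geometric accumulation factor 1/(1 - e^{-ke tau}) applied to the
    single-interval closed form; equivalent to infinite superposition.
    """
    if infusion_h >= interval_h:
        raise ValueError(
            f"infusion duration ({infusion_h} h) must be shorter than "
            f"the dosing interval ({interval_h} h)"
        )
    cl, ke = p.cl_L_h, p.ke_per_h
    r0 = dose_mg / infusion_h
    T, tau = infusion_h, interval_h
    acc = 1.0 / (1.0 - np.exp(-ke * tau))
    e_T = 1.0 - np.exp(-ke * T)

    def css(t_h: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t_h, dtype=float)
        scalar = t.ndim == 0
        t = np.mod(np.atleast_1d(t), tau)
        during = t <= T
        out = np.empty_like(t)
        # running infusion + decayed residue of all previous intervals
        out[during] = (r0 / cl) * (
            (1.0 - np.exp(-ke * t[during]))
            + e_T * np.exp(-ke * (tau - T + t[during])) * acc
        )
        out[~during] = (r0 / cl) * e_T * np.exp(-ke * (t[~during] - T)) * acc
        return float(out[0]) if scalar else out

    return css


def residual_observe(
    conc_true: float | np.ndarray,
    sigma_prop: float,
    eps: float | np.ndarray,
) -> float | np.ndarray:
    """Apply proportional residual error: observed = true * (1 + sigma*eps)."""
    return np.asarray(conc_true) * (1.0 + sigma_prop * np.asarray(eps))
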