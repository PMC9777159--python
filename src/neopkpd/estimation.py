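"""FOCE-I estimation of the population model and stepwise covariate selection.

The marginal -2 log-likelihood is approximated per subject by first-order
conditional estimation with interaction: the conditional mode eta_hat of the
penalized individual objective is found (damped Gauss-Newton, vectorized
across subjects), the model is linearized about eta_hat, and the subject
contribution is

    n_i ln(2 pi) + ln det V_i + r_i' V_i^{-1} r_i,
    V_i = G_i Omega G_i' + diag(sigma^2 f_i(eta_hat)^2),
    r_i = y_i - f_i(eta_hat) + G_i eta_hat,

with G_i = df/d(eta) at eta_hat and residual variance evaluated at the
individual predictions (the "interaction" term).  The outer problem
minimizes the summed objective over log-transformed (theta, omega, sigma)
plus the free covariate exponents with Nelder-Mead.

Covariate selection follows the classical forward (dOFV > 3.84) /
backward (dOFV > 6.635) likelihood-ratio procedure over power models on
median-normalized covariates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .cohort import CovariateRecord
from .dataset import StudyDataset
from .pkmodel import IndividualParams, PopModel, REF_CW_G, REF_GA_WEEKS, REF_PNA_DAYS

logger = logging.getLogger(__name__)

_INNER_GRAD_TOL = 1e-8
_INNER_MAX_ITER = 80
_F_FLOOR = 1e-12
_OFV_SENTINEL = 1e10


# ---------------------------------------------------------------------------
# structural model specification


@dataclass(frozen=True)
class CovariateEffect:
    """A power-model covariate effect (cov/reference)^exponent on CL or V.

    ``exponent=None`` marks the exponent as estimated.
    """

    covariate: str
    parameter: str  # 'cl' | 'v'
    reference: float
    exponent: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in ("cl", "v"):
            raise ValueError("parameter must be 'cl' or 'v'")
        if not self.reference > 0:
            raise ValueError("reference must be positive")

    @property
    def name(self) -> str:
        stem = self.covariate.split("_")[0]
        return f"beta_{stem}_{self.parameter}"


@dataclass(frozen=True)
class StructuralSpec:
    """Which covariate effects enter CL and V, and which exponents are free."""

    cl_effects: tuple[CovariateEffect, ...] = ()
    v_effects: tuple[CovariateEffect, ...] = ()

    @classmethod
    def base(cls) -> "StructuralSpec":
        """Allometric weight scaling with fixed exponents (1 on V, 0.75 on CL)."""
        return cls(
            cl_effects=(CovariateEffect("cw_g", "cl", REF_CW_G, 0.75),),
            v_effects=(CovariateEffect("cw_g", "v", REF_CW_G, 1.0),),
        )

    @classmethod
    def final(cls) -> "StructuralSpec":
        """The published final structure: allometry + PNA/GA maturation on CL."""
        base = cls.base()
        return replace(
            base,
            cl_effects=base.cl_effects
            + (
                CovariateEffect("pna_days", "cl", REF_PNA_DAYS, None),
                CovariateEffect("ga_weeks", "cl", REF_GA_WEEKS, None),
            ),
        )

    def with_effect(self, eff: CovariateEffect) -> "StructuralSpec":
        if eff.parameter == "cl":
            return replace(self, cl_effects=self.cl_effects + (eff,))
        return replace(self, v_effects=self.v_effects + (eff,))

    def without_effect(self, eff: CovariateEffect) -> "StructuralSpec":
        return replace(
            self,
            cl_effects=tuple(e for e in self.cl_effects if e != eff),
            v_effects=tuple(e for e in self.v_effects if e != eff),
        )

    @property
    def free_effects(self) -> tuple[CovariateEffect, ...]:
        return tuple(
            e for e in self.cl_effects + self.v_effects if e.exponent is None
        )

    @property
    def is_final(self) -> bool:
        free = [(e.covariate, e.parameter) for e in self.free_effects]
        return (
            free == [("pna_days", "cl"), ("ga_weeks", "cl")]
            and len(self.cl_effects) == 3
            and len(self.v_effects) == 1
        )

    @property
    def param_names(self) -> list[str]:
        return (
            ["theta_v", "theta_cl"]
            + [e.name for e in self.free_effects]
            + ["omega_cl_sd", "omega_v_sd", "sigma_prop"]
        )


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Estimates, OFV, uncertainty and per-subject/per-observation outputs."""

    spec: StructuralSpec
    estimates: dict[str, float]
    ofv: float
    se: dict[str, float]
    rse_percent: dict[str, float]
    etas: dict[str, tuple[float, float]]
    ebe_params: dict[str, IndividualParams]
    subject_ids: list[str]
    obs_subject: list[str]
    obs_time: np.ndarray
    obs_dv: np.ndarray
    ipred: np.ndarray
    pred: np.ndarray
    converged: bool
    n_fev: int
    n_iter: int
    message: str
    n_bql_excluded: int

    def to_pop_model(self) -> PopModel:
        """Map estimates onto the published four-theta model form."""
        if not self.spec.is_final:
            raise ValueError("fit structure is not the final PNA+GA model")
        e = self.estimates
        return PopModel(
            theta1=e["theta_v"],
            theta2=e["theta_cl"],
            theta3=e["beta_pna_cl"],
            theta4=e["beta_ga_cl"],
            omega=np.diag([e["omega_cl_sd"] ** 2, e["omega_v_sd"] ** 2]),
            sigma_prop=e["sigma_prop"],
        )


@dataclass
class SelectionStep:
    phase: str  # 'forward' | 'backward'
    covariate: str
    parameter: str
    delta_ofv: float
    accepted: bool
    note: str = ""


@dataclass
class CovariateSearchResult:
    steps: list[SelectionStep]
    retained: list[CovariateEffect]
    final: FitResult


# ---------------------------------------------------------------------------
# workspace: vectorized predictions and the FOCE-I objective


class _Workspace:
    """Flattened arrays for one dataset under one structural spec."""

    def __init__(self, dataset: StudyDataset, spec: StructuralSpec):
        self.spec = spec
        self.subject_ids = [s.id for s in dataset.subjects]
        n_subj = len(dataset.subjects)

        y, obs_subj, obs_time, obs_sid = [], [], [], []
        p_obs, p_s, p_T, p_r0 = [], [], [], []
        n_bql = 0
        for i, s in enumerate(dataset.subjects):
            for o in s.observations:
                if o.bql:
                    n_bql += 1
                    continue
                j = len(y)
                y.append(o.dv_mg_L)
                obs_subj.append(i)
                obs_time.append(o.time_h)
                obs_sid.append(s.id)
                for d in s.doses:
                    el = o.time_h - d.start_h
                    if el > 0:
                        p_obs.append(j)
                        p_s.append(el)
                        p_T.append(d.duration_h)
                        p_r0.append(d.rate_mg_h)
        if not y:
            raise ValueError("no quantifiable observations to fit")
        self.n_subj = n_subj
        self.n_obs = len(y)
        self.n_bql = n_bql
        self.y = np.asarray(y)
        self.obs_subj = np.asarray(obs_subj, dtype=np.intp)
        self.obs_time = np.asarray(obs_time)
        self.obs_sid = obs_sid
        self.p_obs = np.asarray(p_obs, dtype=np.intp)
        self.p_s = np.asarray(p_s)
        self.p_T = np.asarray(p_T)
        self.p_r0 = np.asarray(p_r0)
        self.p_subj = self.obs_subj[self.p_obs]
        # branch-free infusion kinetics: b = elapsed time within the
        # infusion, sb = elapsed time after its end (zero while running)
        self.p_b = np.minimum(self.p_s, self.p_T)
        self.p_sb = self.p_s - self.p_b
        # per-subject slices (observations are appended in subject order)
        counts = np.bincount(self.obs_subj, minlength=n_subj)
        ends = np.cumsum(counts)
        self.obs_slices = [slice(e - c, e) for c, e in zip(counts, ends)]
        self.obs_counts = counts
        # subjects grouped by observation count for batched linear algebra
        self.count_groups: list[tuple[int, np.ndarray, np.ndarray]] = []
        for c in np.unique(counts):
            if c == 0:
                continue
            subj_idx = np.flatnonzero(counts == c)
            row_idx = np.stack(
                [np.arange(ends[i] - c, ends[i]) for i in subj_idx]
            )  # (m, c)
            self.count_groups.append((int(c), subj_idx, row_idx))

        # covariate design: fixed log-offsets and free log-ratio columns
        def logratio(eff: CovariateEffect) -> np.ndarray:
            vals = np.array(
                [getattr(s.covariates, eff.covariate) for s in dataset.subjects]
            )
            return np.log(vals / eff.reference)

        self.cl_fixed = np.zeros(n_subj)
        self.v_fixed = np.zeros(n_subj)
        cl_free_cols, v_free_cols, free_names = [], [], []
        for eff in spec.cl_effects:
            lr = logratio(eff)
            if eff.exponent is None:
                cl_free_cols.append(lr)
                v_free_cols.append(np.zeros(n_subj))
                free_names.append(eff.name)
            else:
                self.cl_fixed += eff.exponent * lr
        for eff in spec.v_effects:
            lr = logratio(eff)
            if eff.exponent is None:
                cl_free_cols.append(np.zeros(n_subj))
                v_free_cols.append(lr)
                free_names.append(eff.name)
            else:
                self.v_fixed += eff.exponent * lr
        self.cl_free = np.column_stack(cl_free_cols) if cl_free_cols else np.zeros((n_subj, 0))
        self.v_free = np.column_stack(v_free_cols) if v_free_cols else np.zeros((n_subj, 0))
        self.free_names = free_names
        self.eta_cache = np.zeros((n_subj, 2))

    # -- parameter vector <-> natural values ------------------------------

    @property
    def n_free(self) -> int:
        return self.cl_free.shape[1]

    def pack(self, est: dict[str, float]) -> np.ndarray:
        x = [np.log(est["theta_cl"]), np.log(est["theta_v"])]
        x += [est[name] for name in self.free_names]
        x += [
            np.log(est["omega_cl_sd"]),
            np.log(est["omega_v_sd"]),
            np.log(est["sigma_prop"]),
        ]
        return np.asarray(x)

    def unpack(self, x: np.ndarray) -> dict[str, float]:
        k = self.n_free
        est = {
            "theta_cl": float(np.exp(x[0])),
            "theta_v": float(np.exp(x[1])),
        }
        for i, name in enumerate(self.free_names):
            est[name] = float(x[2 + i])
        est["omega_cl_sd"] = float(np.exp(np.clip(x[2 + k], -10.0, 3.0)))
        est["omega_v_sd"] = float(np.exp(np.clip(x[3 + k], -10.0, 3.0)))
        est["sigma_prop"] = float(np.exp(np.clip(x[4 + k], -10.0, 2.0)))
        return est

    def typical(self, est: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject typical CL and V at the current fixed effects."""
        beta = np.array([est[name] for name in self.free_names])
        cl = est["theta_cl"] * np.exp(self.cl_fixed + self.cl_free @ beta)
        v = est["theta_v"] * np.exp(self.v_fixed + self.v_free @ beta)
        return cl, v

    # -- predictions -------------------------------------------------------

    def predict(
        self, cl: np.ndarray, v: np.ndarray, deriv: bool = False
    ) -> tuple[np.ndarray, ...]:
        """Concentration (and d/d ln CL, d/d ln V) per observation row.

        ``cl``/``v`` are per-subject; derivatives are analytic, by
        superposition of per-infusion closed forms.
        """
        ke = cl / v
        clp = cl[self.p_subj]
        kep = ke[self.p_subj]
        rc = self.p_r0 / clp
        e_b = np.exp(-kep * self.p_b)          # decay over the running part
        e_tail = np.exp(-kep * self.p_sb)      # post-infusion decay (1 while running)
        one_m = 1.0 - e_b
        C = rc * one_m * e_tail
        f = np.bincount(self.p_obs, weights=C, minlength=self.n_obs)
        if not deriv:
            return (f,)
        h_ke = e_tail * (self.p_b * e_b - self.p_sb * one_m)
        q = rc * h_ke * kep
        d1 = np.bincount(self.p_obs, weights=q - C, minlength=self.n_obs)  # d/d ln CL
        d2 = np.bincount(self.p_obs, weights=-q, minlength=self.n_obs)     # d/d ln V
        return f, d1, d2

    # -- inner problem: conditional modes ---------------------------------

    def _indiv_obj(
        self, f: np.ndarray, sigma: float, eta: np.ndarray, om_inv: np.ndarray
    ) -> np.ndarray:
        """-2 log joint density per subject (up to the Omega determinant)."""
        fs = np.maximum(f, _F_FLOOR)
        w = (sigma * fs) ** 2
        e = self.y - f
        terms = e * e / w + np.log(w)
        per_subj = np.bincount(self.obs_subj, weights=terms, minlength=self.n_subj)
        quad = np.einsum("nk,kl,nl->n", eta, om_inv, eta)
        return per_subj + quad

    def conditional_modes(
        self,
        cl_typ: np.ndarray,
        v_typ: np.ndarray,
        omega: np.ndarray,
        sigma: float,
        eta0: np.ndarray | None = None,
    ) -> np.ndarray:
        """MAP eta per subject by damped Gauss-Newton, all subjects at once."""
        om_inv = np.linalg.inv(omega)
        eta = np.zeros((self.n_subj, 2)) if eta0 is None else eta0.copy()
        lam = np.full(self.n_subj, 1e-8)

        def fval(eta_):
            cl = cl_typ * np.exp(eta_[:, 0])
            v = v_typ * np.exp(eta_[:, 1])
            return self.predict(cl, v, deriv=False)[0]

        g = self._indiv_obj(fval(eta), sigma, eta, om_inv)
        for _ in range(_INNER_MAX_ITER):
            cl = cl_typ * np.exp(eta[:, 0])
            v = v_typ * np.exp(eta[:, 1])
            f, d1, d2 = self.predict(cl, v, deriv=True)
            fs = np.maximum(f, _F_FLOOR)
            w = (sigma * fs) ** 2
            e = self.y - f
            common = -2.0 * e / w - 2.0 * e * e / (w * fs) + 2.0 / fs
            g1 = np.bincount(self.obs_subj, weights=d1 * common, minlength=self.n_subj)
            g2 = np.bincount(self.obs_subj, weights=d2 * common, minlength=self.n_subj)
            grad = np.column_stack([g1, g2]) + 2.0 * eta @ om_inv
            if np.abs(grad).max() < _INNER_GRAD_TOL:
                break
            # curvature of the fit term: d(per-obs gradient weight)/df,
            # keeping first-derivative products only (f_kl dropped); fall
            # back to the always-PSD Gauss-Newton weight where indefinite
            u = 2.0 / w + 8.0 * e / (w * fs) + 6.0 * e * e / (w * fs * fs) - 2.0 / (fs * fs)
            gn = 2.0 / w
            h11 = np.bincount(self.obs_subj, weights=d1 * d1 * u, minlength=self.n_subj)
            h12 = np.bincount(self.obs_subj, weights=d1 * d2 * u, minlength=self.n_subj)
            h22 = np.bincount(self.obs_subj, weights=d2 * d2 * u, minlength=self.n_subj)
            H11 = h11 + 2.0 * om_inv[0, 0] + lam
            H12 = h12 + 2.0 * om_inv[0, 1]
            H22 = h22 + 2.0 * om_inv[1, 1] + lam
            bad = (H11 <= 0) | (H11 * H22 - H12 * H12 <= 0)
            if bad.any():
                g11 = np.bincount(self.obs_subj, weights=d1 * d1 * gn, minlength=self.n_subj)
                g12 = np.bincount(self.obs_subj, weights=d1 * d2 * gn, minlength=self.n_subj)
                g22 = np.bincount(self.obs_subj, weights=d2 * d2 * gn, minlength=self.n_subj)
                H11 = np.where(bad, g11 + 2.0 * om_inv[0, 0] + lam, H11)
                H12 = np.where(bad, g12 + 2.0 * om_inv[0, 1], H12)
                H22 = np.where(bad, g22 + 2.0 * om_inv[1, 1] + lam, H22)
            det = H11 * H22 - H12 * H12
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            s1 = (H22 * grad[:, 0] - H12 * grad[:, 1]) / det
            s2 = (H11 * grad[:, 1] - H12 * grad[:, 0]) / det
            delta = np.column_stack([s1, s2])
            # trust region: cap the step length so stiff (small-variance)
            # subjects cannot overshoot into overflow territory
            norm = np.sqrt((delta * delta).sum(axis=1))
            scale = np.minimum(1.0, 2.0 / np.maximum(norm, 1e-300))
            delta *= scale[:, None]
            alpha = np.ones(self.n_subj)
            eta_try = eta - delta
            g_try = self._indiv_obj(fval(eta_try), sigma, eta_try, om_inv)
            for _half in range(12):
                worse = g_try > g + 1e-13
                if not worse.any():
                    break
                alpha[worse] *= 0.5
                eta_try[worse] = eta[worse] - alpha[worse, None] * delta[worse]
                g_new = self._indiv_obj(fval(eta_try), sigma, eta_try, om_inv)
                g_try = np.where(worse, g_new, g_try)
            improved = g_try <= g + 1e-13
            eta = np.where(improved[:, None], eta_try, eta)
            g = np.where(improved, g_try, g)
            lam = np.where(improved, np.maximum(lam * 0.3, 1e-8), lam * 10.0)
            if np.abs(alpha[improved, None] * delta[improved]).max(initial=0.0) < 1e-12:
                break
        return eta

    def conditional_modes_multistart(
        self,
        cl_typ: np.ndarray,
        v_typ: np.ndarray,
        omega: np.ndarray,
        sigma: float,
    ) -> np.ndarray:
        """Conditional modes with a fixed grid of starting points.

        The individual objective can be multimodal for very informative
        (low residual noise) subjects; restarting along the eta_CL axis
        and keeping the per-subject best guards against local modes.
        """
        om_inv = np.linalg.inv(omega)
        s_cl = float(np.sqrt(omega[0, 0]))
        s_v = float(np.sqrt(omega[1, 1]))
        starts = [(0.0, 0.0)]
        starts += [(k * s_cl, 0.0) for k in (-3.0, -1.5, 1.5, 3.0)]
        starts += [(0.0, k * s_v) for k in (-1.5, 1.5)]
        best_eta = None
        best_g = None
        for e0 in starts:
            eta0 = np.tile(np.asarray(e0), (self.n_subj, 1))
            eta = self.conditional_modes(cl_typ, v_typ, omega, sigma, eta0=eta0)
            cl = cl_typ * np.exp(eta[:, 0])
            v = v_typ * np.exp(eta[:, 1])
            f = self.predict(cl, v, deriv=False)[0]
            g = self._indiv_obj(f, sigma, eta, om_inv)
            if best_eta is None:
                best_eta, best_g = eta, g
            else:
                better = g < best_g
                best_eta = np.where(better[:, None], eta, best_eta)
                best_g = np.where(better, g, best_g)
        return best_eta

    # -- FOCE-I objective --------------------------------------------------

    def ofv(
        self,
        est: dict[str, float],
        eta0: np.ndarray | None = None,
        keep_cache: bool = False,
        return_parts: bool = False,
    ):
        """FOCE-I approximate -2 log-likelihood (full constants included)."""
        omega = np.diag([est["omega_cl_sd"] ** 2, est["omega_v_sd"] ** 2])
        sigma = est["sigma_prop"]
        cl_typ, v_typ = self.typical(est)
        if not (np.all(np.isfinite(cl_typ)) and np.all(np.isfinite(v_typ))):
            return _OFV_SENTINEL if not return_parts else (_OFV_SENTINEL, None, None, None)
        eta = self.conditional_modes(cl_typ, v_typ, omega, sigma, eta0=eta0)
        if keep_cache:
            self.eta_cache = eta
        cl = cl_typ * np.exp(eta[:, 0])
        v = v_typ * np.exp(eta[:, 1])
        f, d1, d2 = self.predict(cl, v, deriv=True)
        fs = np.maximum(f, _F_FLOOR)
        w = (sigma * fs) ** 2
        total = 0.0
        ln2pi = np.log(2.0 * np.pi)
        res = self.y - f
        for c, subj_idx, row_idx in self.count_groups:
            G = np.stack([d1[row_idx], d2[row_idx]], axis=-1)  # (m, c, 2)
            V = np.einsum("mik,kl,mjl->mij", G, omega, G)
            V[:, np.arange(c), np.arange(c)] += w[row_idx]
            r = res[row_idx] + np.einsum("mik,mk->mi", G, eta[subj_idx])
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                logger.warning("non-PD conditional covariance encountered")
                return _OFV_SENTINEL if not return_parts else (_OFV_SENTINEL, None, None, None)
            sol = np.linalg.solve(L, r[..., None])[..., 0]
            total += float(
                len(subj_idx) * c * ln2pi
                + 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
                + (sol * sol).sum()
            )
        if not np.isfinite(total):
            return _OFV_SENTINEL if not return_parts else (_OFV_SENTINEL, None, None, None)
        if return_parts:
            return total, eta, f, (d1, d2)
        return total


# ---------------------------------------------------------------------------
# public operations


def foce_objective(dataset: StudyDataset, model: PopModel) -> float:
    """FOCE-I objective (approximate -2 log-likelihood) of the final-form model.

    Deterministic: inner optimizations start from eta = 0.  BQL-flagged
    rows are excluded.
    """
    ws = _Workspace(dataset, StructuralSpec.final())
    est = {
        "theta_v": model.theta1,
        "theta_cl": model.theta2,
        "beta_pna_cl": model.theta3,
        "beta_ga_cl": model.theta4,
        "omega_cl_sd": max(model.omega_cl_sd, 1e-6),
        "omega_v_sd": max(model.omega_v_sd, 1e-6),
        "sigma_prop": model.sigma_prop,
    }
    return float(ws.ofv(est))


def default_init(spec: StructuralSpec | None = None) -> dict[str, float]:
    """Neutral starting values for the outer optimization."""
    spec = spec or StructuralSpec.final()
    est = {
        "theta_v": 1.5,
        "theta_cl": 0.4,
        "omega_cl_sd": 0.4,
        "omega_v_sd": 0.3,
        "sigma_prop": 0.25,
    }
    for eff in spec.free_effects:
        est[eff.name] = 0.1
    return est


def _init_to_dict(
    init: PopModel | dict[str, float] | None, spec: StructuralSpec
) -> dict[str, float]:
    if init is None:
        return default_init(spec)
    if isinstance(init, PopModel):
        est = {
            "theta_v": init.theta1,
            "theta_cl": init.theta2,
            "omega_cl_sd": max(init.omega_cl_sd, 1e-3),
            "omega_v_sd": max(init.omega_v_sd, 1e-3),
            "sigma_prop": max(init.sigma_prop, 1e-3),
        }
        for eff in spec.free_effects:
            if eff.covariate == "pna_days" and eff.parameter == "cl":
                est[eff.name] = init.theta3
            elif eff.covariate == "ga_weeks" and eff.parameter == "cl":
                est[eff.name] = init.theta4
            else:
                est[eff.name] = 0.1
        return est
    est = dict(default_init(spec))
    est.update(init)
    return est


def fit(
    dataset: StudyDataset,
    init: PopModel | dict[str, float] | None = None,
    spec: StructuralSpec | None = None,
    maxfev: int = 4000,
    compute_se: bool = True,
    n_restarts: int = 2,
) -> FitResult:
    """Estimate (theta, omega, sigma) by minimizing the FOCE-I objective.

    Positivity of thetas, omega SDs and sigma is enforced by log
    parameterization; covariate exponents are unconstrained.  The
    Nelder-Mead search is restarted with a fresh simplex at its own
    optimum (up to ``n_restarts`` passes) to escape premature simplex
    collapse.  Standard errors come from a central finite-difference
    Hessian of the objective at the optimum (covariance = 2 H^{-1}).
    """
    spec = spec or StructuralSpec.final()
    ws = _Workspace(dataset, spec)
    est0 = _init_to_dict(init, spec)
    x0 = ws.pack(est0)

    def obj(x: np.ndarray) -> float:
        est = ws.unpack(x)
        return ws.ofv(est, eta0=ws.eta_cache, keep_cache=True)

    x = x0
    res = None
    nfev = nit = 0
    prev = np.inf
    for _pass in range(max(n_restarts, 1)):
        res = optimize.minimize(
            obj,
            x,
            method="Nelder-Mead",
            options=dict(
                maxfev=maxfev, fatol=1e-4, xatol=1e-4, adaptive=True, disp=False
            ),
        )
        x = res.x
        nfev += int(res.nfev)
        nit += int(res.nit)
        if prev - res.fun < 0.01:
            break
        prev = res.fun
    est = ws.unpack(res.x)
    # final deterministic pass from eta = 0
    ofv_val, eta, f_ip, _ = ws.ofv(est, eta0=None, return_parts=True)
    converged = bool(res.success) and ofv_val < _OFV_SENTINEL
    if eta is None:
        eta = np.zeros((ws.n_subj, 2))
        f_ip = np.full(ws.n_obs, np.nan)

    cl_typ, v_typ = ws.typical(est)
    pred = ws.predict(cl_typ, v_typ, deriv=False)[0]
    etas = {sid: (float(eta[i, 0]), float(eta[i, 1]))
            for i, sid in enumerate(ws.subject_ids)}
    ebe = {
        sid: IndividualParams(
            cl_L_h=float(cl_typ[i] * np.exp(eta[i, 0])),
            v_L=float(v_typ[i] * np.exp(eta[i, 1])),
        )
        for i, sid in enumerate(ws.subject_ids)
    }

    se: dict[str, float] = {}
    rse: dict[str, float] = {}
    if compute_se and converged:
        se, rse = _standard_errors(ws, est, ofv_val)

    return FitResult(
        spec=spec,
        estimates=est,
        ofv=float(ofv_val),
        se=se,
        rse_percent=rse,
        etas=etas,
        ebe_params=ebe,
        subject_ids=list(ws.subject_ids),
        obs_subject=list(ws.obs_sid),
        obs_time=ws.obs_time.copy(),
        obs_dv=ws.y.copy(),
        ipred=np.asarray(f_ip),
        pred=pred,
        converged=converged,
        n_fev=nfev,
        n_iter=nit,
        message=str(res.message),
        n_bql_excluded=ws.n_bql,
    )


def _standard_errors(
    ws: _Workspace, est: dict[str, float], f0: float
) -> tuple[dict[str, float], dict[str, float]]:
    """Asymptotic SEs from a finite-difference Hessian on the natural scale."""
    names = ["theta_v", "theta_cl", *ws.free_names,
             "omega_cl_sd", "omega_v_sd", "sigma_prop"]
    p0 = np.array([est[n] for n in names])
    h = np.maximum(np.abs(p0) * 1e-3, 1e-5)

    def f_at(p: np.ndarray) -> float:
        e = dict(zip(names, p))
        return ws.ofv(e, eta0=ws.eta_cache)

    n = len(p0)
    H = np.empty((n, n))
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        pp, pm = p0.copy(), p0.copy()
        pp[i] += h[i]
        pm[i] -= h[i]
        fp[i] = f_at(pp)
        fm[i] = f_at(pm)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ppp, ppm, pmp, pmm = p0.copy(), p0.copy(), p0.copy(), p0.copy()
            ppp[[i, j]] += [h[i], h[j]]
            ppm[i] += h[i]; ppm[j] -= h[j]
            pmp[i] -= h[i]; pmp[j] += h[j]
            pmm[[i, j]] -= [h[i], h[j]]
            H[i, j] = H[j, i] = (
                f_at(ppp) - f_at(ppm) - f_at(pmp) + f_at(pmm)
            ) / (4.0 * h[i] * h[j])
    se: dict[str, float] = {}
    rse: dict[str, float] = {}
    try:
        cov = 2.0 * np.linalg.inv(H)
        d = np.diag(cov)
        ok = np.all(d > 0)
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        logger.warning("information matrix not positive definite; SEs unavailable")
        for nme in names:
            se[nme] = float("nan")
            rse[nme] = float("nan")
        return se, rse
    for i, nme in enumerate(names):
        se[nme] = float(np.sqrt(d[i]))
        rse[nme] = float(100.0 * se[nme] / abs(p0[i])) if p0[i] != 0 else float("nan")
    return se, rse


@dataclass
class EBEResult:
    etas: dict[str, tuple[float, float]]
    params: dict[str, IndividualParams]
    cl_per_kg: dict[str, float]
    v_per_kg: dict[str, float]
    ipred: np.ndarray
    pred: np.ndarray
    obs_subject: list[str]
    obs_time: np.ndarray
    obs_dv: np.ndarray


def empirical_bayes(dataset: StudyDataset, model: PopModel) -> EBEResult:
    """MAP (empirical Bayes) etas and individual parameters at fixed model.

    Subjects without quantifiable observations sit at the prior mode
    (eta = 0).  Weight-normalized parameters use current weight in kg.
    """
    ws = _Workspace(dataset, StructuralSpec.final())
    est = {
        "theta_v": model.theta1,
        "theta_cl": model.theta2,
        "beta_pna_cl": model.theta3,
        "beta_ga_cl": model.theta4,
        "omega_cl_sd": max(model.omega_cl_sd, 1e-6),
        "omega_v_sd": max(model.omega_v_sd, 1e-6),
        "sigma_prop": model.sigma_prop,
    }
    cl_typ, v_typ = ws.typical(est)
    omega = np.diag([est["omega_cl_sd"] ** 2, est["omega_v_sd"] ** 2])
    eta = ws.conditional_modes_multistart(cl_typ, v_typ, omega, est["sigma_prop"])
    cl = cl_typ * np.exp(eta[:, 0])
    v = v_typ * np.exp(eta[:, 1])
    ipred = ws.predict(cl, v, deriv=False)[0]
    pred = ws.predict(cl_typ, v_typ, deriv=False)[0]
    etas, params, clkg, vkg = {}, {}, {}, {}
    for i, (sid, subj) in enumerate(zip(ws.subject_ids, dataset.subjects)):
        etas[sid] = (float(eta[i, 0]), float(eta[i, 1]))
        params[sid] = IndividualParams(cl_L_h=float(cl[i]), v_L=float(v[i]))
        kg = subj.covariates.cw_kg
        clkg[sid] = float(cl[i]) / kg
        vkg[sid] = float(v[i]) / kg
    return EBEResult(
        etas=etas, params=params, cl_per_kg=clkg, v_per_kg=vkg,
        ipred=ipred, pred=pred, obs_subject=list(ws.obs_sid),
        obs_time=ws.obs_time.copy(), obs_dv=ws.y.copy(),
    )


DEFAULT_CANDIDATES = (
    "bw_g", "cw_g", "pna_days", "ga_weeks",
    "pma_weeks", "alb_g_L", "bun_mmol_L", "crea_umol_L",
)


def stepwise_covariates(
    dataset: StudyDataset,
    base: StructuralSpec | None = None,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    parameters: Sequence[str] = ("cl", "v"),
    forward_dofv: float = 3.84,
    backward_dofv: float = 6.635,
    init: PopModel | dict[str, float] | None = None,
    maxfev: int = 2500,
) -> CovariateSearchResult:
    """Forward/backward likelihood-ratio covariate selection.

    Candidates enter as power models on the dataset-median-normalized
    covariate.  Forward phase: every candidate whose univariate OFV drop
    against the base model exceeds ``forward_dofv`` joins the full model.
    Backward phase: each included effect is deleted in turn and retained
    only if its removal raises the OFV by more than ``backward_dofv``.
    """
    base = base or StructuralSpec.base()
    steps: list[SelectionStep] = []

    def _fit(s: StructuralSpec, warm: dict[str, float] | None = None) -> FitResult:
        # warm-start nested fits from the enclosing model's estimates;
        # exponents new to the candidate spec fall back to the default init
        start = warm if warm is not None else init
        return fit(dataset, init=start, spec=s, maxfev=maxfev, compute_se=False)

    base_fit = _fit(base)
    candidates_eff = [
        CovariateEffect(cov, par, dataset.covariate_median(cov), None)
        for cov in candidates
        for par in parameters
    ]

    selected: list[CovariateEffect] = []
    for eff in candidates_eff:
        try:
            f1 = _fit(base.with_effect(eff), warm=base_fit.estimates)
            dofv = base_fit.ofv - f1.ofv
        except Exception as exc:  # numerical failure: skip with a log entry
            logger.warning("forward step %s on %s failed: %s",
                           eff.covariate, eff.parameter, exc)
            steps.append(SelectionStep("forward", eff.covariate, eff.parameter,
                                       float("nan"), False, f"failed: {exc}"))
            continue
        accepted = dofv > forward_dofv
        steps.append(SelectionStep("forward", eff.covariate, eff.parameter,
                                   float(dofv), accepted))
        if accepted:
            selected.append(eff)

    full = base
    for eff in selected:
        full = full.with_effect(eff)
    full_fit = _fit(full, warm=base_fit.estimates) if selected else base_fit

    retained: list[CovariateEffect] = []
    for eff in selected:
        try:
            f_red = _fit(full.without_effect(eff), warm=full_fit.estimates)
            dofv = f_red.ofv - full_fit.ofv
        except Exception as exc:
            logger.warning("backward step %s on %s failed: %s",
                           eff.covariate, eff.parameter, exc)
            steps.append(SelectionStep("backward", eff.covariate, eff.parameter,
                                       float("nan"), True, f"failed: {exc}"))
            retained.append(eff)
            continue
        keep = dofv > backward_dofv
        steps.append(SelectionStep("backward", eff.covariate, eff.parameter,
                                   float(dofv), keep))
        if keep:
            retained.append(eff)

    final_spec = base
    for eff in retained:
        final_spec = final_spec.with_effect(eff)
    final_fit = (
        _fit(final_spec, warm=full_fit.estimates)
        if retained != selected
        else full_fit
    )
    return CovariateSearchResult(steps=steps, retained=retained, final=final_fit)
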