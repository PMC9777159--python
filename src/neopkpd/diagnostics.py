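"""Internal and external model validation.

Internal: conditional weighted residuals (CWRES), nonparametric bootstrap
over subjects, normalized prediction distribution errors (NPDE), and the
visual predictive check (VPC).  External: mean (signed) and mean absolute
prediction error against an independent cohort, with per-subject summaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import StudyDataset, Subject
from .estimation import (
    FitResult,
    StructuralSpec,
    _Workspace,
    empirical_bayes,
    fit,
)
from .pkmodel import PopModel

logger = logging.getLogger(__name__)


def _model_to_est(model: PopModel) -> dict[str, float]:
    return {
        "theta_v": model.theta1,
        "theta_cl": model.theta2,
        "beta_pna_cl": model.theta3,
        "beta_ga_cl": model.theta4,
        "omega_cl_sd": max(model.omega_cl_sd, 1e-6),
        "omega_v_sd": max(model.omega_v_sd, 1e-6),
        "sigma_prop": model.sigma_prop,
    }


# ---------------------------------------------------------------------------
# CWRES


def cwres(dataset: StudyDataset, model: PopModel) -> pd.DataFrame:
    """Conditional weighted residuals under the FOCE-I linearization.

    Per subject: residual r = y - f(eta_hat) + G eta_hat is whitened by
    the Cholesky factor of V = G Omega G' + diag(sigma^2 f^2).  Under a
    correct model CWRES are approximately iid N(0, 1).
    """
    ws = _Workspace(dataset, StructuralSpec.final())
    est = _model_to_est(model)
    omega = np.diag([est["omega_cl_sd"] ** 2, est["omega_v_sd"] ** 2])
    cl_typ, v_typ = ws.typical(est)
    eta = ws.conditional_modes(cl_typ, v_typ, omega, est["sigma_prop"])
    cl = cl_typ * np.exp(eta[:, 0])
    v = v_typ * np.exp(eta[:, 1])
    f, d1, d2 = ws.predict(cl, v, deriv=True)
    w = (est["sigma_prop"] * np.maximum(f, 1e-12)) ** 2
    pred = ws.predict(cl_typ, v_typ, deriv=False)[0]

    out = np.full(ws.n_obs, np.nan)
    for i, sl in enumerate(ws.obs_slices):
        if sl.stop == sl.start:
            continue
        G = np.column_stack([d1[sl], d2[sl]])
        V = G @ omega @ G.T + np.diag(w[sl])
        r = ws.y[sl] - f[sl] + G @ eta[i]
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            logger.warning(
                "singular conditional covariance for subject %s; CWRES flagged NaN",
                ws.subject_ids[i],
            )
            continue
        out[sl] = np.linalg.solve(L, r)
    return pd.DataFrame(
        {
            "subject": ws.obs_sid,
            "time_h": ws.obs_time,
            "dv_mg_L": ws.y,
            "pred": pred,
            "ipred": f,
            "cwres": out,
        }
    )


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    n_resamples: int
    n_converged: int
    summary: pd.DataFrame  # per-parameter: estimate, median, p5, p95
    unreliable: bool

    def __post_init__(self) -> None:
        bad = (self.summary["p5"] > self.summary["median"]) | (
            self.summary["median"] > self.summary["p95"]
        )
        if bad.any():
            raise ValueError("bootstrap percentiles not ordered")


def bootstrap(
    dataset: StudyDataset,
    spec: StructuralSpec | None = None,
    n_resamples: int = 1000,
    seed: int | None = None,
    init: dict[str, float] | PopModel | None = None,
    maxfev: int = 1500,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects with replacement, refit.

    Each replicate preserves the original study size and is refitted from
    the original point estimates; non-converged replicates are counted
    and excluded.  Flagged unreliable when more than 20% fail.
    """
    spec = spec or StructuralSpec.final()
    rng = np.random.default_rng(seed)
    original = fit(dataset, init=init, spec=spec, compute_se=False)
    names = list(original.estimates)
    draws: list[dict[str, float]] = []
    n_subj = dataset.n_subjects
    n_failed = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n_subj, size=n_subj)
        subjects = [
            Subject(
                id=f"B{k:03d}",
                covariates=dataset.subjects[i].covariates,
                doses=dataset.subjects[i].doses,
                observations=dataset.subjects[i].observations,
            )
            for k, i in enumerate(idx)
        ]
        rep = StudyDataset(subjects=subjects)
        try:
            f = fit(rep, init=original.estimates, spec=spec,
                    maxfev=maxfev, compute_se=False, n_restarts=1)
        except Exception as exc:
            logger.warning("bootstrap replicate failed: %s", exc)
            n_failed += 1
            continue
        if not np.isfinite(f.ofv) or f.ofv >= 1e9:
            n_failed += 1
            continue
        draws.append(f.estimates)
    n_ok = len(draws)
    if n_ok == 0:
        raise RuntimeError("no bootstrap replicate converged")
    arr = np.array([[d[n] for n in names] for d in draws])
    summary = pd.DataFrame(
        {
            "parameter": names,
            "estimate": [original.estimates[n] for n in names],
            "median": np.median(arr, axis=0),
            "p5": np.percentile(arr, 5, axis=0),
            "p95": np.percentile(arr, 95, axis=0),
        }
    )
    return BootstrapResult(
        n_resamples=n_resamples,
        n_converged=n_ok,
        summary=summary,
        unreliable=n_failed > 0.2 * n_resamples,
    )


# ---------------------------------------------------------------------------
# NPDE


@dataclass
class NPDEResult:
    npde: np.ndarray
    mean: float
    variance: float
    ks_statistic: float
    ks_pvalue: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.npde)):
            raise ValueError("NPDE values must be finite")


def _simulate_matrix(
    ws: _Workspace, model: PopModel, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_sim, n_obs) simulated observations under the full model."""
    est = _model_to_est(model)
    cl_typ, v_typ = ws.typical(est)
    om = np.asarray(model.omega)
    chol = (
        np.linalg.cholesky(om + 1e-30 * np.eye(2)) if np.any(om) else np.zeros((2, 2))
    )
    out = np.empty((n_sim, ws.n_obs))
    for k in range(n_sim):
        eta = rng.standard_normal((ws.n_subj, 2)) @ chol.T
        cl = cl_typ * np.exp(eta[:, 0])
        v = v_typ * np.exp(eta[:, 1])
        f = ws.predict(cl, v, deriv=False)[0]
        out[k] = f * (1.0 + model.sigma_prop * rng.standard_normal(ws.n_obs))
    return out


def npde(
    dataset: StudyDataset,
    model: PopModel,
    n_sim: int = 1000,
    seed: int | None = None,
) -> NPDEResult:
    """Normalized prediction distribution errors.

    ``n_sim`` replicate datasets are simulated under the model (IIV +
    residual).  Per subject, observed and simulated vectors are
    decorrelated with the inverse Cholesky factor of the empirical
    simulated covariance; the prediction discrepancy of each decorrelated
    observation is its mid-rank among the simulated values, mapped through
    the standard normal quantile function.  Under a correct model NPDE
    follow N(0, 1); tested here by Kolmogorov-Smirnov.
    """
    ws = _Workspace(dataset, StructuralSpec.final())
    rng = np.random.default_rng(seed)
    sims = _simulate_matrix(ws, model, n_sim, rng)
    out = np.empty(ws.n_obs)
    for i, sl in enumerate(ws.obs_slices):
        n_i = sl.stop - sl.start
        if n_i == 0:
            continue
        block = sims[:, sl]                      # (n_sim, n_i)
        mu = block.mean(axis=0)
        scale = float(np.maximum(1.0, np.abs(mu).max()))
        if n_i == 1:
            sd = max(float(block.std(axis=0, ddof=1)[0]), 1e-9 * scale)
            y_star = (ws.y[sl] - mu) / sd
            s_star = (block - mu) / sd
        else:
            cov = np.cov(block, rowvar=False)
            cov = cov + (1e-9 * scale) ** 2 * np.eye(n_i)
            L = np.linalg.cholesky(cov)
            y_star = np.linalg.solve(L, ws.y[sl] - mu)
            s_star = np.linalg.solve(L, (block - mu).T).T
        # rank with a tiny relative tolerance so float round-off between
        # equal quantities counts as a tie, not a strict inequality
        tol = 1e-6 * np.maximum(1.0, np.abs(y_star))
        less = (s_star < y_star - tol).sum(axis=0)
        ties = (np.abs(s_star - y_star) <= tol).sum(axis=0)
        pd_mid = (less + 0.5 * ties + 0.5) / (n_sim + 1.0)
        out[sl] = stats.norm.ppf(pd_mid)
    ks = stats.kstest(out, "norm")
    return NPDEResult(
        npde=out,
        mean=float(out.mean()),
        variance=float(out.var(ddof=1)),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


# ---------------------------------------------------------------------------
# VPC


@dataclass
class VPCResult:
    table: pd.DataFrame  # per bin: observed and simulated-CI percentiles
    coverage: dict[str, float]  # fraction of bins whose observed pct is inside its CI
    n_sim: int


def _time_since_last_dose(dataset: StudyDataset, ws: _Workspace) -> np.ndarray:
    tsld = np.empty(ws.n_obs)
    j = 0
    for s in dataset.subjects:
        starts = np.array([d.start_h for d in s.doses])
        for o in s.observations:
            if o.bql:
                continue
            prior = starts[starts <= o.time_h]
            tsld[j] = o.time_h - (prior.max() if prior.size else 0.0)
            j += 1
    return tsld


def vpc(
    dataset: StudyDataset,
    model: PopModel,
    n_sim: int = 500,
    bins: int = 4,
    seed: int | None = None,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
) -> VPCResult:
    """Visual predictive check on time since last dose.

    Equal-count bins; per bin, the observed 5th/50th/95th percentiles are
    compared with simulation-based 95% confidence intervals of the same
    percentiles.  Empty bins are dropped with a warning.
    """
    ws = _Workspace(dataset, StructuralSpec.final())
    rng = np.random.default_rng(seed)
    tsld = _time_since_last_dose(dataset, ws)
    edges = np.unique(np.quantile(tsld, np.linspace(0, 1, bins + 1)))
    if len(edges) - 1 < bins:
        logger.warning("tied bin edges reduced VPC bins to %d", len(edges) - 1)
    which = np.clip(np.digitize(tsld, edges[1:-1]), 0, len(edges) - 2)
    sims = _simulate_matrix(ws, model, n_sim, rng)

    rows = []
    n_inside = {f"p{p:g}": 0 for p in percentiles}
    n_bins_used = 0
    for b in range(len(edges) - 1):
        mask = which == b
        if not mask.any():
            logger.warning("VPC bin %d is empty; dropped", b)
            continue
        n_bins_used += 1
        row: dict[str, float] = {
            "bin": b,
            "t_lo": edges[b],
            "t_hi": edges[b + 1],
            "n_obs": int(mask.sum()),
        }
        for p in percentiles:
            obs_p = float(np.percentile(ws.y[mask], p))
            sim_p = np.percentile(sims[:, mask], p, axis=1)  # per replicate
            lo, hi = np.percentile(sim_p, [2.5, 97.5])
            row[f"obs_p{p:g}"] = obs_p
            row[f"sim_p{p:g}_lo"] = float(lo)
            row[f"sim_p{p:g}_hi"] = float(hi)
            if lo <= obs_p <= hi:
                n_inside[f"p{p:g}"] += 1
        rows.append(row)
    coverage = {k: v / n_bins_used for k, v in n_inside.items()}
    return VPCResult(table=pd.DataFrame(rows), coverage=coverage, n_sim=n_sim)


# ---------------------------------------------------------------------------
# external validation


@dataclass
class ExternalValidationResult:
    mpe_percent: float
    mape_percent: float
    subject_mpe_percent: dict[str, float]
    pct_subjects_within_20: float
    pct_subjects_within_30: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_subjects_within_20 <= self.pct_subjects_within_30 <= 100:
            raise ValueError("within-percent summaries must be ordered in [0, 100]")


def prediction_error_summary(
    ipred: np.ndarray,
    obs: np.ndarray,
    subject_ids: Sequence[str],
    per_subject: bool = True,
) -> ExternalValidationResult:
    """MPE/MAPE summaries from paired predictions and observations.

    Relative error per observation is r = (IPRED - OBS)/OBS;
    MPE = mean(r) * 100 (signed), MAPE = mean(|r|) * 100.  The within
    +/-20%/30% summaries count subjects by their per-subject MPE when
    ``per_subject`` (the default), otherwise individual observations.
    """
    ipred = np.asarray(ipred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    r = (ipred - obs) / obs
    subj = np.asarray(subject_ids)
    subject_mpe: dict[str, float] = {}
    for sid in dict.fromkeys(subject_ids):
        subject_mpe[sid] = float(100.0 * r[subj == sid].mean())
    if per_subject:
        vals = np.array(list(subject_mpe.values()))
    else:
        vals = 100.0 * r
    return ExternalValidationResult(
        mpe_percent=float(100.0 * r.mean()),
        mape_percent=float(100.0 * np.abs(r).mean()),
        subject_mpe_percent=subject_mpe,
        pct_subjects_within_20=float(100.0 * (np.abs(vals) <= 20.0).mean()),
        pct_subjects_within_30=float(100.0 * (np.abs(vals) <= 30.0).mean()),
    )


def external_validate(
    model: PopModel,
    dataset: StudyDataset,
    per_subject: bool = True,
) -> ExternalValidationResult:
    """Predictive performance against an independent cohort.

    IPRED comes from empirical Bayes (MAP) estimation with the population
    parameters frozen; see :func:`prediction_error_summary` for the
    error definitions.
    """
    ebe = empirical_bayes(dataset, model)
    return prediction_error_summary(
        ebe.ipred, ebe.obs_dv, ebe.obs_subject, per_subject=per_subject
    )
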