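"""Independent numerical oracles used to cross-check the closed forms.

These deliberately avoid the package's analytic implementations: the
concentration oracle integrates the ODE dC/dt = R0(t)/V - ke*C with an
adaptive Runge-Kutta solver; the marginal likelihood oracle integrates
over the random effect with 64-node adaptive Gauss-Hermite quadrature;
the fT>MIC oracle counts threshold exceedances on a dense time grid.
"""
from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from neopkpd import DoseEvent, IndividualParams, PopModel, concentration, individual_params


def ode_concentration(t_eval: np.ndarray, doses: list[DoseEvent], p: IndividualParams) -> np.ndarray:
    """Integrate dC/dt = R(t)/V - ke*C numerically."""

    def rate(t: float) -> float:
        r = 0.0
        for d in doses:
            if d.start_h < t <= d.start_h + d.duration_h:
                r += d.rate_mg_h
        return r

    def rhs(t, y):
        return [rate(t) / p.v_L - p.ke_per_h * y[0]]

    # break integration at infusion edges so the solver never steps over a
    # rate discontinuity
    edges = sorted(
        {0.0, *[d.start_h for d in doses], *[d.start_h + d.duration_h for d in doses],
         *map(float, t_eval)}
    )
    out = {}
    y = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        sol = solve_ivp(rhs, (a, b), [y], rtol=1e-10, atol=1e-12, dense_output=True)
        y = float(sol.y[0, -1])
        for t in t_eval:
            if a < t <= b:
                out[float(t)] = float(sol.sol(t)[0])
    return np.array([out.get(float(t), 0.0) for t in t_eval])


def agh_minus2ll_single_eta(dataset, model: PopModel, n_nodes: int = 64) -> float:
    """Exact (to quadrature error) marginal -2LL with eta_CL as the only
    random effect (omega_V must be negligible in ``model``)."""
    z, wq = hermgauss(n_nodes)
    om = model.omega_cl_sd
    sigma = model.sigma_prop
    total = 0.0
    for s in dataset.subjects:
        t = np.array([o.time_h for o in s.observations if not o.bql])
        y = np.array([o.dv_mg_L for o in s.observations if not o.bql])

        def nll(eta1: float) -> float:
            p = individual_params(model, s.covariates, (eta1, 0.0))
            f = concentration(t, s.doses, p)
            w = (sigma * f) ** 2
            return (
                0.5 * np.sum((y - f) ** 2 / w + np.log(2 * np.pi * w))
                + 0.5 * eta1**2 / om**2
                + 0.5 * np.log(2 * np.pi * om**2)
            )

        res = minimize_scalar(nll, bounds=(-4, 4), method="bounded",
                              options={"xatol": 1e-10})
        mode = res.x
        h = (nll(mode + 1e-4) - 2 * nll(mode) + nll(mode - 1e-4)) / 1e-8
        sd = 1.0 / np.sqrt(h)
        x = mode + np.sqrt(2.0) * sd * z
        vals = np.array([-nll(xi) for xi in x])
        total += -2.0 * np.log(np.sqrt(2.0) * sd * np.sum(wq * np.exp(vals + z**2)))
    return total


def grid_ft_above_mic(
    p: IndividualParams,
    dose_mg: float,
    interval_h: float,
    infusion_h: float,
    mic: float,
    free_fraction: float,
    dt: float = 1e-4,
) -> float:
    """Dense-grid fraction of the steady-state interval above MIC/fu."""
    from neopkpd import steady_state_profile

    css = steady_state_profile(dose_mg, interval_h, infusion_h, p)
    t = np.arange(0.0, interval_h, dt)
    return float((free_fraction * css(t) > mic).mean())
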