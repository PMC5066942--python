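"""Vectorised right-hand sides shared by the full and reduced models."""

from __future__ import annotations

import numpy as np


def reaction_terms(x: np.ndarray, net) -> np.ndarray:
    """Mass-action catalytic reaction contribution to dx/dt.

    ``x`` has shape (n_cells, k). Each reaction X_i -> X_j catalysed by X_l
    proceeds at rate eps * x_i * x_l**alpha; the stoichiometry matrix turns
    per-reaction rates into per-species derivatives.
    """
    sub, _prod, cat, eps, stoich = net.reaction_arrays()
    if len(sub) == 0:
        return np.zeros_like(x)
    rates = eps * x[:, sub] * x[:, cat] ** net.alpha
    return rates @ stoich


def population_rhs(x, v, x_med, net, D, D_med, C, V_med, pin_volumes=False):
    """Time derivatives for n cells plus the shared medium.

    Cell i: reaction terms + D*sigma*(x_med - x) - x*mu, with growth rate
    mu = sum_i D*sigma_i*(x_med_i - x_i). Medium: nutrient supplied from the
    exterior at rate D_med*(C - x_med_0); every diffusible species is
    exchanged with each cell weighted by the cell's volume over V_med.

    Returns (dx, dv, dx_med, mu). With ``pin_volumes`` the dilution term is
    retained but dv is zero (the reduced models hold volumes constant).
    """
    sigma = net.diffusible
    flux = D * sigma * (x_med - x)  # (n, k) influx into each cell
    mu = flux.sum(axis=1)
    dx = reaction_terms(x, net) + flux - x * mu[:, None]
    dv = np.zeros_like(v) if pin_volumes else mu * v
    dx_med = -(flux * v[:, None]).sum(axis=0) / V_med
    dx_med[0] += D_med * (C - x_med[0])
    return dx, dv, dx_med, mu


def pack(x, v, x_med):
    return np.concatenate([x.ravel(), v, x_med])


def unpack(y, n, k):
    x = y[: n * k].reshape(n, k)
    v = y[n * k : n * k + n]
    x_med = y[n * k + n :]
    return x, v, x_med


def make_flat_rhs(net, D, D_med, C, V_med, n, pin_volumes=False):
    """Flat-vector RHS suitable for scipy's ODE solvers."""
    k = net.k

    def rhs(_t, y):
        x, v, x_med = unpack(y, n, k)
        dx, dv, dx_med, _mu = population_rhs(
            x, v, x_med, net, D, D_med, C, V_med, pin_volumes=pin_volumes
        )
        return pack(dx, dv, dx_med)

    return rhs


def rk4_fixed_step(rhs, y0, t0, t1, dt):
    """Classical fixed-step RK4; reference integrator for cross-checks."""
    n_steps = int(round((t1 - t0) / dt))
    y = np.array(y0, dtype=float)
    t = t0
    for _ in range(n_steps):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y
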