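"""Reduced one-cell and two-group models and coexistence-stability analysis.

The full population is reduced to either one isolated cell (r1cell) or two
effective cell groups (r2cell) whose total volume is constant; random
elimination at carrying capacity is then implicitly accounted for by the
growth-dilution term, so volumes are pinned and only compositions evolve.
``V = V_med / v`` is the medium-to-cell volume ratio: small V means strong
cell-cell coupling through the medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._kinetics import pack, population_rhs, unpack
from .networks import CatalyticNetwork

__all__ = [
    "ReducedConfig",
    "ReducedResult",
    "UnresolvedAttractorError",
    "run_r1cell",
    "run_r2cell",
    "run_fixed_ratio",
    "growth_curve_F",
    "coexistence_drift",
    "stability_index",
    "StabilityIndex",
    "classify_phase",
]

#: L1 distance between time-averaged group compositions above which the two
#: groups count as differentiated. Differentiated states differ by O(1) in L1,
#: so 0.1 separates cleanly; exposed as ReducedConfig.diff_threshold.
DIFF_THRESHOLD = 0.1

FIXED_POINT_RANGE = 1e-6   # max per-component range for a fixed point
LIMIT_CYCLE_RANGE = 1e-3   # min per-component range for a limit cycle


class UnresolvedAttractorError(RuntimeError):
    """Long-time behaviour neither settled nor clearly oscillatory."""


@dataclass
class ReducedConfig:
    """Parameters of a reduced-model run.

    C : exterior nutrient concentration
    V : volume ratio V_med / v between medium and total cellular volume
    D : cell-medium diffusion coefficient (D_med defaults to D)
    r1 : volume fraction of group 1 (two-group runs)
    """

    C: float
    V: float
    D: float
    D_med: Optional[float] = None
    r1: float = 0.5
    t_max: float = 1e4
    n_eval: int = 4001
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    split_size: float = 1e-3
    diff_threshold: float = DIFF_THRESHOLD

    def __post_init__(self):
        if not (self.C > 0 and self.V > 0 and self.D >= 0):
            raise ValueError("require C > 0, V > 0, D >= 0")
        if not 0.0 < self.r1 < 1.0:
            raise ValueError("r1 must lie strictly between 0 and 1")

    @property
    def d_med(self) -> float:
        return self.D if self.D_med is None else self.D_med


@dataclass
class ReducedResult:
    """Outcome of an r1cell/r2cell run.

    Compositions are time-averaged over the analysis window (the final half
    of the run), which makes fixed points and limit cycles comparable.
    """

    attractor_kind: str  # "fixed_point" or "limit_cycle"
    compositions: np.ndarray  # (n_groups, k) time-averaged
    mu: np.ndarray  # (n_groups,) time-averaged growth rates
    mu_tot: float
    differentiated: bool
    volumes: np.ndarray
    times: Optional[np.ndarray] = None
    trajectory: Optional[np.ndarray] = None  # (n_times, n_groups, k)
    medium: Optional[np.ndarray] = None  # (n_times, k)


def _integrate_groups(net, cfg, x0_groups, volumes, t_max):
    """Integrate group + medium ODEs; sample the final half densely."""
    n = len(volumes)
    k = net.k
    v = np.asarray(volumes, dtype=float)
    V_med = cfg.V * v.sum()

    def rhs(_t, y):
        x, vv, x_med = unpack(y, n, k)
        dx, _dv, dm, _mu = population_rhs(
            x, vv, x_med, net, cfg.D, cfg.d_med, cfg.C, V_med, pin_volumes=True
        )
        return pack(dx, np.zeros(n), dm)

    y0 = pack(np.asarray(x0_groups, dtype=float), v, np.zeros(k))
    t_eval = np.linspace(t_max / 2, t_max, cfg.n_eval)
    sol = solve_ivp(
        rhs, (0.0, t_max), y0, method=cfg.method, rtol=cfg.rtol, atol=cfg.atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"reduced-model integration failed: {sol.message}")
    ys = sol.y.T  # (n_times, dim)
    xs = ys[:, : n * k].reshape(-1, n, k)
    x_med = ys[:, n * k + n :]
    return sol.t, xs, x_med


def _classify_window(xs: np.ndarray) -> Optional[str]:
    """Attractor kind from the final quarter of the sampled window.

    A sustained limit cycle keeps the same per-component range in both
    halves of the inspection window, while relaxation toward a fixed point
    (even the slow algebraic kind, e.g. when diffusion is switched off and
    catalysts deplete) shows a clearly contracting range.
    """
    tail = xs[int(0.75 * len(xs)) :]
    worst = (tail.max(axis=0) - tail.min(axis=0)).max()
    if worst < FIXED_POINT_RANGE:
        return "fixed_point"
    half = len(tail) // 2
    r_first = (tail[:half].max(axis=0) - tail[:half].min(axis=0)).max()
    r_second = (tail[half:].max(axis=0) - tail[half:].min(axis=0)).max()
    if r_second < 0.9 * r_first:  # still contracting: not a sustained cycle
        return "fixed_point" if worst < LIMIT_CYCLE_RANGE else None
    if worst > LIMIT_CYCLE_RANGE:
        return "limit_cycle"
    return None


def _growth_rates(xs, x_med, net, cfg):
    """Time-averaged growth rate per group over the sampled window."""
    sigma = net.diffusible
    mu_t = (cfg.D * sigma * (x_med[:, None, :] - xs)).sum(axis=2)  # (t, n)
    return mu_t.mean(axis=0)


def _run(net, cfg, x0_groups, volumes, keep_trajectory=False):
    t_max = cfg.t_max
    for _attempt in range(2):
        times, xs, x_med = _integrate_groups(net, cfg, x0_groups, volumes, t_max)
        kind = _classify_window(xs)
        if kind is not None:
            break
        t_max *= 2  # slow transient: extend the horizon once
    if kind is None:
        raise UnresolvedAttractorError(
            f"attractor unresolved after t={t_max:g}: per-component range between "
            f"{FIXED_POINT_RANGE:g} and {LIMIT_CYCLE_RANGE:g}"
        )
    comps = xs.mean(axis=0)
    mu = _growth_rates(xs, x_med, net, cfg)
    r = np.asarray(volumes) / np.sum(volumes)
    differentiated = False
    if len(volumes) == 2:
        differentiated = bool(np.abs(comps[0] - comps[1]).sum() > cfg.diff_threshold)
    return ReducedResult(
        attractor_kind=kind,
        compositions=comps,
        mu=mu,
        mu_tot=float((r * mu).sum()),
        differentiated=differentiated,
        volumes=np.asarray(volumes, dtype=float),
        times=times if keep_trajectory else None,
        trajectory=xs if keep_trajectory else None,
        medium=x_med if keep_trajectory else None,
    )


def _uniform(k):
    return np.full(k, 1.0 / k)


def _split_initial(net, cfg, init_split):
    """Initial compositions of the two groups.

    ``"small"``: uniform compositions with a relative perturbation of
    ``cfg.split_size`` applied antisymmetrically to chemicals 1 and 2 —
    probes spontaneous instability of the homogeneous state.
    ``"large"``: group 1 concentrated on {X1, X3} and group 2 on {X2, X4} —
    probes the basin of the differentiated state (bistable phase IV).
    A float is treated as a custom small-split amplitude.
    """
    k = net.k
    if isinstance(init_split, str) and init_split == "large":
        x1 = np.full(k, 0.1 / (k - 2))
        x2 = x1.copy()
        x1[1] = x1[3] = 0.45
        x2[2] = x2[4] = 0.45
        return np.array([x1 / x1.sum(), x2 / x2.sum()])
    delta = cfg.split_size if init_split == "small" else float(init_split)
    base = _uniform(k)
    x1 = base.copy()
    x2 = base.copy()
    x1[1] *= 1 + delta
    x1[2] *= 1 - delta
    x2[1] *= 1 - delta
    x2[2] *= 1 + delta
    return np.array([x1 / x1.sum(), x2 / x2.sum()])


def run_r1cell(net: CatalyticNetwork, cfg: ReducedConfig, keep_trajectory=False):
    """Isolated cell with pinned volume; mu averaged over the final window.

    The initial composition is the uniform simplex point with a small
    antisymmetric perturbation on chemicals 1 and 2: the 1<->2 / 3<->4
    exchange symmetry of the built-in networks makes the symmetric subspace
    dynamically invariant, and an exactly symmetric start would never leave
    it even when the attractor (e.g. a limit cycle) lives off it.
    """
    x0 = _uniform(net.k)
    if net.k > 2:
        x0 = x0.copy()
        x0[1] *= 1 + cfg.split_size
        x0[2] *= 1 - cfg.split_size
        x0 /= x0.sum()
    return _run(net, cfg, [x0], [1.0], keep_trajectory)


def run_r2cell(net, cfg, init_split="small", keep_trajectory=False):
    """Two symmetric cell groups sharing the medium (r1 = 1/2 by default)."""
    x0 = _split_initial(net, cfg, init_split)
    volumes = [cfg.r1, 1.0 - cfg.r1]
    return _run(net, cfg, x0, volumes, keep_trajectory)


def run_fixed_ratio(net, cfg, keep_trajectory=False):
    """Two differentiated groups at a fixed volume ratio r1 : 1-r1.

    Group 1 starts at the type-1-like composition (concentrated on X1, X3)
    and group 2 at the type-2-like one, so the run tracks the differentiated
    branch; mu[0] is F(r1) and mu[1] is G(1-r1).
    """
    x0 = _split_initial(net, cfg, "large")
    volumes = [cfg.r1, 1.0 - cfg.r1]
    return _run(net, cfg, x0, volumes, keep_trajectory)


def _with_r1(cfg: ReducedConfig, r1: float) -> ReducedConfig:
    import dataclasses

    return dataclasses.replace(cfg, r1=r1)


def growth_curve_F(net, cfg, r_grid) -> pd.DataFrame:
    """Growth rates of both differentiated groups across a volume-ratio grid.

    Returns a table with columns (r1, mu1, mu2, mu_tot, mu_iso); mu1 traces
    the curve F(r1). Individual grid failures are recorded as NaN rows.
    """
    iso = run_r1cell(net, cfg)
    rows = []
    for r in r_grid:
        if not 0.0 < r < 1.0:
            raise ValueError(f"grid ratio {r} outside (0, 1)")
        try:
            res = run_fixed_ratio(net, _with_r1(cfg, r))
            rows.append((r, res.mu[0], res.mu[1], res.mu_tot, float(iso.mu[0])))
        except (RuntimeError, ValueError):
            rows.append((r, np.nan, np.nan, np.nan, float(iso.mu[0])))
    return pd.DataFrame(rows, columns=["r1", "mu1", "mu2", "mu_tot", "mu_iso"])


def coexistence_drift(F_table: pd.DataFrame) -> Callable[[float], float]:
    """Replicator-style drift of the type-1 volume fraction.

    dr/dt = r (1 - r) [F(r) - F(1 - r)], built by interpolating the mu1
    column of a growth-curve table whose grid contains each mirrored pair
    (r, 1-r). Fixed points at r in {0, 1/2, 1} for symmetric networks.
    """
    r = np.asarray(F_table["r1"], dtype=float)
    mirrored = np.isclose(np.sort(r), np.sort(1.0 - r))
    if not mirrored.all():
        raise ValueError("grid is not symmetric under r -> 1-r; cannot form F(1-r)")
    order = np.argsort(r)
    r_sorted = r[order]
    f_sorted = np.asarray(F_table["mu1"], dtype=float)[order]

    def drift(r1: float) -> float:
        if r1 <= 0.0 or r1 >= 1.0:
            return 0.0
        F = np.interp(r1, r_sorted, f_sorted)
        F_mirror = np.interp(1.0 - r1, r_sorted, f_sorted)
        return r1 * (1.0 - r1) * (F - F_mirror)

    return drift


@dataclass
class StabilityIndex:
    """Finite-difference estimate of F'(1/2) and its interpretation."""

    slope: float
    slope_refined: float
    delta: float
    defined: bool = True
    sign_stable: bool = True
    note: str = ""

    @property
    def stable(self) -> Optional[bool]:
        """True if balanced coexistence of the two types is stable."""
        if not self.defined:
            return None
        return self.slope < 0


def stability_index(net, cfg, delta: float = 0.05) -> StabilityIndex:
    """Central-difference slope of F at the symmetric point r1 = 1/2.

    A positive slope means the majority type outgrows the minority, so the
    balanced fixed point of the volume-fraction drift is unstable; negative
    means coexistence is self-correcting. The sign is confirmed at delta/2.
    """
    if not 0.0 < delta < 0.5:
        raise ValueError("delta must lie in (0, 1/2)")

    def F(r):
        res = run_fixed_ratio(net, _with_r1(cfg, r))
        if not res.differentiated:
            raise UnresolvedAttractorError(
                f"groups not differentiated at r1={r}: F undefined"
            )
        return float(res.mu[0])

    try:
        slope = (F(0.5 + delta) - F(0.5 - delta)) / (2 * delta)
        half = delta / 2
        slope_refined = (F(0.5 + half) - F(0.5 - half)) / (2 * half)
    except UnresolvedAttractorError as exc:
        return StabilityIndex(np.nan, np.nan, delta, defined=False, note=str(exc))
    return StabilityIndex(
        slope=slope,
        slope_refined=slope_refined,
        delta=delta,
        sign_stable=bool(np.sign(slope) == np.sign(slope_refined)),
    )


def classify_phase(net, C, V, D, **cfg_kwargs) -> str:
    """Phase of the reduced models at (C, V, D).

    I   : isolated cell at a fixed point, two groups never differentiate.
    II  : isolated fixed point; two groups differentiate from a small split
          (pitchfork to two distinct fixed points).
    III : isolated cell oscillates; two groups reach distinct fixed points
          from a small split (oscillation death).
    IV  : isolated cell oscillates; differentiation only from a large split,
          while a small split stays synchronized (bistability).
    """
    cfg = ReducedConfig(C=C, V=V, D=D, **cfg_kwargs)
    if D == 0:
        return "I"
    iso = run_r1cell(net, cfg)
    small = run_r2cell(net, cfg, init_split="small")
    if iso.attractor_kind == "fixed_point":
        return "II" if small.differentiated else "I"
    if small.differentiated:
        return "III"
    large = run_r2cell(net, cfg, init_split="large")
    return "IV" if large.differentiated else "I"
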