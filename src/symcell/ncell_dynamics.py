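"""The full N-cell model: growing, dividing cells in a shared medium.

Each cell carries a concentration vector on the unit simplex and a volume.
Intracellular catalytic reactions convert the nutrient into other species;
diffusible species are exchanged with a well-mixed medium of fixed volume,
and the net influx defines the growth rate mu. A cell divides when its
volume doubles; when the population exceeds the carrying capacity N,
surplus cells are eliminated uniformly at random.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from ._kinetics import make_flat_rhs, pack, population_rhs, unpack
from .networks import CatalyticNetwork

__all__ = [
    "CellState",
    "MediumState",
    "SimConfig",
    "PopulationState",
    "NCellTrajectory",
    "IntegrationFailure",
    "intracellular_derivative",
    "medium_derivative",
    "step_population",
    "run_ncell",
]


class IntegrationFailure(RuntimeError):
    pass


@dataclass
class CellState:
    """One cell: simplex concentration vector, volume, and lineage info.

    ``divisions`` counts the divisions along this cell's ancestry line; the
    population mean of this counter is the divisions-per-cell series.
    """

    x: np.ndarray
    v: float = 1.0
    v_birth: float = 1.0
    id: int = 0
    parent_id: Optional[int] = None
    divisions: int = 0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)


@dataclass
class MediumState:
    """Shared-medium concentrations and its (constant) volume."""

    x_med: np.ndarray
    V_med: float

    def __post_init__(self):
        self.x_med = np.asarray(self.x_med, dtype=float)


@dataclass
class SimConfig:
    """Parameters of an N-cell run.

    N : carrying capacity (max cells in the medium)
    C : nutrient concentration in the medium's exterior
    V_med : medium volume
    D : diffusion coefficient between cells and the medium
    D_med : diffusion coefficient between medium and exterior (defaults to D)
    division_noise : relative amplitude of the multiplicative composition
        perturbation applied to daughters at division; symmetry breaking
        needs a nonzero value, and 1e-6 is far below any composition scale.
    chunk_dt : integration chunk between division/elimination checks.
    """

    N: int = 100
    C: float = 0.15
    V_med: float = 100.0
    D: float = 1.0
    D_med: Optional[float] = None
    t_max: float = 1e4
    record_interval: float = 10.0
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    seed: int = 0
    division_noise: float = 1e-6
    chunk_dt: float = 1.0

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be at least 1")
        if self.C < 0 or self.D < 0 or (self.D_med is not None and self.D_med < 0):
            raise ValueError("C, D, D_med must be non-negative")
        if self.V_med <= 0:
            raise ValueError("V_med must be positive")
        if self.division_noise < 0:
            raise ValueError("division_noise must be non-negative")

    @property
    def d_med(self) -> float:
        return self.D if self.D_med is None else self.D_med


@dataclass
class PopulationState:
    cells: list
    medium: MediumState
    t: float = 0.0
    next_id: int = 1


@dataclass
class NCellTrajectory:
    """Recorded N-cell time series plus division/elimination bookkeeping."""

    times: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)  # (list[CellState], MediumState)
    division_events: list = field(default_factory=list)  # (t, parent, d1, d2)
    elimination_events: list = field(default_factory=list)  # (t, cell id)
    division_counts: list = field(default_factory=list)  # mean lineage divisions per cell
    populations: list = field(default_factory=list)
    clipped_mass: float = 0.0

    def concentration_array(self, idx: int) -> np.ndarray:
        """Stack of cell concentration matrices at snapshot ``idx``."""
        cells, _ = self.snapshots[idx]
        return np.array([c.x for c in cells])


def _check_lengths(cell: CellState, medium: MediumState, net: CatalyticNetwork):
    if len(cell.x) != net.k or len(medium.x_med) != net.k:
        raise ValueError(
            f"length mismatch: cell has {len(cell.x)}, medium {len(medium.x_med)}, "
            f"network k={net.k}"
        )


def intracellular_derivative(cell, medium, net, cfg):
    """dx/dt for one cell (reactions + influx − dilution) and its growth rate."""
    _check_lengths(cell, medium, net)
    x = np.atleast_2d(cell.x)
    v = np.array([cell.v])
    dx, _dv, _dm, mu = population_rhs(
        x, v, medium.x_med, net, cfg.D, cfg.d_med, cfg.C, medium.V_med
    )
    return dx[0], float(mu[0])

def medium_derivative(cells, medium, net, cfg):
    """dx_med/dt: exterior nutrient supply minus net uptake by all cells."""
    if not cells:
        d = np.zeros(net.k)
        d[0] = cfg.d_med * (cfg.C - medium.x_med[0])
        return d
    x = np.array([c.x for c in cells])
    v = np.array([c.v for c in cells])
    _dx, _dv, dm, _mu = population_rhs(
        x, v, medium.x_med, net, cfg.D, cfg.d_med, cfg.C, medium.V_med
    )
    return dm


def _divide(cell: CellState, noise: float, rng, next_id: int):
    """Split a doubled cell into two equal-volume daughters.

    Each daughter's composition is the parent's multiplied component-wise by
    (1 + noise*u), u ~ U[-1, 1], then renormalised to the simplex.
    """
    daughters = []
    for _ in range(2):
        x = cell.x.copy()
        if noise > 0:
            x = x * (1.0 + noise * rng.uniform(-1.0, 1.0, size=len(x)))
            x = np.clip(x, 0.0, None)
            x /= x.sum()
        daughters.append(
            CellState(
                x=x,
                v=cell.v / 2,
                v_birth=cell.v / 2,
                id=next_id,
                parent_id=cell.id,
                divisions=cell.divisions + 1,
            )
        )
        next_id += 1
    return daughters, next_id


def step_population(state, net, cfg, dt, rng):
    """Advance cells + medium by ``dt``; apply divisions and eliminations.

    Divisions are located by the solver's event detection (a cell divides
    the moment its volume reaches twice its birth volume); locating them
    exactly matters because any systematic overshoot would compound into an
    upward drift of birth volumes across generations, inflating the total
    cellular volume. The carrying capacity is enforced immediately after
    each division. Returns ``(state, divisions, eliminations, clipped)``
    where the event lists hold ``(t, parent, d1, d2)`` and ``(t, cell_id)``
    tuples and ``clipped`` is the negative-concentration mass floored to 0.
    """
    k = net.k
    t_end = state.t + dt
    divisions = []
    eliminations = []
    clipped = 0.0
    while state.t < t_end - 1e-12:
        n = len(state.cells)
        x = np.array([c.x for c in state.cells])
        v = np.array([c.v for c in state.cells])
        v_div = 2.0 * np.array([c.v_birth for c in state.cells])
        y0 = pack(x, v, state.medium.x_med)
        rhs = make_flat_rhs(net, cfg.D, cfg.d_med, cfg.C, state.medium.V_med, n)

        def doubling(_t, y, _vd=v_div, _n=n, _k=k):
            return float(np.max(y[_n * _k : _n * _k + _n] - _vd))

        doubling.terminal = True
        doubling.direction = 1.0
        sol = solve_ivp(
            rhs,
            (state.t, t_end),
            y0,
            method=cfg.method,
            rtol=cfg.rtol,
            atol=cfg.atol,
            events=doubling,
        )
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            bad = "state non-finite" if sol.success else sol.message
            raise IntegrationFailure(f"integration failed at t={state.t:.6g}: {bad}")
        x, v, x_med = unpack(sol.y[:, -1], n, k)
        clipped += float(-x[x < 0].sum()) + float(-x_med[x_med < 0].sum())
        x = np.clip(x, 0.0, None)
        state.medium.x_med = np.clip(x_med, 0.0, None)
        for cell, xi, vi in zip(state.cells, x, v):
            cell.x = xi
            cell.v = float(vi)
        state.t = float(sol.t[-1])

        new_cells = []
        divided = False
        for cell in state.cells:
            if cell.v >= 2.0 * cell.v_birth * (1.0 - 1e-12):
                daughters, state.next_id = _divide(
                    cell, cfg.division_noise, rng, state.next_id
                )
                divisions.append((state.t, cell.id, daughters[0].id, daughters[1].id))
                new_cells.extend(daughters)
                divided = True
            else:
                new_cells.append(cell)
        state.cells = new_cells
        while len(state.cells) > cfg.N:
            victim = rng.integers(len(state.cells))
            eliminations.append((state.t, state.cells[victim].id))
            del state.cells[victim]
        if not divided and state.t < t_end - 1e-12:
            # terminal event fired without an actual crossing; avoid stalling
            raise IntegrationFailure(
                f"division event at t={state.t:.6g} located no doubled cell"
            )
    return state, divisions, eliminations, clipped


def run_ncell(net: CatalyticNetwork, cfg: SimConfig) -> NCellTrajectory:
    """Run the N-cell model from a single founder cell.

    The founder has a uniform-Dirichlet composition on the simplex (seeded),
    unit volume, and the medium starts empty (the nutrient fills through the
    exterior supply term). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    x0 = rng.dirichlet(np.ones(net.k))
    founder = CellState(x=x0, v=1.0, v_birth=1.0, id=0, parent_id=None)
    state = PopulationState(
        cells=[founder],
        medium=MediumState(x_med=np.zeros(net.k), V_med=cfg.V_med),
    )
    traj = NCellTrajectory()
    next_record = 0.0

    def record():
        traj.times.append(state.t)
        traj.snapshots.append(
            ([copy.deepcopy(c) for c in state.cells], copy.deepcopy(state.medium))
        )
        traj.populations.append(len(state.cells))
        traj.division_counts.append(
            float(np.mean([c.divisions for c in state.cells]))
        )

    record()
    next_record = cfg.record_interval
    while state.t < cfg.t_max - 1e-12:
        dt = min(cfg.chunk_dt, cfg.t_max - state.t)
        state, divs, elims, clipped = step_population(state, net, cfg, dt, rng)
        traj.division_events.extend(divs)
        traj.elimination_events.extend(elims)
        traj.clipped_mass += clipped
        if state.t >= next_record - 1e-9:
            record()
            next_record += cfg.record_interval
    return traj
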