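"""Catalytic reaction networks shared by all cells.

A network is a set of catalysed conversions ``X_i + a*X_l -> X_j + a*X_l``
over ``k`` chemical species, together with a membrane-diffusibility flag per
species. Chemical 0 is the nutrient: it is the only species supplied from
outside the medium, and it is never produced or used as a catalyst.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Reaction",
    "CatalyticNetwork",
    "generate_random_network",
    "build_network_1",
    "build_network_2",
    "validate_network",
    "save_network",
    "load_network",
    "InfeasibleEnsembleError",
]


class InfeasibleEnsembleError(ValueError):
    """Raised when the requested random ensemble cannot be sampled."""


@dataclass(frozen=True, order=True)
class Reaction:
    """One catalysed conversion ``X_substrate -> X_product`` by ``X_catalyst``.

    The reaction proceeds at rate ``rate_constant * x_substrate * x_catalyst**alpha``
    where ``alpha`` is the catalytic order stored on the network.
    """

    substrate: int
    product: int
    catalyst: int
    rate_constant: float = 1.0


@dataclass
class CatalyticNetwork:
    """Reaction topology plus diffusibility flags, shared by every cell.

    Attributes
    ----------
    k : int
        Number of chemical species; species 0 is the nutrient.
    reactions : tuple of Reaction
    diffusible : ndarray of 0/1, length k
        ``diffusible[i] == 1`` iff ``X_i`` crosses the cell membrane.
    alpha : float
        Order of the catalytic reactions (default 2).
    """

    k: int
    reactions: tuple
    diffusible: np.ndarray
    alpha: float = 2.0
    _arrays: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.reactions = tuple(self.reactions)
        self.diffusible = np.asarray(self.diffusible, dtype=float)

    def reaction_arrays(self):
        """Vectorised view (substrates, products, catalysts, rate constants)."""
        if not self._arrays:
            sub = np.array([r.substrate for r in self.reactions], dtype=int)
            prod = np.array([r.product for r in self.reactions], dtype=int)
            cat = np.array([r.catalyst for r in self.reactions], dtype=int)
            eps = np.array([r.rate_constant for r in self.reactions], dtype=float)
            # stoichiometry matrix mapping per-reaction rates to d x / dt
            stoich = np.zeros((len(self.reactions), self.k))
            for row, (i, j) in enumerate(zip(sub, prod)):
                stoich[row, i] -= 1.0
                stoich[row, j] += 1.0
            self._arrays.update(sub=sub, prod=prod, cat=cat, eps=eps, stoich=stoich)
        a = self._arrays
        return a["sub"], a["prod"], a["cat"], a["eps"], a["stoich"]

    def __eq__(self, other):
        if not isinstance(other, CatalyticNetwork):
            return NotImplemented
        return (
            self.k == other.k
            and self.alpha == other.alpha
            and sorted(self.reactions) == sorted(other.reactions)
            and np.array_equal(self.diffusible, other.diffusible)
        )


def validate_network(net: CatalyticNetwork) -> list:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    problems = []
    if net.k < 2:
        problems.append(f"k={net.k} too small: need at least the nutrient and one product")
    if len(net.diffusible) != net.k:
        problems.append(
            f"diffusible vector has length {len(net.diffusible)}, expected k={net.k}"
        )
    elif net.diffusible[0] != 1:
        problems.append("nutrient X_0 must be diffusible (sigma_0 = 1)")
    seen = set()
    for r in net.reactions:
        triple = (r.substrate, r.product, r.catalyst)
        if not all(0 <= idx < net.k for idx in triple):
            problems.append(f"reaction {triple} has an index outside [0, {net.k})")
            continue
        if r.substrate == r.product:
            problems.append(f"reaction {triple}: substrate equals product")
        if r.product == r.catalyst:
            problems.append(f"reaction {triple}: autocatalytic (product is its own catalyst)")
        if r.product == 0:
            problems.append(f"reaction {triple}: nutrient cannot be a product")
        if r.catalyst == 0:
            problems.append(f"reaction {triple}: nutrient cannot be a catalyst")
        if triple in seen:
            problems.append(f"duplicate reaction {triple}")
        seen.add(triple)
    return problems


def generate_random_network(
    k: int,
    rho: int,
    p_diff: float,
    seed,
    alpha: float = 2.0,
    epsilon: float = 1.0,
) -> CatalyticNetwork:
    """Sample a random catalytic network from the study ensemble.

    Every chemical (the nutrient included) is the substrate of exactly ``rho``
    reactions; for each, the (product, catalyst) pair is drawn uniformly
    without replacement among pairs satisfying product != substrate,
    product != catalyst, and neither product nor catalyst being the nutrient.
    Each non-nutrient chemical is independently diffusible with probability
    ``p_diff``; the nutrient is always diffusible.

    Parameters mirror the published ensemble: ``k=20``, ``rho=4``,
    ``p_diff=0.15``.
    """
    if k < 3:
        raise InfeasibleEnsembleError(f"k={k} leaves no valid (product, catalyst) pair")
    if rho < 1:
        raise ValueError("rho must be at least 1")
    if not 0.0 <= p_diff <= 1.0:
        raise ValueError("p_diff must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    reactions = []
    for i in range(k):
        pairs = [
            (j, l)
            for j in range(1, k)
            for l in range(1, k)
            if j != i and j != l
        ]
        if len(pairs) < rho:
            raise InfeasibleEnsembleError(
                f"substrate {i}: only {len(pairs)} valid (product, catalyst) pairs "
                f"but rho={rho} requested"
            )
        chosen = rng.choice(len(pairs), size=rho, replace=False)
        for idx in sorted(chosen):
            j, l = pairs[idx]
            reactions.append(Reaction(i, j, l, epsilon))
    sigma = np.zeros(k)
    sigma[0] = 1.0
    sigma[1:] = (rng.random(k - 1) < p_diff).astype(float)
    net = CatalyticNetwork(k=k, reactions=tuple(reactions), diffusible=sigma, alpha=alpha)
    assert not validate_network(net)
    return net


def build_network_1(alpha: float = 2.0) -> CatalyticNetwork:
    """Six-species cross-feeding network with X_5 non-diffusible.

    The nutrient X_0 feeds four reactions: it is converted to X_3 (catalysed
    by X_1), to X_4 (by X_2), to X_1 (by X_4) and to X_2 (by X_3). Two
    mutually repressive reactions X_1 -> X_5 (by X_2) and X_2 -> X_5 (by X_1)
    form a double-negative feedback loop. Diffusible species: X_0, X_3, X_4.
    Under differentiation, type-1 cells accumulate {X_1, X_3} and type-2
    cells {X_2, X_4}; each type's diffusible product catalyses the other
    type's nutrient uptake, so the two types cross-feed.
    """
    reactions = (
        Reaction(0, 3, 1),
        Reaction(0, 4, 2),
        Reaction(0, 1, 4),
        Reaction(0, 2, 3),
        Reaction(1, 5, 2),
        Reaction(2, 5, 1),
    )
    sigma = np.array([1.0, 0.0, 0.0, 1.0, 1.0, 0.0])
    return CatalyticNetwork(k=6, reactions=reactions, diffusible=sigma, alpha=alpha)


def build_network_2(alpha: float = 2.0) -> CatalyticNetwork:
    """Same topology as network 1 but with X_5 diffusible.

    The single changed diffusibility flag flips the coexistence of the two
    differentiated types from unstable to stable.
    """
    net = build_network_1(alpha=alpha)
    sigma = net.diffusible.copy()
    sigma[5] = 1.0
    return CatalyticNetwork(k=net.k, reactions=net.reactions, diffusible=sigma, alpha=alpha)


def save_network(net: CatalyticNetwork, path) -> None:
    """Write a network to its plain-text format (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_dumps(net))


def _dumps(net: CatalyticNetwork) -> str:
    buf = io.StringIO()
    buf.write(f"k={net.k}\n")
    buf.write(f"alpha={net.alpha!r}\n")
    flags = ",".join(str(int(s)) for s in net.diffusible)
    buf.write(f"diffusible={flags}\n")
    for r in net.reactions:
        buf.write(f"{r.substrate} {r.product} {r.catalyst} {r.rate_constant!r}\n")
    return buf.getvalue()


def load_network(path) -> CatalyticNetwork:
    """Read a network from the plain-text format written by :func:`save_network`."""
    header = {}
    reactions = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                header[key.strip()] = value.strip()
            else:
                i, j, l, eps = line.split()
                reactions.append(Reaction(int(i), int(j), int(l), float(eps)))
    try:
        k = int(header["k"])
        alpha = float(header["alpha"])
        sigma = np.array([float(s) for s in header["diffusible"].split(",")])
    except KeyError as exc:
        raise ValueError(f"network file missing header line for {exc}") from exc
    return CatalyticNetwork(k=k, reactions=tuple(reactions), diffusible=sigma, alpha=alpha)
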