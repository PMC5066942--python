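"""Closed-form estimates for the growth advantage of division of labor.

These are assumption-laden back-of-envelope results (uniform concentration
across non-nutrient species, steady state, equal nutrient level in isolated
and differentiated cells). They are deliberately pure functions with no
simulation dependency so they cannot be mistaken for simulated quantities.
"""

from __future__ import annotations

__all__ = ["estimated_growth_rate", "theoretical_R_mu", "specialization_gain"]


def estimated_growth_rate(x0: float, k: int, q_paths: int, alpha: float) -> float:
    """Steady-state growth rate of a cell using a k-species network.

    Assumes the non-nutrient mass (1 - x0) is spread evenly over the k - 1
    non-nutrient species, each of the ``q_paths`` nutrient-consuming
    reactions runs at x0 * x**alpha with x = (1 - x0)/(k - 1), and the
    nutrient balance fixes the normalisation 1/(1 + x0).
    """
    if not 0.0 <= x0 < 1.0:
        raise ValueError(f"x0 must lie in [0, 1), got {x0}")
    if k < 2:
        raise ValueError("k must be at least 2")
    x = (1.0 - x0) / (k - 1)
    return q_paths * x0 * x**alpha / (1.0 + x0)


def theoretical_R_mu(
    k: int, q_paths: int, k_prime: int, q_prime: int, alpha: float
) -> float:
    """Estimated ratio of differentiated to isolated growth rate.

    R_mu = (q'/q) * [(k-1)/(k'-1)]**alpha for a differentiated cell running
    a sub-network of k' species and q' nutrient paths, assuming the nutrient
    concentration is the same in both states. Greater than 1 for the
    six-species cross-feeding network (k=6, q=4, k'=4, q'=2) when alpha >= 2:
    concentrating mass on fewer species outweighs losing half the paths.
    """
    if k < 2 or k_prime < 2:
        raise ValueError("k and k_prime must be at least 2")
    return (q_prime / q_paths) * ((k - 1) / (k_prime - 1)) ** alpha


def specialization_gain(alpha: float) -> float:
    """Production gain of full specialisation over a generalist cell.

    Two symmetric nutrient-consuming reactions with total catalyst budget c:
    a generalist (c/2 each) produces 2*x0*(c/2)**alpha in total, a pair of
    specialists (c on one catalyst each) produces x0*c**alpha per cell. The
    ratio is 2**(alpha-1), independent of x0 and c — no advantage at linear
    kinetics, factor 2 at alpha = 2.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return 2.0 ** (alpha - 1.0)
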