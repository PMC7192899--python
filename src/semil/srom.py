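"""Stochastic reduced-order models: sparse discrete approximation of a
continuous input distribution.

Output data are only available at a handful of fixed input values
``{x_i}`` (the concentrations actually pipetted in the experiment), so each
continuous input distribution in the design space must be replaced by
probability masses ``P_i`` on that fixed support.  The best masses minimise

    J(P) = integral over u in [0,1] of (F_cont(u) - F_disc(u))^2 du
           + w * sum_r (m_r(cont) - m_r(disc))^2

the squared CDF mismatch plus the squared mismatch of the first raw moments,
everything computed in the normalised log coordinate u so both terms are
dimensionless and O(1).  The discrete CDF is the right-continuous step
function of the masses.  The problem is a small convex QP on the probability
simplex; it is solved deterministically with SLSQP from a fixed
cell-probability initialisation, so no randomness enters the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .design_space import ContinuousInputDistribution

DEFAULT_MOMENT_ORDERS: tuple[int, ...] = (1, 2)
DEFAULT_QUAD_NODES = 1000


class SromFitError(RuntimeError):
    """Optimizer failed to converge; carries the final objective value."""

    def __init__(self, message: str, objective: float):
        super().__init__(f"{message} (objective={objective:.6g})")
        self.objective = objective


@dataclass(frozen=True)
class SupportSet:
    """Sorted distinct input concentrations at which output data exist."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or len(v) == 0:
            raise ValueError("support must be a non-empty 1-D array")
        if np.any(np.diff(v) <= 0):
            raise ValueError("support values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def log_spaced(cls, x_lo: float, x_hi: float, n: int) -> "SupportSet":
        return cls(np.geomspace(x_lo, x_hi, n))


@dataclass(frozen=True)
class DiscreteInputDistribution:
    """Probability masses on a fixed support; always on the simplex."""

    support: SupportSet
    masses: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", p)
        if p.shape != self.support.values.shape:
            raise ValueError("masses and support sizes differ")
        if np.any(p < -1e-12):
            raise ValueError("negative probability mass")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"masses sum to {p.sum()}, not 1")

    def unit_positions(self, bounds) -> np.ndarray:
        return bounds.to_unit(self.support.values)

    def entropy_bits(self) -> float:
        p = self.masses[self.masses > 0]
        return float(-(p * np.log2(p)).sum())


def _quad_nodes(n_nodes: int) -> np.ndarray:
    # midpoint rule on [0, 1]
    return (np.arange(n_nodes) + 0.5) / n_nodes


def cdf_error(
    cont: ContinuousInputDistribution,
    disc: DiscreteInputDistribution,
    n_nodes: int = DEFAULT_QUAD_NODES,
) -> float:
    """Integrated squared CDF mismatch in the normalised log coordinate."""
    u_nodes = _quad_nodes(n_nodes)
    F_cont = cont.unit_cdf(u_nodes)
    u_i = cont.bounds.to_unit(disc.support.values)
    step = u_nodes[:, None] >= u_i[None, :] - 1e-15
    F_disc = step @ disc.masses
    return float(np.mean((F_cont - F_disc) ** 2))


def moment_error(
    cont: ContinuousInputDistribution,
    disc: DiscreteInputDistribution,
    orders: tuple[int, ...] = DEFAULT_MOMENT_ORDERS,
) -> float:
    """Sum of squared raw-moment mismatches of the normalised log coordinate."""
    if len(orders) == 0:
        raise ValueError("orders must be non-empty")
    u_i = cont.bounds.to_unit(disc.support.values)
    err = 0.0
    for r in orders:
        m_cont = cont.unit_moment(r)
        m_disc = float(np.dot(disc.masses, u_i**r))
        err += (m_cont - m_disc) ** 2
    return err


def _objective_pieces(cont, support, orders, n_nodes):
    """Precompute the linear operators of the quadratic objective."""
    u_nodes = _quad_nodes(n_nodes)
    F_cont = cont.unit_cdf(u_nodes)
    u_i = cont.bounds.to_unit(support.values)
    A = (u_nodes[:, None] >= u_i[None, :] - 1e-15).astype(float)
    U = np.stack([u_i**r for r in orders])  # (n_orders, n_support)
    m_cont = np.array([cont.unit_moment(r) for r in orders])
    return F_cont, A, U, m_cont


def fit_discrete(
    cont: ContinuousInputDistribution,
    support: SupportSet,
    weight: float = 1.0,
    orders: tuple[int, ...] = DEFAULT_MOMENT_ORDERS,
    n_nodes: int = DEFAULT_QUAD_NODES,
) -> DiscreteInputDistribution:
    """Best discrete approximation of ``cont`` on the fixed support.

    Minimises ``cdf_error + weight * moment_error`` over the probability
    simplex.  Initialisation is the deterministic cell-probability vector
    (continuous CDF differenced at the log-midpoints between support
    points), which already sits on the simplex; the returned masses never
    have a larger objective than that initialisation.
    """
    if len(support) < 2:
        raise ValueError("support must contain at least 2 points")
    F_cont, A, U, m_cont = _objective_pieces(cont, support, orders, n_nodes)
    n = len(support)

    def objective(p):
        r_cdf = A @ p - F_cont
        r_mom = U @ p - m_cont
        return float(np.mean(r_cdf**2) + weight * np.dot(r_mom, r_mom))

    def gradient(p):
        r_cdf = A @ p - F_cont
        r_mom = U @ p - m_cont
        return (2.0 / len(F_cont)) * (A.T @ r_cdf) + 2.0 * weight * (U.T @ r_mom)

    # cell-probability initialisation: difference the CDF at support midpoints
    u_i = cont.bounds.to_unit(support.values)
    mids = np.concatenate(([0.0], (u_i[1:] + u_i[:-1]) / 2.0, [1.0]))
    p0 = np.diff(cont.unit_cdf(mids))
    p0 = np.clip(p0, 0.0, None)
    p0 = p0 / p0.sum() if p0.sum() > 0 else np.full(n, 1.0 / n)

    res = minimize(
        objective,
        p0,
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0,
                      "jac": lambda p: np.ones_like(p)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    p = np.clip(res.x, 0.0, None)
    total = p.sum()
    if not res.success and (total <= 0 or not np.isfinite(total)):
        raise SromFitError("SROM optimisation failed", float(res.fun))
    p = p / total
    # keep the monotonicity guarantee: never return worse than the start
    if objective(p) > objective(p0):
        if not res.success:
            raise SromFitError("SROM optimisation did not improve", objective(p))
        p = p0
    return DiscreteInputDistribution(support, p)
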