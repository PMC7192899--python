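"""Design space of bounded input probability distributions.

The design space is the family of continuous probability distributions of the
input stimulus over which a mutual information landscape is evaluated.  Each
member is a beta distribution in the normalised log coordinate

    u = log10(x / x_min) / log10(x_max / x_min),   u in [0, 1],

so the density of the input concentration ``x`` itself is

    p(x) = rho_beta(u; alpha, beta) / (x * ln(x_max / x_min)).

This family contains the log-uniform distribution (alpha = beta = 1),
unimodal distributions (alpha, beta > 1) and antimodal ones
(alpha, beta < 1), all on the same bounded support.

Landscape coordinates are the geometric mean ``E`` and geometric standard
deviation ``sigma`` of the input; both are matched exactly to the first two
moments of the beta distribution in log10 space, which makes the
(E, sigma) -> (alpha, beta) map closed-form and invertible.  A pair
(E, sigma) is *feasible* when the implied log-scale variance is below the
maximum a beta distribution on a bounded interval can carry,
``s^2 < m (1 - m)`` with ``m`` the normalised log-mean and ``s`` the
normalised log-SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class InfeasibleDistributionError(ValueError):
    """Raised when (E, sigma) cannot be realised by a log-beta distribution."""


@dataclass(frozen=True)
class InputBounds:
    """Closed interval of admissible input concentrations, 0 < x_min < x_max."""

    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if not (0.0 < self.x_min < self.x_max):
            raise ValueError(
                f"require 0 < x_min < x_max, got ({self.x_min}, {self.x_max})"
            )

    @property
    def log10_span(self) -> float:
        """L = log10(x_max / x_min), the width of the interval in decades."""
        return math.log10(self.x_max / self.x_min)

    def to_unit(self, x):
        """Map a concentration to the normalised log coordinate u in [0, 1]."""
        return np.log10(np.asarray(x, dtype=float) / self.x_min) / self.log10_span

    def from_unit(self, u):
        """Inverse of :meth:`to_unit`."""
        return self.x_min * 10.0 ** (np.asarray(u, dtype=float) * self.log10_span)


@dataclass(frozen=True)
class ContinuousInputDistribution:
    """A log-transformed beta distribution of the input concentration."""

    bounds: InputBounds
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("beta shape parameters must be positive")

    # -- densities -------------------------------------------------------

    def pdf(self, x):
        """Probability density per unit input concentration.

        Zero outside [x_min, x_max]; non-positive ``x`` is a domain error.
        """
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("input concentration must be positive")
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.zeros_like(x)
        inside = (x >= self.bounds.x_min) & (x <= self.bounds.x_max)
        if np.any(inside):
            u = self.bounds.to_unit(x[inside])
            rho = stats.beta.pdf(u, self.alpha, self.beta)
            out[inside] = rho / (
                x[inside] * math.log(self.bounds.x_max / self.bounds.x_min)
            )
        return out[0] if scalar else out

    def cdf(self, x):
        """Cumulative probability; 0 below x_min, 1 above x_max."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.zeros_like(x)
        out[x >= self.bounds.x_max] = 1.0
        inside = (x > self.bounds.x_min) & (x < self.bounds.x_max)
        if np.any(inside):
            u = self.bounds.to_unit(x[inside])
            out[inside] = stats.beta.cdf(u, self.alpha, self.beta)
        return out[0] if scalar else out

    def unit_pdf(self, u):
        """Beta density in the normalised log coordinate."""
        return stats.beta.pdf(u, self.alpha, self.beta)

    def unit_cdf(self, u):
        """Beta CDF in the normalised log coordinate."""
        return stats.beta.cdf(u, self.alpha, self.beta)

    def unit_ppf(self, q):
        """Beta quantile function in the normalised log coordinate."""
        return stats.beta.ppf(q, self.alpha, self.beta)

    def unit_moment(self, order: int) -> float:
        """Raw moment E[u^order] of the normalised log coordinate."""
        return float(stats.beta.moment(order, self.alpha, self.beta))

    # -- landscape coordinates ------------------------------------------

    @property
    def geometric_mean(self) -> float:
        m = self.alpha / (self.alpha + self.beta)
        return float(self.bounds.from_unit(m))

    @property
    def geometric_sd(self) -> float:
        a, b = self.alpha, self.beta
        s = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        return 10.0 ** (s * self.bounds.log10_span)


def from_geometric_moments(
    bounds: InputBounds, E: float, sigma: float
) -> ContinuousInputDistribution:
    """Log-beta distribution with geometric mean ``E`` and geometric SD ``sigma``.

    Exact moment matching in log10 space: with L = log10(x_max/x_min),
    m = log10(E/x_min)/L and s = log10(sigma)/L, the beta parameters are
    alpha = m*nu, beta = (1-m)*nu with nu = m(1-m)/s^2 - 1.

    Raises
    ------
    InfeasibleDistributionError
        If s^2 >= m(1-m): no beta distribution on a bounded interval can be
        that wide at that centre.
    ValueError
        If E is outside (x_min, x_max) or sigma <= 1.
    """
    if not (bounds.x_min < E < bounds.x_max):
        raise ValueError(f"E={E} must lie strictly inside ({bounds.x_min}, {bounds.x_max})")
    if not sigma > 1.0:
        raise ValueError(f"geometric SD must exceed 1, got {sigma}")
    L = bounds.log10_span
    m = math.log10(E / bounds.x_min) / L
    s = math.log10(sigma) / L
    s2 = s * s
    if s2 >= m * (1.0 - m):
        raise InfeasibleDistributionError(
            f"(E={E}, sigma={sigma}) infeasible: s^2={s2:.6g} >= m(1-m)={m * (1 - m):.6g}"
        )
    nu = m * (1.0 - m) / s2 - 1.0
    return ContinuousInputDistribution(bounds, alpha=m * nu, beta=(1.0 - m) * nu)


@dataclass(frozen=True)
class DesignGrid:
    """Log-spaced (E, sigma) grid with a feasibility mask.

    ``feasible[i, j]`` refers to (E_values[i], sigma_values[j]).
    """

    bounds: InputBounds
    E_values: np.ndarray
    sigma_values: np.ndarray
    feasible: np.ndarray = field(repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.E_values), len(self.sigma_values)

    def distribution(self, i: int, j: int) -> ContinuousInputDistribution:
        """The distribution at grid cell (i, j); raises if infeasible."""
        return from_geometric_moments(
            self.bounds, float(self.E_values[i]), float(self.sigma_values[j])
        )

    def cells(self):
        """Yield (i, j, E, sigma) over feasible cells in row-major order."""
        for i, E in enumerate(self.E_values):
            for j, sig in enumerate(self.sigma_values):
                if self.feasible[i, j]:
                    yield i, j, float(E), float(sig)


def make_grid(
    bounds: InputBounds,
    E_range: tuple[float, float],
    sigma_range: tuple[float, float],
    n_E: int,
    n_sigma: int,
) -> DesignGrid:
    """Construct a log-spaced design grid and mark infeasible cells.

    Infeasible (E, sigma) pairs are masked rather than raised, so wide-sigma
    corners of the design space simply drop out of the landscape.
    """
    if n_E < 2 or n_sigma < 2:
        raise ValueError("need at least 2 grid points per axis")
    E_lo, E_hi = E_range
    s_lo, s_hi = sigma_range
    if not (bounds.x_min < E_lo < E_hi < bounds.x_max):
        raise ValueError("E_range must lie strictly inside the input bounds")
    if not (1.0 < s_lo < s_hi):
        raise ValueError("sigma_range must satisfy 1 < sigma_min < sigma_max")
    E_values = np.geomspace(E_lo, E_hi, n_E)
    sigma_values = np.geomspace(s_lo, s_hi, n_sigma)
    feasible = np.zeros((n_E, n_sigma), dtype=bool)
    for i, E in enumerate(E_values):
        for j, sig in enumerate(sigma_values):
            try:
                from_geometric_moments(bounds, float(E), float(sig))
            except InfeasibleDistributionError:
                continue
            feasible[i, j] = True
    if not feasible.any():
        raise ValueError("design grid has no feasible (E, sigma) cells")
    return DesignGrid(bounds, E_values, sigma_values, feasible)
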