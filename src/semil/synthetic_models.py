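"""Synthetic ground-truth generators for validating the landscape pipeline.

Two generators are provided:

* :class:`GammaResponseModel` — a dose–response channel whose output at input
  ``x`` is gamma distributed with a Hill-function mean

      mean(x) = g0 + g_max * x^n / (K^n + x^n)

  and variance ``mean + c * mean^2`` (a Poissonian term plus a
  multiplicative-noise term with squared coefficient of variation ``c``).
  Because the conditional density is known in closed form, the exact mutual
  information for any continuous input distribution can be computed by 2-D
  numerical integration, giving a per-cell ground truth for error maps.

* :class:`ReactionNetwork` + :func:`gillespie_simulate` — an exact stochastic
  simulation (direct method) of a chemical master equation, one independent
  trajectory per cell, read out at a single fixed time, mimicking a
  flow-cytometry snapshot of a lactose-operon-like induction circuit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import special, stats

from .design_space import (
    ContinuousInputDistribution,
    DesignGrid,
    InputBounds,
    from_geometric_moments,
)
from .mi_core import SingleCellDataset
from .srom import SupportSet

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# gamma-response model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaResponseModel:
    """Gamma-distributed gene-expression output with a Hill-function mean.

    Parameters
    ----------
    basal : float
        Output level at zero input (g0, output units).
    amplitude : float
        Induced dynamic range (g_max).
    half_max : float
        Input at half-maximal induction (K, input units).
    hill : float
        Hill coefficient (steepness of the response).
    noise_scale : float
        Squared multiplicative coefficient of variation c:
        Var(g|x) = mean + c * mean^2.
    """

    basal: float = 50.0
    amplitude: float = 5000.0
    half_max: float = 50.0
    hill: float = 2.0
    noise_scale: float = 0.1

    def __post_init__(self) -> None:
        for name in ("basal", "amplitude", "half_max", "hill"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")

    def mean_response(self, x):
        """Mean output g0 + g_max * x^n / (K^n + x^n)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("input must be non-negative")
        xn = (x / self.half_max) ** self.hill
        return self.basal + self.amplitude * xn / (1.0 + xn)

    def variance(self, x):
        m = self.mean_response(x)
        return m + self.noise_scale * m**2

    def gamma_params(self, x):
        """(shape, scale) of the conditional gamma output distribution."""
        m = np.asarray(self.mean_response(x), dtype=float)
        v = m + self.noise_scale * m**2
        return m**2 / v, v / m

    def quantile(self, q: float, x):
        k, theta = self.gamma_params(x)
        return stats.gamma.ppf(q, k, scale=theta)

    def sample_outputs(self, x: float, n_cells: int, seed=None) -> np.ndarray:
        """i.i.d. gamma draws of the output at input ``x``."""
        if n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        rng = np.random.default_rng(seed)
        k, theta = self.gamma_params(float(x))
        return rng.gamma(k, theta, size=n_cells)

    def sample_dataset(
        self, support: SupportSet, n_cells: int, seed: int = 0
    ) -> SingleCellDataset:
        """Mock flow-cytometry dataset: ``n_cells`` outputs at each support value."""
        rng = np.random.default_rng(seed)
        groups = {
            float(x): self.sample_outputs(x, n_cells, rng.integers(2**31))
            for x in support.values
        }
        return SingleCellDataset(groups, discrete_outputs=False)


def default_validation_model(noise_scale: float = 1.0) -> GammaResponseModel:
    """The packaged validation fixture (g0=50, g_max=5000, K=50, n=2).

    The default noise is the highest of the packaged sweep: sparse input
    supports can only stand in for a continuous input when the conditional
    output distributions of neighbouring inputs overlap, which is the
    regime the wide-band dose-response fixture represents.  Pass a smaller
    ``noise_scale`` for the low-noise members of the sweep.
    """
    return GammaResponseModel(noise_scale=noise_scale)


NOISE_SWEEP: tuple[float, ...] = (1.0, 0.1, 0.01)  # decreasing-noise fixtures


class GammaMIOracle:
    """Exact mutual information of a gamma-response channel by quadrature.

    The x-integral uses equal-probability nodes (beta quantiles at midpoint
    probabilities), which handles the integrable endpoint singularities of
    antimodal input densities exactly; the output integral uses the
    trapezoid rule on a fixed log-output grid spanning beyond the 1e-8 and
    1 - 1e-8 conditional quantiles at every admissible input.
    """

    def __init__(
        self,
        model: GammaResponseModel,
        bounds: InputBounds,
        n_x: int = 400,
        n_g: int = 800,
    ):
        self.model = model
        self.bounds = bounds
        self.n_x = n_x
        self.n_g = n_g
        # global log-output grid covering every x in the bounds
        probe = np.geomspace(bounds.x_min, bounds.x_max, 257)
        lo = float(np.min(model.quantile(1e-8, probe)))
        hi = float(np.max(model.quantile(1.0 - 1e-8, probe)))
        self.y = np.linspace(math.log(lo), math.log(hi), n_g)
        self.dy = self.y[1] - self.y[0]

    def _kernel(self, x: np.ndarray) -> np.ndarray:
        """Rows f(y | x_i) of the conditional log-output density, renormalised."""
        k, theta = self.model.gamma_params(x)
        k = np.atleast_1d(k)[:, None]
        theta = np.atleast_1d(theta)[:, None]
        y = self.y[None, :]
        # density of y = ln g when g ~ Gamma(k, theta)
        logf = k * y - np.exp(y) / theta - k * np.log(theta) - special.gammaln(k)
        K = np.exp(logf)
        mass = K.sum(axis=1) * self.dy  # trapezoid ~ riemann on uniform grid
        return K / mass[:, None]

    def mi(self, cont: ContinuousInputDistribution) -> float:
        """I(X; g) in bits for the given continuous input distribution."""
        q = (np.arange(self.n_x) + 0.5) / self.n_x
        u = cont.unit_ppf(q)
        x = cont.bounds.from_unit(u)
        K = self._kernel(x)
        marginal = K.mean(axis=0)
        # log-difference form: robust when K underflows to subnormals
        pos = K > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            logK = np.log(np.where(pos, K, 1.0))
            logm = np.log(np.maximum(marginal, np.finfo(float).tiny))
        integrand = np.where(pos, K * (logK - logm[None, :]), 0.0)
        return float(integrand.sum() * self.dy / self.n_x / LN2)

    def grid_mi(self, grid: DesignGrid) -> np.ndarray:
        """Ground-truth MI at every feasible grid cell (NaN elsewhere)."""
        out = np.full(grid.shape, np.nan)
        for i, j, E, sig in grid.cells():
            out[i, j] = self.mi(from_geometric_moments(grid.bounds, E, sig))
        return out


def true_mi_numeric(
    model: GammaResponseModel,
    cont: ContinuousInputDistribution,
    n_x: int = 400,
    n_g: int = 800,
    tol_bits: float = 0.005,
    max_doublings: int = 3,
) -> float:
    """Exact MI with a refinement-doubling convergence check.

    Doubles both grid resolutions until consecutive values agree within
    ``tol_bits``; raises if the quadrature does not converge.
    """
    previous = GammaMIOracle(model, cont.bounds, n_x, n_g).mi(cont)
    for _ in range(max_doublings):
        n_x *= 2
        n_g *= 2
        current = GammaMIOracle(model, cont.bounds, n_x, n_g).mi(cont)
        if abs(current - previous) < tol_bits:
            return current
        previous = current
    raise RuntimeError(
        f"MI quadrature did not converge to {tol_bits} bits "
        f"(last change {abs(current - previous):.4g})"
    )


# ---------------------------------------------------------------------------
# small-noise-limit check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseTrendReport:
    """Optima and CDF-matching distances across a decreasing-noise sweep."""

    noise_scales: tuple[float, ...]
    E_opt: tuple[float, ...]
    sigma_opt: tuple[float, ...]
    sup_distance: tuple[float, ...]  # sup |optimal CDF - normalised mean response|


def normalized_mean_response(model: GammaResponseModel, bounds: InputBounds, x):
    """Mean response rescaled to [0, 1] over the input bounds."""
    lo = model.mean_response(bounds.x_min)
    hi = model.mean_response(bounds.x_max)
    return (model.mean_response(x) - lo) / (hi - lo)


def response_matched_cdf_distance(
    model: GammaResponseModel,
    cont: ContinuousInputDistribution,
    n_probe: int = 512,
) -> float:
    """sup-distance between an input CDF and the normalised mean response.

    In the small-noise limit the optimal input CDF converges to the
    normalised mean response curve, so this distance should shrink as the
    output noise decreases.
    """
    x = np.geomspace(cont.bounds.x_min, cont.bounds.x_max, n_probe)
    return float(
        np.max(np.abs(cont.cdf(x) - normalized_mean_response(model, cont.bounds, x)))
    )


def optimal_input_cdf_check(
    models: Sequence[GammaResponseModel],
    support: SupportSet,
    grid: DesignGrid,
    n_cells: int,
    seed: int = 0,
    **landscape_kwargs,
) -> NoiseTrendReport:
    """Run the full pipeline per model and report the small-noise-limit trend."""
    from .landscape import compute_landscape, find_optimum

    if any(
        not np.allclose(models[0].mean_response(support.values), m.mean_response(support.values))
        for m in models
    ):
        raise ValueError("models must share the same mean response function")
    E_opt, s_opt, dist = [], [], []
    for idx, model in enumerate(models):
        data = model.sample_dataset(support, n_cells, seed=seed + idx)
        ls = compute_landscape(grid, data, seed=seed + idx, **landscape_kwargs)
        opt = find_optimum(ls)
        cont = from_geometric_moments(grid.bounds, opt.E, opt.sigma)
        E_opt.append(opt.E)
        s_opt.append(opt.sigma)
        dist.append(response_matched_cdf_distance(model, cont))
    return NoiseTrendReport(
        noise_scales=tuple(m.noise_scale for m in models),
        E_opt=tuple(E_opt),
        sigma_opt=tuple(s_opt),
        sup_distance=tuple(dist),
    )


# ---------------------------------------------------------------------------
# Gillespie stochastic simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One reaction channel: a stoichiometric change and a propensity.

    The propensity is vectorised: it maps a (n_cells, n_species) state
    matrix and the scalar input ``x`` to a (n_cells,) array of rates.
    """

    change: np.ndarray
    propensity: Callable[[np.ndarray, float], np.ndarray]
    name: str = ""


@dataclass(frozen=True)
class ReactionNetwork:
    """A chemical reaction network with a scalar input and one output species."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    initial_state: np.ndarray
    output_species: str

    def __post_init__(self) -> None:
        if self.output_species not in self.species:
            raise ValueError(f"unknown output species {self.output_species!r}")
        init = np.asarray(self.initial_state, dtype=np.int64)
        object.__setattr__(self, "initial_state", init)
        if init.shape != (len(self.species),) or np.any(init < 0):
            raise ValueError("initial state must be non-negative, one entry per species")

    @property
    def output_index(self) -> int:
        return self.species.index(self.output_species)


def gillespie_simulate(
    net: ReactionNetwork,
    x: float,
    n_cells: int,
    t_end: float,
    seed=None,
    max_events: int = 10_000_000,
) -> np.ndarray:
    """Exact SSA (direct method), one trajectory per cell, read out at t_end.

    All trajectories advance synchronously through vectorised draws; each
    cell keeps its own clock, so the per-trajectory statistics are exactly
    those of the sequential direct method.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    changes = np.stack([r.change for r in net.reactions]).astype(np.int64)
    state = np.tile(net.initial_state, (n_cells, 1))
    t = np.zeros(n_cells)
    alive = np.ones(n_cells, dtype=bool)
    events = 0
    while alive.any():
        idx = np.flatnonzero(alive)
        sub = state[idx]
        a = np.stack([r.propensity(sub, x) for r in net.reactions], axis=1)
        if np.any(a < 0) or not np.all(np.isfinite(a)):
            raise RuntimeError("propensity became negative or non-finite")
        a_tot = a.sum(axis=1)
        quiescent = a_tot <= 0.0
        if quiescent.any():  # absorbing state: nothing more can fire
            alive[idx[quiescent]] = False
            keep = ~quiescent
            idx, sub, a, a_tot = idx[keep], sub[keep], a[keep], a_tot[keep]
            if idx.size == 0:
                continue
        dt = rng.exponential(1.0 / a_tot)
        t_new = t[idx] + dt
        done = t_new >= t_end
        alive[idx[done]] = False
        fire = ~done
        idx_f = idx[fire]
        if idx_f.size:
            cum = np.cumsum(a[fire], axis=1)
            r = rng.random(idx_f.size) * a_tot[fire]
            which = (r[:, None] >= cum).sum(axis=1)
            state[idx_f] += changes[which]
            if np.any(state[idx_f] < 0):
                raise RuntimeError("species count became negative")
            t[idx_f] = t_new[fire]
            events += idx_f.size
            if events > max_events:
                raise RuntimeError(
                    f"exceeded {max_events} reaction events (propensity overflow?)"
                )
    return state[:, net.output_index].copy()


def sample_dataset_ssa(
    net: ReactionNetwork,
    support: SupportSet,
    n_cells: int,
    t_end: float,
    seed: int = 0,
) -> SingleCellDataset:
    """Simulated single-cell dataset of output counts at each input value."""
    rng = np.random.default_rng(seed)
    groups = {
        float(x): gillespie_simulate(net, float(x), n_cells, t_end, rng.integers(2**31))
        for x in support.values
    }
    return SingleCellDataset(groups, discrete_outputs=True)


# -- packaged networks ------------------------------------------------------

def birth_death_network(birth: float = 10.0, death: float = 0.1) -> ReactionNetwork:
    """Single-species birth-death process (Poisson stationary distribution)."""
    return ReactionNetwork(
        species=("P",),
        reactions=(
            Reaction(np.array([1]), lambda s, x: np.full(len(s), birth), "birth"),
            Reaction(np.array([-1]), lambda s, x: death * s[:, 0], "death"),
        ),
        initial_state=np.array([0]),
        output_species="P",
    )


def two_stage_network(
    k_tx: float = 5.0, d_m: float = 1.0, k_p: float = 4.0, d_p: float = 0.1
) -> ReactionNetwork:
    """mRNA -> protein cascade; stationary protein Fano factor ~ 1 + burst size."""
    return ReactionNetwork(
        species=("M", "P"),
        reactions=(
            Reaction(np.array([1, 0]), lambda s, x: np.full(len(s), k_tx), "tx"),
            Reaction(np.array([-1, 0]), lambda s, x: d_m * s[:, 0], "mdeg"),
            Reaction(np.array([0, 1]), lambda s, x: k_p * s[:, 0], "tl"),
            Reaction(np.array([0, -1]), lambda s, x: d_p * s[:, 1], "pdeg"),
        ),
        initial_state=np.array([0, 0]),
        output_species="P",
    )


def lac_network(
    feedback: bool = False,
    k_tx: float = 50.0,
    d_m: float = 10.0,
    k_p: float = 20.0,
    d_p: float = 1.0,
    R_total: float = 50.0,
    theta: float = 5.0,
    K: float = 40.0,
    m: float = 2.0,
    fb_gain: float = 3.0,
    P_scale: float = 100.0,
) -> ReactionNetwork:
    """Lactose-operon-like induction circuit: inducer inactivates a repressor
    that throttles transcription of a two-stage (mRNA, reporter) cascade.

    Active repressor at inducer level x is ``R_total * K^m / (K^m + x^m)``
    and the transcription propensity is ``k_tx * (1 - R / (R + theta))``.
    With ``feedback=True`` the reporter stands in for the lacY permease: the
    effective intracellular inducer is scaled by ``1 + fb_gain * P/P_scale``,
    the positive-feedback motif that widens and flattens the landscape.
    """

    def active_repressor(x_eff):
        return R_total * K**m / (K**m + np.maximum(x_eff, 0.0) ** m)

    def tx_propensity(s, x):
        if feedback:
            x_eff = x * (1.0 + fb_gain * s[:, 1] / P_scale)
        else:
            x_eff = np.full(len(s), float(x))
        R = active_repressor(x_eff)
        return k_tx * (1.0 - R / (R + theta))

    return ReactionNetwork(
        species=("M", "P"),
        reactions=(
            Reaction(np.array([1, 0]), tx_propensity, "tx"),
            Reaction(np.array([-1, 0]), lambda s, x: d_m * s[:, 0], "mdeg"),
            Reaction(np.array([0, 1]), lambda s, x: k_p * s[:, 0], "tl"),
            Reaction(np.array([0, -1]), lambda s, x: d_p * s[:, 1], "pdeg"),
        ),
        initial_state=np.array([0, 0]),
        output_species="P",
    )
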