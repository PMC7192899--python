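"""Mutual information landscapes over the (E, sigma) design space.

For every feasible design-grid cell the pipeline is: map (E, sigma) to a
log-beta input distribution, fit its sparse discrete approximation on the
measured input values, and evaluate the bias-corrected mutual information of
that discrete input through the model-free output channel.  The binning and
the stratified subsamples are computed once per dataset and shared across
cells; the 1/N extrapolation is redone per cell because each cell weights
the input groups differently.

Infeasible or failed cells carry NaN, never 0 (0 bits is a meaningful
landscape value).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import mi_core, srom
from .design_space import DesignGrid, from_geometric_moments
from .mi_core import SingleCellDataset, SubsampledConditionals
from .srom import SupportSet

NEAR_OPTIMAL_TOL = 0.05  # bits, the near-optimal contour convention
HIGH_MI_WINDOW = 0.5  # bits below the maximum: "high information" region


@dataclass
class MILandscape:
    """Grid of mutual information values (bits); NaN marks undefined cells."""

    grid: DesignGrid
    I_values: np.ndarray = field(repr=False)
    support: SupportSet
    metadata: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.I_values)


@dataclass(frozen=True)
class Optimum:
    E: float
    sigma: float
    I: float
    on_boundary: bool
    index: tuple[int, int]


class LandscapeCellError(RuntimeError):
    """A per-cell SROM or MI failure, annotated with the cell coordinates."""


def compute_landscape(
    grid: DesignGrid,
    dataset: SingleCellDataset,
    *,
    n_bins: int | None = None,
    fractions: tuple[float, ...] = mi_core.DEFAULT_FRACTIONS,
    reps: int = mi_core.DEFAULT_REPS,
    seed: int = 0,
    srom_weight: float = 1.0,
    moment_orders: tuple[int, ...] = srom.DEFAULT_MOMENT_ORDERS,
    bias_correction: bool = True,
) -> MILandscape:
    """Bias-corrected mutual information at every feasible (E, sigma) cell."""
    if not grid.feasible.any():
        raise ValueError("design grid has no feasible cells")
    support = dataset.support()
    binning = mi_core.make_binning(dataset, n_bins)
    if bias_correction:
        sub = SubsampledConditionals(dataset, binning, fractions, reps, seed)
        cond = sub.conditional_model()
    else:
        sub = None
        cond = mi_core.estimate_conditional(dataset, binning)

    I = np.full(grid.shape, np.nan)
    for i, j, E, sig in grid.cells():
        try:
            cont = from_geometric_moments(grid.bounds, E, sig)
            disc = srom.fit_discrete(
                cont, support, weight=srom_weight, orders=moment_orders
            )
            if sub is not None:
                I[i, j], _, _ = sub.corrected_mi(disc.masses)
            else:
                I[i, j] = mi_core.mutual_information(disc, cond)
        except Exception as exc:  # attach the coordinates before propagating
            raise LandscapeCellError(
                f"landscape cell (E={E:.4g}, sigma={sig:.4g}) failed: {exc}"
            ) from exc
    metadata = {
        "n_bins": binning.n_bins,
        "discrete_outputs": dataset.discrete_outputs,
        "bias_correction": bias_correction,
        "fractions": list(fractions) if bias_correction else None,
        "reps": reps if bias_correction else None,
        "seed": seed,
        "srom_weight": srom_weight,
        "moment_orders": list(moment_orders),
        "counts_per_input": dataset.counts.tolist(),
    }
    return MILandscape(grid, I, support, metadata)


def find_optimum(ls: MILandscape) -> Optimum:
    """Argmax cell of the landscape; ties broken by smallest sigma, then E.

    ``on_boundary`` is true when the argmax touches the edge of the feasible
    region (array edge or a 4-neighbour that is infeasible/undefined).
    """
    defined = ls.defined
    if not defined.any():
        raise ValueError("landscape has no defined cells")
    I_max = np.nanmax(ls.I_values)
    ties = np.argwhere(defined & (ls.I_values == I_max))
    order = np.lexsort(
        (ls.grid.E_values[ties[:, 0]], ls.grid.sigma_values[ties[:, 1]])
    )
    i, j = map(int, ties[order[0]])
    n_E, n_sigma = ls.grid.shape
    on_boundary = False
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ni, nj = i + di, j + dj
        if not (0 <= ni < n_E and 0 <= nj < n_sigma) or not defined[ni, nj]:
            on_boundary = True
            break
    return Optimum(
        E=float(ls.grid.E_values[i]),
        sigma=float(ls.grid.sigma_values[j]),
        I=float(I_max),
        on_boundary=on_boundary,
        index=(i, j),
    )


def near_optimal_region(ls: MILandscape, tol: float = NEAR_OPTIMAL_TOL) -> np.ndarray:
    """Mask of cells within ``tol`` bits of the landscape maximum."""
    opt = find_optimum(ls)
    return ls.defined & (ls.I_values >= opt.I - tol)


def error_landscape(ls: MILandscape, oracle_I: np.ndarray) -> np.ndarray:
    """delta_I = I_estimated - I_correct per cell, NaN where undefined."""
    oracle_I = np.asarray(oracle_I, dtype=float)
    if oracle_I.shape != ls.I_values.shape:
        raise ValueError(
            f"oracle shape {oracle_I.shape} != landscape shape {ls.I_values.shape}"
        )
    return ls.I_values - oracle_I


def high_information_region(
    oracle_I: np.ndarray, window: float = HIGH_MI_WINDOW
) -> np.ndarray:
    """Cells whose ground-truth MI is within ``window`` bits of the true maximum."""
    oracle_I = np.asarray(oracle_I, dtype=float)
    if not np.isfinite(oracle_I).any():
        raise ValueError("oracle landscape has no defined cells")
    return np.isfinite(oracle_I) & (oracle_I >= np.nanmax(oracle_I) - window)


def write_landscape(ls: MILandscape, csv_path, json_path=None) -> None:
    """Long-format CSV (E, sigma, I, feasible) plus a JSON settings sidecar.

    Undefined cells are written with an empty I field, never 0.
    """
    import pandas as pd

    n_E, n_sigma = ls.grid.shape
    ii, jj = np.meshgrid(np.arange(n_E), np.arange(n_sigma), indexing="ij")
    df = pd.DataFrame(
        {
            "E": ls.grid.E_values[ii.ravel()],
            "sigma": ls.grid.sigma_values[jj.ravel()],
            "I": ls.I_values.ravel(),
            "feasible": ls.grid.feasible.ravel(),
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")
    if json_path is not None:
        opt = find_optimum(ls)
        sidecar = {
            "support": ls.support.values.tolist(),
            "settings": ls.metadata,
            "optimum": {
                "E": round(opt.E, 4),
                "sigma": round(opt.sigma, 4),
                "I": round(opt.I, 4),
                "on_boundary": opt.on_boundary,
            },
        }
        with open(json_path, "w") as fh:
            json.dump(sidecar, fh, indent=2)


def read_landscape_csv(csv_path) -> "pd.DataFrame":
    import pandas as pd

    return pd.read_csv(csv_path)


def plot_landscape(ls: MILandscape, path, tol: float = NEAR_OPTIMAL_TOL) -> None:
    """Heat map of the landscape with the optimum dot and near-optimal contour."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    opt = find_optimum(ls)
    fig, ax = plt.subplots(figsize=(5, 4))
    E, S = np.meshgrid(ls.grid.E_values, ls.grid.sigma_values, indexing="ij")
    pcm = ax.pcolormesh(E, S, np.ma.masked_invalid(ls.I_values), shading="nearest")
    with np.errstate(invalid="ignore"):
        ax.contour(
            E, S, np.where(ls.defined, ls.I_values, -np.inf),
            levels=[opt.I - tol], colors="white", linewidths=1.0,
        )
    ax.plot(opt.E, opt.sigma, "o", color="white", mec="black", ms=6)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("geometric mean, E")
    ax.set_ylabel("geometric SD, $\\sigma$")
    fig.colorbar(pcm, ax=ax, label="I (bits)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
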