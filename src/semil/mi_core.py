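"""Model-free mutual information estimation from single-cell output data.

The channel is described by the conditional distributions of a scalar
gene-expression output ``g`` at each fixed input value ``x_i``.  Observed
bin frequencies are used directly as the conditional probabilities (no
parametric output model, no pseudocounts).  Mutual information for a given
discrete input distribution P(x_i) is the standard decomposition

    I(X; g) = H(g) - sum_i P(x_i) H(g | x_i)          [bits]

with H the Shannon entropy in bits and the marginal
P(g_j) = sum_i P(x_i) P(g_j | x_i).

Plug-in MI from finite data is biased upward by an amount that scales like
1/N.  The estimate at each point of the design space is therefore corrected
by stratified subsampling: each input group is subsampled to fractions f of
its size, the plug-in MI is recomputed (averaged over repeats), and a
straight line in 1/(f N) is extrapolated to the infinite-data intercept.

Continuous outputs are binned with pooled equal-frequency (quantile) bins,
which equalise bin occupancy and keep the small-count bias uniform across
bins; naturally discrete outputs (molecule counts) use the non-negative
integers up to the observed maximum as their bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .srom import DiscreteInputDistribution, SupportSet

LN2 = np.log(2.0)

DEFAULT_FRACTIONS: tuple[float, ...] = (1.0, 0.8, 0.625, 0.5)
DEFAULT_REPS = 5
MAX_BINS = 256
MIN_SUBSAMPLE = 10


@dataclass
class SingleCellDataset:
    """Single-cell outputs grouped by the input value at which they were measured."""

    groups: dict[float, np.ndarray]
    discrete_outputs: bool = False

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("dataset has no input groups")
        clean: dict[float, np.ndarray] = {}
        for x, g in self.groups.items():
            arr = np.asarray(g, dtype=float).ravel()
            if arr.size == 0:
                raise ValueError(f"input group x={x} is empty")
            clean[float(x)] = arr
        self.groups = clean

    @property
    def input_values(self) -> np.ndarray:
        return np.array(sorted(self.groups))

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(self.groups[x]) for x in self.input_values])

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def support(self) -> SupportSet:
        return SupportSet(self.input_values)

    def pooled(self) -> np.ndarray:
        return np.concatenate([self.groups[x] for x in self.input_values])

    def subset(self, input_values) -> "SingleCellDataset":
        """Restrict to a subset of the measured input values."""
        keep = {float(x): self.groups[float(x)] for x in input_values}
        return SingleCellDataset(keep, discrete_outputs=self.discrete_outputs)


@dataclass(frozen=True)
class BinningScheme:
    """Output bins: sorted edges; value v falls in bin j iff edges[j] <= v < edges[j+1].

    Values below the first or above the last edge are clipped into the
    terminal bins, so every output always has a bin.
    """

    edges: np.ndarray
    discrete: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", e)
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(e) < 3:
            raise ValueError("need at least 2 bins")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, values) -> np.ndarray:
        """Bin index per value (terminal bins absorb out-of-range values)."""
        return np.searchsorted(self.edges[1:-1], np.asarray(values), side="right")


def default_n_bins(dataset: SingleCellDataset) -> int:
    """ceil(sqrt(smallest group size)), capped at 256 bins."""
    return int(min(MAX_BINS, np.ceil(np.sqrt(dataset.counts.min()))))


def make_binning(dataset: SingleCellDataset, n_bins: int | None = None) -> BinningScheme:
    """Pooled equal-frequency bins for continuous outputs; integer bins for counts."""
    if dataset.discrete_outputs:
        g_max = int(dataset.pooled().max())
        edges = np.arange(-0.5, g_max + 1.5)
        if len(edges) < 3:  # all zeros: still need >= 2 bins
            edges = np.array([-0.5, 0.5, 1.5])
        return BinningScheme(edges, discrete=True)
    if n_bins is None:
        n_bins = default_n_bins(dataset)
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2 for continuous outputs")
    pooled = dataset.pooled()
    edges = np.quantile(pooled, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < n_bins + 1:
        warnings.warn(
            f"duplicate quantile edges merged: {len(edges) - 1} effective bins "
            f"instead of {n_bins}",
            stacklevel=2,
        )
    if len(edges) < 3:
        # fewer than 2 distinct bins after merging: split at the dominant value
        v = np.unique(pooled)
        if len(v) < 2:
            raise ValueError("outputs are constant; cannot bin into >= 2 bins")
        edges = np.array([v[0], (v[0] + v[-1]) / 2, v[-1]])
    # widen terminal edges so min/max samples land inside
    edges = edges.astype(float)
    return BinningScheme(edges)


@dataclass(frozen=True)
class ConditionalOutputModel:
    """Row-stochastic matrix P(g = g_j | X = x_i) with per-input sample sizes."""

    inputs: SupportSet
    bin_scheme: BinningScheme
    probs: np.ndarray = field(repr=False)
    counts_per_input: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.shape[0] != len(self.inputs):
            raise ValueError("one probability row per input value required")
        if np.any(p < 0):
            raise ValueError("negative conditional probability")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("conditional rows must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.probs.shape[1]


def estimate_conditional(
    dataset: SingleCellDataset, binning: BinningScheme
) -> ConditionalOutputModel:
    """Observed bin frequencies per input group, used directly as probabilities."""
    inputs = dataset.input_values
    n_bins = binning.n_bins
    probs = np.empty((len(inputs), n_bins))
    for i, x in enumerate(inputs):
        codes = binning.assign(dataset.groups[x])
        probs[i] = np.bincount(codes, minlength=n_bins) / len(codes)
    return ConditionalOutputModel(
        SupportSet(inputs), binning, probs, dataset.counts
    )


def marginal_output(
    disc: DiscreteInputDistribution, cond: ConditionalOutputModel
) -> np.ndarray:
    """P(g_j) = sum_i P(x_i) P(g_j | x_i)."""
    _check_support(disc, cond)
    return disc.masses @ cond.probs


def entropy(p) -> float:
    """Shannon entropy in bits; 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    return float(-xlogy(p, p).sum() / LN2)


def _row_entropies(probs: np.ndarray) -> np.ndarray:
    return -xlogy(probs, probs).sum(axis=1) / LN2


def _check_support(disc: DiscreteInputDistribution, cond: ConditionalOutputModel):
    if len(disc.support) != len(cond.inputs) or not np.allclose(
        disc.support.values, cond.inputs.values, rtol=1e-12
    ):
        raise ValueError("input support of the distribution and channel differ")


def mutual_information(
    disc: DiscreteInputDistribution, cond: ConditionalOutputModel
) -> float:
    """Plug-in mutual information I(X; g) in bits (clamped at 0)."""
    _check_support(disc, cond)
    return _mi_from_matrix(disc.masses, cond.probs)


def _mi_from_matrix(masses: np.ndarray, probs: np.ndarray) -> float:
    marginal = masses @ probs
    I = entropy(marginal) - float(np.dot(masses, _row_entropies(probs)))
    return max(I, 0.0)


class SubsampledConditionals:
    """Precomputed subsampled conditional matrices for bias-corrected MI.

    The stratified subsamples (and hence the conditional probability rows)
    do not depend on the input weighting, so across a design grid they are
    drawn once and shared; only the extrapolation, which mixes the rows with
    each cell's own masses, is per cell.
    """

    def __init__(
        self,
        dataset: SingleCellDataset,
        binning: BinningScheme,
        fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
        reps: int = DEFAULT_REPS,
        seed: int = 0,
    ):
        fractions = tuple(fractions)
        if not fractions or any(not (0.0 < f <= 1.0) for f in fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if 1.0 not in fractions:
            raise ValueError("fractions must include 1.0 (the full dataset)")
        if reps < 1:
            raise ValueError("reps must be >= 1")
        self.fractions = fractions
        self.reps = reps
        inputs = dataset.input_values
        counts = dataset.counts
        n_bins = binning.n_bins
        for f in fractions:
            small = np.floor(f * counts).astype(int)
            if np.any(small < MIN_SUBSAMPLE):
                raise ValueError(
                    f"subsampling fraction {f} leaves fewer than "
                    f"{MIN_SUBSAMPLE} cells in a group"
                )
        codes = [binning.assign(dataset.groups[x]) for x in inputs]
        rng = np.random.default_rng(seed)
        self.inv_n = np.empty(len(fractions))
        self.prob_stacks: list[np.ndarray] = []  # (reps, n_inputs, n_bins) per fraction
        for k, f in enumerate(fractions):
            n_sub = np.floor(f * counts).astype(int)
            self.inv_n[k] = 1.0 / n_sub.sum()
            n_reps = 1 if f == 1.0 else reps
            stack = np.empty((n_reps, len(inputs), n_bins))
            for r in range(n_reps):
                for i, c in enumerate(codes):
                    sub = c if f == 1.0 else rng.permutation(c)[: n_sub[i]]
                    stack[r, i] = np.bincount(sub, minlength=n_bins) / n_sub[i]
            self.prob_stacks.append(stack)
        self.full_probs = self.prob_stacks[fractions.index(1.0)][0]
        self.inputs = SupportSet(inputs)
        self.binning = binning
        self.counts = counts

    def corrected_mi(self, masses: np.ndarray) -> tuple[float, float, dict]:
        """Extrapolated MI, naive (full-data) MI and fit diagnostics."""
        means = np.empty(len(self.fractions))
        for k, stack in enumerate(self.prob_stacks):
            means[k] = np.mean([_mi_from_matrix(masses, probs) for probs in stack])
        naive = means[list(self.fractions).index(1.0)]
        if len(self.fractions) == 1:
            return naive, naive, {"slope": 0.0, "points": means.copy()}
        slope, intercept = np.polyfit(self.inv_n, means, 1)
        corrected = max(float(intercept), 0.0)
        diagnostics = {
            "slope": float(slope),
            "inv_n": self.inv_n.copy(),
            "points": means.copy(),
        }
        return corrected, naive, diagnostics

    def conditional_model(self) -> ConditionalOutputModel:
        return ConditionalOutputModel(
            self.inputs, self.binning, self.full_probs, self.counts
        )


def bias_corrected_mi(
    dataset: SingleCellDataset,
    disc: DiscreteInputDistribution,
    binning: BinningScheme,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
) -> tuple[float, float, dict]:
    """Finite-sampling-corrected MI by subsampling extrapolation.

    Each input group is subsampled without replacement to floor(f * N_i)
    cells for every fraction f (``reps`` repeats, averaged), the plug-in MI
    is recomputed, and MI is regressed on 1/(f N_total); the intercept is
    the infinite-data extrapolation.  Deterministic given ``seed``.

    Returns ``(corrected, naive, diagnostics)``.
    """
    sub = SubsampledConditionals(dataset, binning, fractions, reps, seed)
    _check_support(disc, sub.conditional_model())
    return sub.corrected_mi(disc.masses)
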