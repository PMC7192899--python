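"""Channel capacity by the Blahut–Arimoto algorithm.

Capacity is the maximum mutual information over *all* discrete input
distributions on the measured support, without the design-space restriction
to log-beta shapes.  It therefore upper-bounds every landscape value and
serves as the comparison baseline: the landscape's optimum reports how much
of the unconstrained capacity a biologically plausible (smooth, bounded)
input family can realise.  The Blahut–Arimoto optimal input is typically
spiky — masses concentrated on a few support points — which is exactly the
interpretability problem the design space avoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LN2 = np.log(2.0)


@dataclass(frozen=True)
class CapacityResult:
    capacity: float  # bits
    optimal_masses: np.ndarray
    iterations: int
    gap: float  # upper-bound minus lower-bound at termination, bits


class CapacityConvergenceError(RuntimeError):
    def __init__(self, iterations: int, gap: float):
        super().__init__(
            f"Blahut-Arimoto did not converge in {iterations} iterations (gap {gap:.3g} bits)"
        )
        self.gap = gap


def blahut_arimoto(cond, tol: float = 1e-6, max_iter: int = 10_000) -> CapacityResult:
    """Capacity of a discrete memoryless channel given row-stochastic P(g|x).

    Accepts a conditional-output model or a bare row-stochastic matrix.
    Alternating updates from the uniform prior; terminates when the
    standard upper/lower capacity bounds differ by less than ``tol`` bits.
    The objective is concave, so the result is initialisation-independent.
    """
    W = np.asarray(getattr(cond, "probs", cond), dtype=float)
    if W.ndim != 2 or np.any(W < 0) or not np.allclose(W.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("conditional matrix must be row-stochastic")
    n_in = W.shape[0]
    p = np.full(n_in, 1.0 / n_in)
    logW = np.log(np.where(W > 0, W, 1.0))
    for it in range(1, max_iter + 1):
        q = p @ W  # output marginal
        with np.errstate(divide="ignore"):
            logq = np.log(np.where(q > 0, q, 0.0))
        # D(W_x || q) in nats per input
        d = np.einsum("ij,ij->i", W, logW - np.where(W > 0, logq, 0.0))
        lower = float(p @ d) / LN2
        upper = float(d.max()) / LN2
        if upper - lower < tol:
            return CapacityResult(lower, p, it, upper - lower)
        p = p * np.exp(d - d.max())
        p /= p.sum()
    raise CapacityConvergenceError(max_iter, upper - lower)
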