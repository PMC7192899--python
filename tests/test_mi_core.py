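"""Binning, model-free channel estimation, entropies and bias correction."""

import numpy as np
import pytest

from semil.mi_core import (
    BinningScheme,
    ConditionalOutputModel,
    SingleCellDataset,
    SubsampledConditionals,
    bias_corrected_mi,
    entropy,
    estimate_conditional,
    make_binning,
    marginal_output,
    mutual_information,
)
from semil.srom import DiscreteInputDistribution, SupportSet


def channel(W, inputs=None):
    """Wrap a row-stochastic matrix as a conditional-output model."""
    n_in, n_out = W.shape
    if inputs is None:
        inputs = np.arange(float(n_in))
    scheme = BinningScheme(np.arange(-0.5, n_out + 0.5))
    return ConditionalOutputModel(
        SupportSet(inputs), scheme, W, np.full(n_in, 100)
    )


def binary_channel_dataset(n, p_low=0.1, p_high=0.9, seed=0):
    """Two-input channel with Bernoulli outputs; analytic MI available."""
    rng = np.random.default_rng(seed)
    return SingleCellDataset(
        {
            1.0: (rng.random(n) < p_low).astype(float),
            10.0: (rng.random(n) < p_high).astype(float),
        },
        discrete_outputs=True,
    )


def h2(p):
    return -p * np.log2(p) - (1 - p) * np.log2(1 - p)


UNIFORM_2 = DiscreteInputDistribution(
    SupportSet(np.array([1.0, 10.0])), np.array([0.5, 0.5])
)


class TestMakeBinning:
    def test_quantile_edges_on_uniform_sample(self):
        data = SingleCellDataset({1.0: np.arange(1.0, 1001.0)})
        scheme = make_binning(data, n_bins=10)
        assert scheme.n_bins == 10
        interior = scheme.edges[1:-1]
        assert np.allclose(interior, np.arange(100, 1000, 100), atol=1.0)
        # equal occupancy
        counts = np.bincount(scheme.assign(data.groups[1.0]), minlength=10)
        assert counts.max() - counts.min() <= 1

    def test_discrete_outputs_use_integer_bins(self):
        data = SingleCellDataset(
            {1.0: np.array([0, 1, 7, 3]), 2.0: np.array([2, 2])}, discrete_outputs=True
        )
        scheme = make_binning(data, n_bins=99)  # n_bins ignored for counts
        assert scheme.n_bins == 8  # integers 0..7
        assert np.array_equal(scheme.assign(np.arange(8)), np.arange(8))

    def test_massive_ties_merge_edges(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([np.full(900, 5.0), rng.random(100) * 10])
        data = SingleCellDataset({1.0: vals})
        with pytest.warns(UserWarning):
            scheme = make_binning(data, n_bins=10)
        assert 2 <= scheme.n_bins <= 3  # 90% ties leave at most ~2 usable bins

    def test_out_of_range_values_clip_into_terminal_bins(self):
        data = SingleCellDataset({1.0: np.arange(1.0, 101.0)})
        scheme = make_binning(data, n_bins=4)
        assert scheme.assign(np.array([-50.0]))[0] == 0
        assert scheme.assign(np.array([1e9]))[0] == scheme.n_bins - 1


class TestEstimateConditional:
    def test_frequencies_counted_directly(self):
        data = SingleCellDataset(
            {1.0: np.array([1.0, 1.0, 2.0, 3.0]), 5.0: np.array([2.0, 2.0])},
            discrete_outputs=True,
        )
        cond = estimate_conditional(data, make_binning(data))
        assert np.allclose(cond.probs[0], [0.0, 0.5, 0.25, 0.25])
        assert np.allclose(cond.probs[1], [0.0, 0.0, 1.0, 0.0])

    def test_rows_against_histogram_oracle(self, rng):
        data = SingleCellDataset({1.0: rng.normal(size=500), 2.0: rng.normal(1.0, 2.0, 700)})
        scheme = make_binning(data, n_bins=8)
        cond = estimate_conditional(data, scheme)
        for i, x in enumerate(data.input_values):
            hist, _ = np.histogram(data.groups[x], bins=scheme.edges)
            # histogram drops nothing here because edges span the pooled range
            assert np.allclose(cond.probs[i], hist / hist.sum())
        assert np.allclose(cond.probs.sum(axis=1), 1.0)


class TestMarginalAndEntropy:
    def test_unit_mass_selects_row(self):
        data = binary_channel_dataset(100)
        cond = estimate_conditional(data, make_binning(data))
        disc = DiscreteInputDistribution(SupportSet(np.array([1.0, 10.0])), np.array([0.0, 1.0]))
        assert np.allclose(marginal_output(disc, cond), cond.probs[1])

    def test_uniform_mixture_of_unit_rows(self):
        cond_probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        data = SingleCellDataset(
            {1.0: np.zeros(10), 10.0: np.ones(10)}, discrete_outputs=True
        )
        cond = estimate_conditional(data, make_binning(data))
        assert np.allclose(cond.probs, cond_probs)
        assert np.allclose(marginal_output(UNIFORM_2, cond), [0.5, 0.5])

    @pytest.mark.parametrize(
        "p,expected",
        [([0.5, 0.5], 1.0), ([1.0, 0.0, 0.0], 0.0), ([0.3, 0.7], 0.8812908992306927)],
    )
    def test_entropy_values(self, p, expected):
        assert entropy(np.array(p)) == pytest.approx(expected, abs=1e-12)

    def test_entropy_rejects_negative(self):
        with pytest.raises(ValueError):
            entropy(np.array([1.2, -0.2]))


class TestMutualInformation:
    def test_noiseless_channel_counts_levels(self):
        """Identity channel over 4 inputs at uniform input: exactly 2 bits."""
        data = SingleCellDataset(
            {float(k): np.full(20, 3.0 * k) for k in range(4)}, discrete_outputs=True
        )
        cond = estimate_conditional(data, make_binning(data))
        disc = DiscreteInputDistribution(data.support(), np.full(4, 0.25))
        assert mutual_information(disc, cond) == pytest.approx(2.0, abs=1e-12)

    def test_constant_channel_is_zero(self):
        data = SingleCellDataset(
            {1.0: np.array([2.0, 3.0] * 10), 5.0: np.array([2.0, 3.0] * 10)},
            discrete_outputs=True,
        )
        cond = estimate_conditional(data, make_binning(data))
        disc = DiscreteInputDistribution(data.support(), np.array([0.3, 0.7]))
        assert mutual_information(disc, cond) == pytest.approx(0.0, abs=1e-12)

    def test_against_double_sum_oracle(self, rng):
        """Entropy decomposition equals the direct sum P_i W_ij log(W_ij / q_j)."""
        W = rng.dirichlet(np.ones(4), size=3)
        masses = rng.dirichlet(np.ones(3))
        cond = channel(W)
        disc = DiscreteInputDistribution(SupportSet(np.arange(3.0)), masses)
        q = masses @ W
        expected = sum(
            masses[i] * W[i, j] * np.log2(W[i, j] / q[j])
            for i in range(3)
            for j in range(4)
            if W[i, j] > 0
        )
        assert mutual_information(disc, cond) == pytest.approx(expected, abs=1e-12)

    def test_data_processing_bounds(self, rng):
        for _ in range(10):
            W = rng.dirichlet(np.ones(5), size=3)
            masses = rng.dirichlet(np.ones(3))
            cond = channel(W)
            disc = DiscreteInputDistribution(SupportSet(np.arange(3.0)), masses)
            I = mutual_information(disc, cond)
            assert 0.0 <= I <= entropy(masses) + 1e-12
            assert I <= np.log2(W.shape[1]) + 1e-12

    def test_merging_output_bins_never_increases_mi(self, rng):
        """Coarse-graining monotonicity on random channels."""
        for _ in range(10):
            W = rng.dirichlet(np.ones(6), size=4)
            masses = rng.dirichlet(np.ones(4))
            merged = np.column_stack([W[:, 0] + W[:, 1], W[:, 2:]])
            q, qm = masses @ W, masses @ merged

            def mi(mat, marg):
                nz = mat > 0
                return sum(
                    masses[i] * mat[i, j] * np.log2(mat[i, j] / marg[j])
                    for i in range(mat.shape[0])
                    for j in range(mat.shape[1])
                    if nz[i, j]
                )

            assert mi(merged, qm) <= mi(W, q) + 1e-12

    def test_support_mismatch_rejected(self):
        data = binary_channel_dataset(50)
        cond = estimate_conditional(data, make_binning(data))
        disc = DiscreteInputDistribution(SupportSet(np.array([1.0, 11.0])), np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            mutual_information(disc, cond)


class TestBiasCorrectedMI:
    def test_recovers_analytic_channel_mi(self):
        """2-input binary channel at N = 1e5: corrected MI within 0.01 bits."""
        data = binary_channel_dataset(100_000, seed=5)
        true_I = 1.0 - h2(0.1)
        corrected, naive, diag = bias_corrected_mi(
            data, UNIFORM_2, make_binning(data), seed=3
        )
        assert corrected == pytest.approx(true_I, abs=0.01)

    def test_single_fraction_degenerates_to_naive(self):
        data = binary_channel_dataset(2000, seed=2)
        corrected, naive, _ = bias_corrected_mi(
            data, UNIFORM_2, make_binning(data), fractions=(1.0,), seed=0
        )
        assert corrected == naive

    def test_plug_in_bias_grows_when_subsampling(self):
        """Plug-in MI bias is positive and ~1/N: subsampled estimates sit higher."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 300
            data = SingleCellDataset(
                {
                    1.0: np.floor(rng.random(n) * 12),
                    10.0: np.floor(rng.random(n) ** 2 * 12),
                },
                discrete_outputs=True,
            )
            sub = SubsampledConditionals(
                data, make_binning(data), fractions=(1.0, 0.5), reps=20, seed=seed
            )
            masses = np.array([0.5, 0.5])
            from semil.mi_core import _mi_from_matrix

            m_full = np.mean([_mi_from_matrix(masses, P) for P in sub.prob_stacks[0]])
            m_half = np.mean([_mi_from_matrix(masses, P) for P in sub.prob_stacks[1]])
            wins += m_half >= m_full
        assert wins >= 15

    def test_convergence_with_sample_size(self):
        """Median error of the corrected estimate shrinks as N grows."""
        true_I = 1.0 - h2(0.1)
        med_err = []
        for n in (1000, 10_000, 100_000):
            errs = []
            for seed in range(10):
                data = binary_channel_dataset(n, seed=seed)
                corrected, _, _ = bias_corrected_mi(
                    data, UNIFORM_2, make_binning(data), seed=seed
                )
                errs.append(abs(corrected - true_I))
            med_err.append(np.median(errs))
        assert med_err[2] < med_err[0]

    def test_determinism_given_seed(self):
        data = binary_channel_dataset(5000, seed=7)
        a = bias_corrected_mi(data, UNIFORM_2, make_binning(data), seed=9)[0]
        b = bias_corrected_mi(data, UNIFORM_2, make_binning(data), seed=9)[0]
        assert a == b

    def test_too_small_subsample_rejected(self):
        data = binary_channel_dataset(15, seed=0)
        with pytest.raises(ValueError):
            bias_corrected_mi(data, UNIFORM_2, make_binning(data), fractions=(1.0, 0.5))
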