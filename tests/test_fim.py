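"""Fisher information of synchrony: construction, spectra, pivotal structure."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import synchfim as sf

from conftest import kl_quadratic_form, random_model, strong_neuron_model


def theta_delta(N: int, vec: np.ndarray) -> sf.ParameterDelta:
    """Lift a theta-space vector to a ParameterDelta."""
    model = sf.model_from_theta(N, vec)
    return sf.ParameterDelta(dh=model.h, dJ=model.J)


class TestCoarseFisherTheta:
    def test_single_neuron_is_constant(self):
        model = sf.PottsModel(h=np.zeros((1, 3)), J=np.zeros((1, 1)))
        G = sf.coarse_fisher_theta(model)
        assert not G.any()

    @pytest.mark.parametrize("granularity", ["fine", "coarse"])
    def test_positive_semidefinite(self, model4, granularity):
        G = sf.coarse_fisher_theta(model4, granularity=granularity)
        assert np.allclose(G, G.T)
        assert np.linalg.eigvalsh(G).min() >= -1e-10 * np.linalg.eigvalsh(G).max()

    def test_matches_finite_difference_kl(self, model3):
        # diagonal entries against the KL definition along single parameters
        G = sf.coarse_fisher_theta(model3)
        for i in [0, 3, 7]:
            e = np.zeros(sf.n_params(3))
            e[i] = 1.0
            oracle = kl_quadratic_form(model3, theta_delta(3, e))
            assert G[i, i] == pytest.approx(oracle, rel=1e-3)

    def test_mc_path_converges(self, model3):
        exact = sf.coarse_fisher_theta(model3)
        errs = []
        for T in (2_000, 50_000):
            mc = sf.coarse_fisher_theta(
                model3, method="mc", mc_settings={"T": T, "seed": 17}
            )
            errs.append(np.abs(mc - exact).max())
        assert errs[1] < errs[0]
        assert errs[1] < 0.05 * np.abs(exact).max()


class TestObservableFIM:
    def test_symmetric_psd(self, model4):
        F = sf.observable_fim(model4)
        w = np.linalg.eigvalsh(F.values)
        assert np.allclose(F.values, F.values.T, atol=1e-8)
        assert w.min() >= -1e-8 * w.max()

    def test_direction_ordering_matcher_major(self):
        dirs = sf.observable_directions(3)
        assert dirs == [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
        assert len(sf.observable_directions(50)) == 2450

    def test_identical_independent_neurons_against_oracle(self):
        # with identically distributed independent neurons the only surviving
        # observable derivative is the matcher-target agreement term; the
        # resulting diagonal entries are equal across directions and match
        # the finite-difference KL oracle
        h = np.zeros((3, 3))
        h[:, 0], h[:, 2] = 0.3, -0.2
        model = sf.PottsModel(h=h, J=np.zeros((3, 3)))
        F = sf.observable_fim(model)
        diag = np.diag(F.values)
        assert np.allclose(diag, diag[0], rtol=1e-10)
        delta = sf.localized_jacobian(model, sf.PerturbationDirection(0, 1))
        oracle = kl_quadratic_form(model, delta)
        assert diag[0] == pytest.approx(oracle, rel=1e-3)

    def test_diagonal_against_kl_oracle(self, model3):
        F = sf.observable_fim(model3)
        for d, (m, t) in enumerate(F.directions):
            delta = sf.localized_jacobian(model3, sf.PerturbationDirection(m, t))
            oracle = kl_quadratic_form(model3, delta)
            assert F.values[d, d] == pytest.approx(oracle, rel=1e-3)

    def test_rank_bound(self, model4):
        lam = sf.observable_fim(model4).eigenvalues()
        numerical_rank = (lam > 1e-10 * lam[0]).sum()
        bound = min(len(lam), len(sf.enumerate_synchrony_states(4)) - 1)
        assert numerical_rank <= bound

    def test_permutation_equivariance(self):
        model = random_model(4, seed=19)
        perm = np.array([2, 0, 3, 1])
        permuted = sf.PottsModel(
            h=model.h[perm], J=model.J[np.ix_(perm, perm)]
        )
        F = sf.observable_fim(model)
        Fp = sf.observable_fim(permuted)
        assert np.allclose(
            np.linalg.eigvalsh(F.values), np.linalg.eigvalsh(Fp.values), atol=1e-8
        )
        # entries map under the induced permutation of directions
        lookup = {d: i for i, d in enumerate(Fp.directions)}
        inv = np.argsort(perm)
        for i, (m, t) in enumerate(F.directions[:4]):
            j = lookup[(inv[m], inv[t])]
            assert F.values[i, i] == pytest.approx(Fp.values[j, j], rel=1e-8)


class TestCanonicalFIM:
    def test_submatrix_of_theta_fisher(self, model3):
        G = sf.coarse_fisher_theta(model3)
        F = sf.canonical_fim(model3)
        assert np.allclose(F.values, G[6:, 6:])
        assert F.directions == sf.coupling_pairs(3)

    def test_diagonal_against_kl_oracle(self, model3):
        F = sf.canonical_fim(model3)
        for d, (m, t) in enumerate(F.directions):
            delta = sf.canonical_direction((m, t), N=3)
            oracle = kl_quadratic_form(model3, delta)
            assert F.values[d, d] == pytest.approx(oracle, rel=1e-3)


class TestEigenmodes:
    def test_trace_identity_and_orthonormality(self, model4):
        F = sf.observable_fim(model4)
        modes = sf.eigenmodes(F)
        assert sum(m.eigenvalue for m in modes) == pytest.approx(
            np.trace(F.values), rel=1e-8
        )
        mats = np.stack([m.eigenmatrix.ravel() for m in modes])
        assert np.allclose(mats @ mats.T, np.eye(len(modes)), atol=1e-8)
        for m in modes:
            assert np.allclose(np.diag(m.eigenmatrix), 0.0)
            assert np.abs(m.eigenmatrix).max() == m.eigenmatrix.max()  # sign fix

    def test_matches_independent_eigensolver(self, model3):
        from scipy.linalg import eigh

        F = sf.observable_fim(model3)
        lam = np.array([m.eigenvalue for m in sf.eigenmodes(F)])
        ref = eigh(F.values, eigvals_only=True)[::-1]
        assert np.allclose(lam, ref, atol=1e-10)


class TestUniformity:
    def test_uniform_off_diagonal_matrix(self):
        N = 5
        v = np.ones((N, N)) - np.eye(N)
        v /= np.linalg.norm(v)
        mode = sf.EigenMode(rank=1, eigenvalue=1.0, eigenmatrix=v)
        U, V = sf.uniformity(mode)
        assert np.allclose(V, V[0]) and np.allclose(U, U[0])

    def test_concentrated_column(self):
        N = 6
        v = np.zeros((N, N))
        v[1:, 0] = 1.0 / np.sqrt(N - 1)
        mode = sf.EigenMode(rank=1, eigenvalue=1.0, eigenmatrix=v)
        U, V = sf.uniformity(mode)
        assert V[0] == pytest.approx(N - 1)
        assert np.allclose(V[1:], 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_cauchy_schwarz_bound(self, seed):
        # sum_j V_j <= N for any unit-Frobenius-norm matrix
        rng = np.random.default_rng(seed)
        N = 7
        v = rng.normal(size=(N, N))
        np.fill_diagonal(v, 0.0)
        v /= np.linalg.norm(v)
        _, V = sf.uniformity(sf.EigenMode(rank=1, eigenvalue=1.0, eigenmatrix=v))
        assert V.sum() <= N + 1e-12


class TestPivotalNeurons:
    def test_single_run_flags_are_binary(self, model4):
        modes = sf.eigenmodes(sf.observable_fim(model4))
        flags = sf.pivotal_neurons(modes, percentile=99.0)
        assert set(np.unique(flags)) <= {0.0, 1.0}

    def test_identical_runs_keep_binary_fractions(self, model4):
        modes = sf.eigenmodes(sf.observable_fim(model4))
        flags = sf.pivotal_neurons([modes] * 5, percentile=99.0)
        assert set(np.unique(flags)) <= {0.0, 1.0}

    def test_strong_neuron_is_most_flagged(self):
        model = strong_neuron_model()
        modes = sf.eigenmodes(sf.observable_fim(model))
        flags = sf.pivotal_neurons(modes, percentile=99.0)
        assert flags[0] >= flags.max() - 1e-12


class TestMatcherBlocks:
    def test_interlacing_and_trace_partition(self, model4):
        F = sf.observable_fim(model4)
        blocks = sf.matcher_block_eigenvalues(F)
        lam_max = np.linalg.eigvalsh(F.values)[-1]
        assert (blocks <= lam_max + 1e-12).all()
        trace_blocks = sum(
            np.trace(F.values[m * 3 : (m + 1) * 3, m * 3 : (m + 1) * 3])
            for m in range(4)
        )
        assert trace_blocks == pytest.approx(np.trace(F.values))

    def test_block_ranking_tracks_column_uniformity(self):
        model = strong_neuron_model()
        F = sf.observable_fim(model)
        blocks = sf.matcher_block_eigenvalues(F)
        modes = sf.eigenmodes(F)
        col_u = np.stack([sf.uniformity(m)[1] for m in modes]).max(axis=0)
        assert spearmanr(blocks, col_u).statistic > 0


class TestSubsampleSensitivity:
    def test_full_size_normalizes_to_one(self):
        model = random_model(5, seed=23)
        curve = sf.subsample_sensitivity(model, [5], ranking="pivotal")
        assert curve["mean"][0] == pytest.approx(1.0)

    def test_monotone_in_nested_subsets(self):
        model = random_model(6, seed=24)
        curve = sf.subsample_sensitivity(model, [2, 3, 4, 5, 6], ranking="pivotal")
        assert (np.diff(curve["mean"]) >= -1e-12).all()

    def test_pivotal_dominates_random(self):
        model = strong_neuron_model()
        F = sf.observable_fim(model)
        sizes = [2, 4, 6, 8]
        pivotal = sf.subsample_sensitivity(model, sizes, ranking="pivotal", F=F)
        rand = sf.subsample_sensitivity(
            model, sizes, ranking="random", M=10, seed=0, F=F
        )
        assert (pivotal["mean"] >= rand["mean"] - 1e-12).all()

    def test_small_sizes_rejected(self):
        with pytest.raises(ValueError):
            sf.subsample_sensitivity(random_model(4, seed=0), [1, 3])


class TestNullsAndDesign:
    def test_shuffle_preserves_coupling_multiset(self, model4):
        null = sf.shuffled_coupling_null(model4, seed=3)
        orig = sorted(model4.J[np.triu_indices(4, 1)])
        new = sorted(null.J[np.triu_indices(4, 1)])
        assert np.allclose(orig, new)
        assert np.array_equal(null.h, model4.h)

    def test_shuffle_determinism(self, model4):
        a = sf.shuffled_coupling_null(model4, seed=5)
        b = sf.shuffled_coupling_null(model4, seed=5)
        assert np.array_equal(a.J, b.J)

    def test_sample_size_bound(self):
        assert sf.sample_size_bound(1e-2, 1e3) == pytest.approx(10.0)
        assert sf.sample_size_bound(1.0, 1.0) == 1.0
        assert sf.sample_size_bound(2e-2, 1e3) == pytest.approx(2.5)
        with pytest.raises(ValueError):
            sf.sample_size_bound(0.0, 1.0)
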