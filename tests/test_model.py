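"""Core SEM algebra: model matrix, precision, likelihood, cycle reversal."""

import itertools

import numpy as np
import pytest
import scipy.stats

from eqtlnet.model import (
    JointDataset,
    NetworkModel,
    build_model_matrix,
    conditional_log_likelihood,
    f2_genotype_covariance,
    implied_covariance,
    implied_precision,
    moral_graph_from_structure,
    moral_support,
    reverse_cycle,
)
from eqtlnet.simulate import sample_expression, sample_f2_genotypes

from conftest import chain_model, random_model


def unit_model(b: np.ndarray, w: np.ndarray | None = None, **kw) -> NetworkModel:
    p = b.shape[0]
    w = np.eye(p) if w is None else w
    kw.setdefault("sigma", np.ones(p))
    kw.setdefault("assignment", np.arange(w.shape[1]))
    kw.setdefault("genotype_cov", np.eye(w.shape[1]))
    return NetworkModel(b=b, w=w, **kw)


class TestNetworkModelInvariants:
    def test_nonzero_diagonal_rejected(self):
        b = np.array([[0.1, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="self-loops"):
            unit_model(b)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            unit_model(np.zeros((2, 2)), sigma=np.array([1.0, 0.0]))

    def test_singular_i_minus_b_rejected(self):
        b = np.array([[0.0, 1.0], [1.0, 0.0]])  # spectral radius 1
        with pytest.raises(ValueError, match="singular"):
            unit_model(b)

    def test_unique_cis_requires_injective_assignment(self):
        w = np.zeros((2, 2))
        w[0, 0] = w[0, 1] = 1.0
        with pytest.raises(ValueError, match="injective"):
            unit_model(np.zeros((2, 2)), w=w, assignment=np.array([0, 0]))

    def test_unique_cis_support_check(self):
        w = np.eye(2)
        w[1, 0] = 0.5  # extra trans entry
        with pytest.raises(ValueError, match="support"):
            unit_model(np.zeros((2, 2)), w=w)


class TestModelMatrix:
    def test_identity_case_blocks(self):
        m = unit_model(np.zeros((2, 2)))
        btilde = build_model_matrix(m).btilde
        expected = np.block(
            [[np.eye(2), -np.eye(2)], [np.zeros((2, 2)), np.eye(2)]]
        )
        np.testing.assert_allclose(btilde, expected, atol=1e-12)

    def test_two_gene_chain_blocks(self):
        b_val = 0.7
        b = np.zeros((2, 2))
        b[1, 0] = b_val  # y0 -> y1
        m = unit_model(b)
        btilde = build_model_matrix(m).btilde
        np.testing.assert_allclose(
            btilde[:2, :2], np.array([[1.0, 0.0], [-b_val, 1.0]]), atol=1e-12
        )
        np.testing.assert_allclose(btilde[:2, 2:], -np.eye(2), atol=1e-12)

    def test_gram_matrix_reproduces_precision_random_model(self, rng):
        m = random_model(rng, p=5)
        btilde = build_model_matrix(m).btilde
        omega = implied_precision(m).omega
        assert np.max(np.abs(btilde.T @ btilde - omega)) < 1e-10


class TestPrecisionAndCovariance:
    def test_independent_genes_precision(self):
        m = unit_model(np.zeros((2, 2)))
        omega = implied_precision(m).omega
        expected = np.block(
            [[np.eye(2), -np.eye(2)], [-np.eye(2), 2 * np.eye(2)]]
        )
        np.testing.assert_allclose(omega, expected, atol=1e-12)

    def test_chain_induces_eqtl_to_parent_link(self):
        # y0 -> y1 makes eQTL 1 conditionally dependent on phenotype 0
        b_val = 0.6
        b = np.zeros((2, 2))
        b[1, 0] = b_val
        omega = implied_precision(unit_model(b))
        assert omega.yx[0, 1] == pytest.approx(b_val)

    def test_precision_covariance_inverse_pair(self, rng):
        m = random_model(rng, p=6, allow_cycles=True)
        omega = implied_precision(m).omega
        cov = implied_covariance(m)
        np.testing.assert_allclose(
            cov @ omega, np.eye(omega.shape[0]), atol=1e-8
        )

    def test_phenotype_covariance_block_closed_form(self, rng):
        m = random_model(rng, p=4)
        cov = implied_covariance(m)
        ib_inv = np.linalg.inv(np.eye(m.p) - m.b)
        expected = ib_inv @ (
            m.w @ m.genotype_cov @ m.w.T + np.diag(m.sigma)
        ) @ ib_inv.T
        np.testing.assert_allclose(cov[: m.p, : m.p], expected, atol=1e-10)

    def test_disconnected_covariance_is_blockdiagonal(self):
        p = 3
        m = NetworkModel(
            b=np.zeros((p, p)),
            w=np.zeros((p, p)),
            sigma=np.array([0.5, 1.0, 2.0]),
            assignment=np.arange(p),
            genotype_cov=np.eye(p),
            unique_cis=False,
        )
        cov = implied_covariance(m)
        np.testing.assert_allclose(
            cov,
            np.block(
                [
                    [np.diag(m.sigma), np.zeros((p, p))],
                    [np.zeros((p, p)), np.eye(p)],
                ]
            ),
            atol=1e-12,
        )


class TestMoralSupport:
    def test_diagonal_precision_gives_empty_graph(self):
        from eqtlnet.model import PrecisionMatrix

        prec = PrecisionMatrix(omega=np.diag([1.0, 2.0, 3.0]), p=3, q=0)
        assert moral_support(prec).edges == set()

    def test_collider_marries_parents(self):
        # y0 -> y2 <- y1: moralization joins the co-parents
        b = np.zeros((3, 3))
        b[2, 0] = b[2, 1] = 1.0
        graph = moral_support(implied_precision(unit_model(b)))
        phen = {tuple(sorted(e)) for e in graph.phenotype_edges()}
        assert phen == {(0, 2), (1, 2), (0, 1)}

    def test_chain_eqtl_links_cis_gene_and_its_parent(self):
        model = chain_model(4)
        graph = moral_support(implied_precision(model))
        # locus k touches exactly its cis gene k and that gene's parent k-1,
        # resolving the chain's otherwise-equivalent orientations
        for k in range(4):
            expected = {k} if k == 0 else {k, k - 1}
            assert {i for kk, i in graph.eqtl_phenotype_edges() if kk == k} == expected

    @pytest.mark.parametrize("allow_cycles", [False, True])
    def test_matches_combinatorial_moralization(self, rng, allow_cycles):
        for _ in range(100):
            m = random_model(rng, p=5, expected_degree=2.0, allow_cycles=allow_cycles)
            oracle = moral_support(implied_precision(m))
            expected = moral_graph_from_structure(m.b != 0, m.assignment)
            assert oracle == expected


class TestConditionalLogLikelihood:
    def test_matches_multivariate_normal_density(self, rng):
        m = unit_model(np.zeros((1, 1)), w=np.eye(1))
        y = rng.normal(size=(3, 1))
        x = rng.normal(size=(3, 1))
        data = JointDataset(y, x, ["g0"], ["m0"])
        cov = implied_covariance(m)
        centered = data.centered()
        oracle = scipy.stats.multivariate_normal(
            mean=np.zeros(2), cov=cov
        ).logpdf(centered).sum()
        assert conditional_log_likelihood(data, m) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_cycle_reversal_preserves_likelihood(self, rng):
        b = np.zeros((3, 3))
        b[1, 0] = b[2, 1] = b[0, 2] = 0.5
        m = unit_model(b, sigma=np.full(3, 0.25))
        alt, _ = reverse_cycle(m, [0, 1, 2])
        x = sample_f2_genotypes(40, 3, rng)
        y = sample_expression(m, x, rng)
        data = JointDataset(y, x, list("abc"), list("xyz"))
        ll_a = conditional_log_likelihood(data, m)
        ll_b = conditional_log_likelihood(data, alt)
        assert abs(ll_a - ll_b) < 1e-8 * max(1.0, abs(ll_a))

    def test_maximized_near_generating_parameters(self, rng):
        m = chain_model(3)
        x = sample_f2_genotypes(10_000, 3, rng)
        y = sample_expression(m, x, rng)
        data = JointDataset(y, x, list("abc"), list("xyz"))
        ll_true = conditional_log_likelihood(data, m)
        b_pert = m.b.copy()
        b_pert[1, 0] += 0.2
        m_pert = NetworkModel(
            b=b_pert, w=m.w, sigma=m.sigma, assignment=m.assignment,
            genotype_cov=m.genotype_cov,
        )
        assert conditional_log_likelihood(data, m_pert) < ll_true

    def test_dimension_mismatch_raises(self, rng):
        m = chain_model(3)
        data = JointDataset(
            rng.normal(size=(5, 2)), rng.normal(size=(5, 2)),
            ["a", "b"], ["x", "y"],
        )
        with pytest.raises(ValueError, match="mismatch"):
            conditional_log_likelihood(data, m)


class TestReverseCycle:
    def make_cycle(self, k=3, effect=0.5):
        b = np.zeros((k, k))
        for i in range(k):
            b[(i + 1) % k, i] = effect
        return unit_model(b, sigma=np.full(k, 0.25))

    def test_reversal_flips_cycle_and_preserves_covariance(self):
        m = self.make_cycle()
        alt, transform = reverse_cycle(m, [0, 1, 2])
        assert alt.directed_edges() == {(1, 0), (2, 1), (0, 2)}
        delta = np.abs(implied_covariance(m) - implied_covariance(alt))
        scale = np.max(np.abs(implied_covariance(m)))
        assert np.max(delta) < 1e-10 * scale
        m2 = transform.a  # orthonormality checked at construction too
        np.testing.assert_allclose(m2.T @ m2, np.eye(m2.shape[0]), atol=1e-10)

    def test_assignment_permuted_along_cycle(self):
        m = self.make_cycle()
        alt, _ = reverse_cycle(m, [0, 1, 2])
        moved = {
            k for k in range(3) if alt.assignment[k] != m.assignment[k]
        }
        assert moved == {0, 1, 2}
        assert sorted(alt.assignment.tolist()) == [0, 1, 2]

    def test_acyclic_input_raises(self):
        m = chain_model(3)
        with pytest.raises(ValueError, match="not a directed cycle"):
            reverse_cycle(m, [0, 1, 2])

    def test_double_reversal_restores_structure(self):
        m = self.make_cycle(4, effect=0.4)
        alt, _ = reverse_cycle(m, [0, 1, 2, 3])
        back, _ = reverse_cycle(alt, [3, 2, 1, 0])
        assert back.directed_edges() == m.directed_edges()
        np.testing.assert_allclose(back.b, m.b, atol=1e-10)


class TestDagUniqueness:
    """No non-identity signed permutation yields a valid equivalent DAG model.

    A permuted model matrix can be renormalized into a valid parametrization
    only if its phenotype diagonal is wholly nonzero, which forces the
    permutation's non-trivial orbits to trace directed cycles of B — absent
    in a DAG.
    """

    @pytest.mark.parametrize("p", [2, 3, 4])
    def test_exhaustive_signed_permutations(self, rng, p):
        m = random_model(rng, p=p, expected_degree=min(1.5, p - 1))
        assert m.is_dag()
        top = build_model_matrix(m).btilde[: m.p, : m.p]
        for perm in itertools.permutations(range(p)):
            if perm == tuple(range(p)):
                continue
            permuted_diag = np.array([top[perm[i], i] for i in range(p)])
            assert np.any(permuted_diag == 0.0), (
                f"permutation {perm} would admit an equivalent model"
            )


class TestJointDataset:
    def test_row_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal sample counts"):
            JointDataset(
                rng.normal(size=(5, 2)), rng.normal(size=(4, 2)),
                ["a", "b"], ["x", "y"],
            )

    def test_sample_cov_recomputable_from_centered_data(self, rng):
        data = JointDataset(
            rng.normal(size=(30, 2)), rng.normal(size=(30, 3)),
            ["a", "b"], ["x", "y", "z"],
        )
        z = data.centered()
        np.testing.assert_allclose(data.sample_cov, z.T @ z / 30, atol=1e-12)
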