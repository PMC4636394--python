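"""Linearized and nonlinear mean-field contact-network dynamics."""

import numpy as np
import pytest
import scipy.linalg

import ryrcn as R
from ryrcn.mean_field import (
    CNRates,
    eigenmode_correlation,
    expected_open_total,
    expected_open_vector,
    lcn_solution,
    mode_weights,
    nonlinear_mf_solve,
    stability_margin,
)


def expm_propagator(adj, rates, t):
    """Independent matrix-exponential oracle for the LCN solution."""
    m = rates.beta * adj.entries.astype(float) - rates.delta * np.eye(adj.n)
    return scipy.linalg.expm(m * t)


# ---------------------------------------------------------------------------
# lcn_solution

def test_lcn_t0_identity(eig7x7, nominal_rates):
    rng = np.random.default_rng(1)
    p0 = rng.random(49)
    assert lcn_solution(eig7x7, nominal_rates, p0, 0.0) == pytest.approx(p0, abs=1e-10)


def test_lcn_single_channel_decay():
    E = R.eigendecompose(R.build_adjacency(R.LatticeCluster(((0, 0),))))
    rates = CNRates(beta=0.115, delta=0.5)
    out = lcn_solution(E, rates, [1.0], 2.0)
    assert out[0] == pytest.approx(np.exp(-1.0), abs=1e-12)


def test_lcn_domino_symmetric_mode(adj_domino, nominal_rates):
    """p0=(1,1) projects only on the symmetric mode: both decay as e^{(b-d)t}."""
    E = R.eigendecompose(adj_domino)
    out = lcn_solution(E, nominal_rates, [1.0, 1.0], 5.0)
    expected = np.exp((nominal_rates.beta - nominal_rates.delta) * 5.0)
    assert out == pytest.approx([expected, expected], abs=1e-12)
    oracle = expm_propagator(adj_domino, nominal_rates, 5.0) @ np.ones(2)
    assert out == pytest.approx(oracle, abs=1e-10)


def test_lcn_mode_purity(eig7x7, nominal_rates):
    """An eigenvector initial condition stays on its own eigenmode."""
    for i in (0, 5):
        p0 = eig7x7.eigenvectors[:, i]
        out = lcn_solution(eig7x7, nominal_rates, p0, 3.0)
        scale = np.exp((nominal_rates.beta * eig7x7.eigenvalues[i] - nominal_rates.delta) * 3.0)
        assert out == pytest.approx(p0 * scale, abs=1e-10)


def test_lcn_length_mismatch(eig7x7, nominal_rates):
    with pytest.raises(ValueError):
        lcn_solution(eig7x7, nominal_rates, np.ones(3), 1.0)


# ---------------------------------------------------------------------------
# expected open channels

def test_expected_open_vector_t0_is_ones(eig7x7, nominal_rates):
    assert expected_open_vector(eig7x7, nominal_rates, 0.0) == pytest.approx(
        np.ones(49), abs=1e-10
    )


def test_expected_open_vector_interior_exceeds_corner(rect7x7, eig7x7, nominal_rates):
    vec = expected_open_vector(eig7x7, nominal_rates, 8.0)
    idx = {s: j for j, s in enumerate(rect7x7.sites)}
    interior = [vec[idx[(r, c)]] for r in range(1, 6) for c in range(1, 6)]
    corners = [vec[idx[s]] for s in ((0, 0), (0, 6), (6, 0), (6, 6))]
    assert min(interior) > max(corners)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_expected_open_matches_expm_oracle(seed, nominal_rates):
    cl = R.generate_random_cluster(25, seed)
    a = R.build_adjacency(cl)
    E = R.eigendecompose(a)
    t = 8.0
    prop = expm_propagator(a, nominal_rates, t)
    col_sums = prop.sum(axis=0)
    assert expected_open_vector(E, nominal_rates, t) == pytest.approx(col_sums, abs=1e-8)
    assert expected_open_total(E, nominal_rates, t) == pytest.approx(
        float(np.ones(a.n) @ prop @ np.ones(a.n)) / a.n, abs=1e-8
    )


def test_expected_open_total_edge_cases(eig7x7, nominal_rates):
    assert expected_open_total(eig7x7, nominal_rates, 0.0) == pytest.approx(1.0, abs=1e-10)
    E1 = R.eigendecompose(R.build_adjacency(R.LatticeCluster(((0, 0),))))
    assert expected_open_total(E1, nominal_rates, 4.0) == pytest.approx(np.exp(-2.0), abs=1e-12)


def test_dominant_term_constant_at_threshold(eig7x7):
    """At beta = delta/lambda1 the dominant mode weight is time-invariant."""
    rates = CNRates(beta=0.5 / eig7x7.lambda1, delta=0.5)
    w0 = mode_weights(eig7x7, rates, 0.0)
    w8 = mode_weights(eig7x7, rates, 8.0)
    assert w8.c[0] == pytest.approx(w0.c[0], abs=1e-12)


def test_decay_growth_dichotomy(eig7x7):
    lam = eig7x7.lambda1
    sub = expected_open_total(eig7x7, CNRates(0.9 * 0.5 / lam, 0.5), 100.0)
    supra = expected_open_total(eig7x7, CNRates(1.1 * 0.5 / lam, 0.5), 100.0)
    assert sub < 0.05
    assert supra > 20.0


# ---------------------------------------------------------------------------
# mode weights

def test_mode_weights_domino(adj_domino, nominal_rates):
    E = R.eigendecompose(adj_domino)
    w = mode_weights(E, nominal_rates)
    assert w.c_frac == pytest.approx([1.0, 0.0], abs=1e-12)


def test_mode_weights_normalization(eig7x7, nominal_rates):
    w = mode_weights(eig7x7, nominal_rates, 8.0)
    assert w.c_frac.sum() == pytest.approx(1.0, abs=1e-10)
    w0 = mode_weights(eig7x7, nominal_rates, 0.0)
    assert w0.c.sum() == pytest.approx(1.0, abs=1e-10)  # sum (u^T v_i)^2 = n


def test_solid_cluster_is_single_mode(eig7x7, nominal_rates):
    w = mode_weights(eig7x7, nominal_rates)
    assert w.c_frac[0] > 0.9


def test_dumbbell_subdominant_mode_emerges(nominal_rates):
    """A bottleneck splits the cluster into two functional subdomains.

    The lobes must differ in size: with equal lobes the splitting mode
    is odd by mirror symmetry and its overlap with the all-one vector
    vanishes, so it carries no weight.
    """
    dumbbell = R.generate_dumbbell_cluster(5, 3, 1, block2=4)  # n = 44
    solid = R.generate_rect_lattice(4, 11)                     # n = 44
    frac = {}
    for name, cl in (("dumbbell", dumbbell), ("solid", solid)):
        E = R.eigendecompose(R.build_adjacency(cl))
        frac[name] = np.sort(mode_weights(E, nominal_rates).c_frac)[::-1]
    assert frac["dumbbell"][1] > frac["solid"][1]
    assert frac["dumbbell"][1] > 0.2  # a genuinely bimodal cluster

    # symmetric control: the splitting mode is weightless
    E_sym = R.eigendecompose(R.build_adjacency(R.generate_dumbbell_cluster(5, 3, 1)))
    assert np.sort(mode_weights(E_sym, nominal_rates).c_frac)[::-1][1] < 0.05


# ---------------------------------------------------------------------------
# stability

def test_stability_classification(eig7x7):
    lam = eig7x7.lambda1
    assert stability_margin(eig7x7, CNRates(0.115, 0.5)).classification == "sub"
    assert 0.5 / 0.115 > lam  # delta/beta = 4.35 exceeds lambda1 = 3.70
    at = stability_margin(eig7x7, CNRates(0.5 / lam, 0.5))
    assert at.classification == "threshold"
    assert at.margin == pytest.approx(0.0, abs=1e-12)
    assert stability_margin(eig7x7, CNRates(1.0 / lam, 0.5)).classification == "supra"


# ---------------------------------------------------------------------------
# nonlinear mean field

def test_nonlinear_fixed_point_and_single_channel(nominal_rates):
    a = R.build_adjacency(R.generate_rect_lattice(2, 2))
    t = np.linspace(0, 10, 11)
    traj = nonlinear_mf_solve(a, nominal_rates, np.zeros(4), t)
    assert np.allclose(traj, 0.0)
    a1 = R.build_adjacency(R.LatticeCluster(((0, 0),)))
    traj1 = nonlinear_mf_solve(a1, nominal_rates, [1.0], t)
    assert traj1[:, 0] == pytest.approx(np.exp(-0.5 * t), abs=1e-7)


@pytest.mark.parametrize("seed", [0, 3])
def test_lcn_upper_bounds_nonlinear(seed):
    """Dropping the -beta p (Ap) term makes the LCN an entrywise upper bound."""
    rng = np.random.default_rng(seed)
    cl = R.generate_random_cluster(12, seed)
    a = R.build_adjacency(cl)
    E = R.eigendecompose(a)
    rates = CNRates(0.3, 0.5)  # strong coupling: nonlinearity matters
    p0 = rng.random(12)
    t_grid = np.linspace(0, 8, 9)
    nl = nonlinear_mf_solve(a, rates, p0, t_grid)
    for i, t in enumerate(t_grid):
        lin = lcn_solution(E, rates, p0, t)
        assert np.all(lin >= nl[i] - 1e-7)


def test_nonlinear_stays_in_unit_box(nominal_rates):
    a = R.build_adjacency(R.generate_rect_lattice(3, 3))
    traj = nonlinear_mf_solve(a, CNRates(1.0, 0.5), np.full(9, 0.9), np.linspace(0, 20, 21))
    assert traj.min() >= -1e-7
    assert traj.max() <= 1.0 + 1e-7


# ---------------------------------------------------------------------------
# eigenmode correlations

def test_correlation_full_reconstruction(eig7x7, nominal_rates):
    assert eigenmode_correlation(eig7x7, nominal_rates, k=49) == pytest.approx(1.0, abs=1e-9)


def test_correlation_solid_cluster_single_mode(eig7x7, nominal_rates):
    assert eigenmode_correlation(eig7x7, nominal_rates, k=1) > 0.95


def test_correlation_dumbbell_needs_second_mode(nominal_rates):
    """Bimodal clusters: low rho1, second mode required, tertiary marginal."""
    E = R.eigendecompose(R.build_adjacency(R.generate_dumbbell_cluster(5, 3, 1, block2=4)))
    rho = [eigenmode_correlation(E, nominal_rates, k=k) for k in (1, 2, 3)]
    assert rho[0] < 0.8
    assert rho[1] > 0.95
    assert rho[1] - rho[0] > rho[2] - rho[1]


def test_correlation_spearman_option(eig7x7, nominal_rates):
    rho = eigenmode_correlation(eig7x7, nominal_rates, k=1, method="spearman")
    assert 0.8 < rho <= 1.0
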