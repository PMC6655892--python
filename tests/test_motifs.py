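"""Motif moments/cumulants against loop oracles; resummed predictions."""

import numpy as np
import pytest

from motifdim import (EffectiveNetwork, er_closed_form, er_cumulants,
                      internal_covariance, mean_covariance_from_cumulants,
                      measure_motifs, motif_moments, taylor_coefficients,
                      traces_from_cumulants)
from motifdim.exceptions import DivergenceError
from motifdim.motifs import (MotifStatistics, dim_from_cumulants,
                             dim_with_input, highdim_input_approx,
                             moments_to_cumulants)

from conftest import random_psd, random_subcritical


# ---------------------------------------------------------------------------
# moments against explicit index-loop oracles
# ---------------------------------------------------------------------------

def brute_moments(G, u):
    """Triple-loop motif sums in the scaled normalization."""
    N = G.shape[0]
    out = {}
    out["chain1"] = sum(u[i] * G[i, j] * u[j]
                        for i in range(N) for j in range(N))
    G2 = G @ G
    out["chain2"] = sum(u[i] * G2[i, j] * u[j]
                        for i in range(N) for j in range(N))
    out["div11"] = sum(u[i] * G[i, k] * G[j, k] * u[j]
                       for i in range(N) for j in range(N) for k in range(N))
    out["conv11"] = sum(u[i] * G[k, i] * G[k, j] * u[j]
                        for i in range(N) for j in range(N) for k in range(N))
    out["trace11"] = sum(G[i, k] * G[i, k] for i in range(N)
                         for k in range(N)) / N
    out["trace20"] = sum(G[i, k] * G[k, i] for i in range(N)
                         for k in range(N)) / N
    return out


def test_moments_match_brute_force(rng):
    G = random_subcritical(rng, 12, radius=0.5)
    u = np.full(12, 1 / np.sqrt(12))
    stats = motif_moments(G, max_order=2)
    ref = brute_moments(G, u)
    m = stats.moments
    assert m["chain"][1] == pytest.approx(ref["chain1"], rel=1e-12)
    assert m["chain"][2] == pytest.approx(ref["chain2"], rel=1e-12)
    assert m["divergent"][1, 1] == pytest.approx(ref["div11"], rel=1e-12)
    assert m["convergent"][1, 1] == pytest.approx(ref["conv11"], rel=1e-12)
    assert m["trace"][1, 1] == pytest.approx(ref["trace11"], rel=1e-12)
    assert m["trace"][2, 0] == pytest.approx(ref["trace20"], rel=1e-12)
    assert m["reciprocal"][2] == pytest.approx(ref["trace20"] * 12, rel=1e-12)


def test_weighted_moments_match_brute_force(rng):
    G = random_subcritical(rng, 10, radius=0.5)
    u = rng.standard_normal(10)
    u /= np.linalg.norm(u)
    stats = motif_moments(G, max_order=2, u=u)
    ref = brute_moments(G, u)
    assert stats.moments["divergent"][1, 1] == pytest.approx(ref["div11"],
                                                             rel=1e-12)
    assert stats.moments["convergent"][1, 1] == pytest.approx(ref["conv11"],
                                                              rel=1e-12)


def test_uniform_weight_vector_reproduces_unweighted(rng):
    G = random_subcritical(rng, 15, radius=0.5)
    a = motif_moments(G, max_order=3)
    b = motif_moments(G, max_order=3, u=np.full(15, 1 / np.sqrt(15)))
    for key in ("chain", "divergent", "convergent"):
        assert np.allclose(a.moments[key], b.moments[key])


def test_conventional_normalization_accessor():
    # two neurons, single synapse of strength g: the conventional first
    # chain moment is the plain sum of entries
    g = 0.37
    G = np.array([[0.0, 0.0], [g, 0.0]])
    stats = motif_moments(G, max_order=2)
    assert stats.moment("chain", 1) == pytest.approx(g, rel=1e-12)


def test_order2_fast_path_equals_general_path(rng):
    from motifdim.motifs import (_empty_tables, _trace_moments_general,
                                 _trace_moments_order2)
    G = random_subcritical(rng, 30, radius=0.5)
    a, b = _empty_tables(2), _empty_tables(2)
    _trace_moments_order2(G, a)
    _trace_moments_general(G, b, 2)
    for key in ("trace", "trace4", "reciprocal"):
        assert np.allclose(a[key], b[key], atol=1e-14)


# ---------------------------------------------------------------------------
# cumulants
# ---------------------------------------------------------------------------

def test_low_order_cumulant_relations(rng):
    G = random_subcritical(rng, 14, radius=0.5)
    stats = measure_motifs(G, max_order=2)
    m, k = stats.moments, stats.cumulants
    assert k["chain"][1] == pytest.approx(m["chain"][1], rel=1e-12)
    # kappa_2 = mu_2 - mu_1^2 (single nontrivial composition of 2)
    assert k["chain"][2] == pytest.approx(m["chain"][2] - m["chain"][1] ** 2,
                                          rel=1e-10)
    # divergent (1,1): remove the product of two single edges
    assert k["divergent"][1, 1] == pytest.approx(
        m["divergent"][1, 1] - m["chain"][1] ** 2, rel=1e-10)
    # order-zero trace cumulants are forced to 1 - 1/N
    assert k["trace"][0, 0] == pytest.approx(1 - 1 / 14)
    assert k["trace4"][0] == pytest.approx(1 - 1 / 14)


def test_zero_matrix_cumulants():
    stats = measure_motifs(np.zeros((9, 9)), max_order=3)
    k = stats.cumulants
    assert np.allclose(k["chain"], 0.0)
    assert np.allclose(k["divergent"], 0.0)
    assert np.allclose(k["convergent"], 0.0)
    assert k["trace"][0, 0] == pytest.approx(1 - 1 / 9)
    assert np.abs(k["trace"]).sum() == pytest.approx(1 - 1 / 9)


def test_cumulant_inverse_reproduces_moments(rng):
    """Rebuilding the divergent moment table from cumulants is exact."""
    from motifdim.motifs import _p2_mul, _p_inv
    K = 5
    G = random_subcritical(rng, 12, radius=0.45)
    stats = measure_motifs(G, max_order=K)
    kch = stats.cumulants["chain"]
    c1 = -kch.copy()
    c1[0] = 1.0
    R = _p_inv(c1, K)
    oneKd = stats.cumulants["divergent"].copy()
    oneKd[0, 0] += 1.0
    rebuilt = _p2_mul(np.outer(R, R), oneKd, K)
    mask = stats.moments["divergent"] != 0
    assert np.allclose(rebuilt[mask], stats.moments["divergent"][mask],
                       rtol=1e-9)


# ---------------------------------------------------------------------------
# resummed predictions against the exact linear response
# ---------------------------------------------------------------------------

def test_uncoupled_limits():
    stats = measure_motifs(np.zeros((50, 50)), max_order=2)
    assert mean_covariance_from_cumulants(stats, c0=2.0) == \
        pytest.approx(2.0 / 50)
    trc, trc2 = traces_from_cumulants(stats, c0=2.0)
    assert trc == pytest.approx(2.0 * 50)
    assert trc2 == pytest.approx(4.0 * 50)
    assert dim_from_cumulants(stats).raw == pytest.approx(50.0)


def test_untruncated_expansion_converges_to_exact(rng):
    """Geometric error decay of <C>, Tr C, Tr C^2 in the truncation order."""
    G = random_subcritical(rng, 18, radius=0.45)
    net = EffectiveNetwork(G=G)
    C = internal_covariance(net)
    exact = {"mean": C.mean(), "tr": np.trace(C), "tr2": float(np.sum(C * C))}
    stats = measure_motifs(G, max_order=10)
    errs = []
    for K in (2, 4, 6, 8, 10):
        trc, trc2 = traces_from_cumulants(stats, order=K)
        errs.append(max(
            abs(mean_covariance_from_cumulants(stats, order=K)
                / exact["mean"] - 1),
            abs(trc / exact["tr"] - 1), abs(trc2 / exact["tr2"] - 1)))
    assert errs[-1] < 1e-2
    assert errs[-1] < errs[0] / 10  # decays by more than 10x over 8 orders


def test_mean_covariance_er_geometric_factor():
    """With only kappa_1 = rho/N the mean is (c0/N)(1-rho)^-2."""
    stats = er_cumulants(200, 0.6)
    assert mean_covariance_from_cumulants(stats, c0=3.0) == \
        pytest.approx(3.0 / 200 / 0.4 ** 2, rel=1e-12)


def test_divergence_guard():
    stats = er_cumulants(100, 1.2)
    with pytest.raises(DivergenceError):
        mean_covariance_from_cumulants(stats)
    with pytest.raises(DivergenceError):
        er_closed_form(100, 1.0)


def test_er_closed_form_values():
    assert er_closed_form(1000, 0.0).raw == pytest.approx(1000.0)
    assert er_closed_form(1000, 0.5).raw == pytest.approx(991.1418719, rel=1e-8)
    assert abs(er_closed_form(1000, 1 - 1e-6).raw - 1.0) < 1e-4
    assert er_closed_form(1000, 0.3).method == "closed_form_ER"


@pytest.mark.parametrize("rho", [0.1, 0.5, 0.8, 0.95])
def test_er_cumulants_reduce_to_closed_form(rho):
    for N in (100, 1000):
        a = dim_from_cumulants(er_cumulants(N, rho)).raw
        b = er_closed_form(N, rho).raw
        assert a == pytest.approx(b, rel=1e-10)


# ---------------------------------------------------------------------------
# Taylor coefficients
# ---------------------------------------------------------------------------

def test_taylor_special_values():
    tc = taylor_coefficients(500, [0.0])  # uncoupled reference, r = 1
    assert tc.r == pytest.approx(1.0)
    assert tc.alpha_div == pytest.approx(0.0, abs=1e-12)
    assert tc.alpha_con == tc.alpha_div
    assert tc.alpha_TrC == pytest.approx(2 * 500)


def test_taylor_matches_finite_differences():
    N, rho, h = 1000, 0.8, 1e-6
    tc = taylor_coefficients(N, [rho])

    def dim_at(**extra):
        kw = dict(chain={1: rho})
        for key, val in extra.items():
            kw[key] = val
        return dim_from_cumulants(
            MotifStatistics.from_cumulants(N, 2, **kw)).raw

    checks = {
        "alpha_ch": lambda e: {"chain": {1: rho, 2: e}},
        "alpha_div": lambda e: {"divergent": {(1, 1): e}},
        "alpha_con": lambda e: {"convergent": {(1, 1): e}},
        "alpha_TrC": lambda e: {"trace": {(1, 1): e}},
        "alpha_TrC2": lambda e: {"trace4": {2: e}},
    }
    for name, make in checks.items():
        fd = (dim_at(**make(h)) - dim_at(**make(-h))) / (2 * h)
        assert fd == pytest.approx(getattr(tc, name), rel=1e-3), name


@pytest.mark.parametrize("N", [100, 1000])
def test_taylor_sign_structure(N):
    """Chains/divergent/convergent lower dimension; net trace effect raises it."""
    for r in np.linspace(1.01, 10.0, 25):
        tc = taylor_coefficients(N, [1.0 - 1.0 / r])
        assert tc.alpha_ch < 0
        assert tc.alpha_div < 0
        assert tc.alpha_div == tc.alpha_con
        assert tc.alpha_TrC > 0
        assert tc.alpha_TrC2 < 0
        assert tc.net_trace_effect > 0


# ---------------------------------------------------------------------------
# stimulus-driven predictions
# ---------------------------------------------------------------------------

def test_dim_with_input_zero_strengths_is_internal(rng):
    G = random_subcritical(rng, 20, radius=0.4)
    st = measure_motifs(G, 2)
    u = rng.standard_normal(20)
    u /= np.linalg.norm(u)
    ext = [measure_motifs(G, 2, u=u)]
    a = dim_with_input(st, ext, c0=1.0, strengths=[0.0], g=10.0).raw
    assert a == pytest.approx(dim_from_cumulants(st).raw, rel=1e-12)


def test_dim_with_input_pure_input_limit():
    """Uncoupled network, vanishing noise: Dim equals the factor count."""
    N = 12
    G = np.zeros((N, N))
    F = np.eye(N)[:3]
    st_int = measure_motifs(G, 2)
    ext = [measure_motifs(G, 2, u=f) for f in F]
    res = dim_with_input(st_int, ext, c0=1e-9, strengths=[0.4] * 3, g=1.0)
    assert res.raw == pytest.approx(3.0, rel=1e-6)


def test_eq24_inequality_chain(rng):
    """The bounds behind the high-dimensional-input approximation.

    The Cauchy-Schwarz part Tr(C_int C_ext)^2 <= Tr(C_int^2) Tr(C_ext^2)
    holds for any PSD pair.  The outer bound by (Tr C_int + Tr C_ext)^2 / 2
    is not scale-invariant; it holds in the unit-variance normalization the
    theory works in (covariances near c0 I with high-dimensional spectra),
    which is what the approximation exploits.
    """
    for _ in range(10):
        Ci = random_psd(rng, 30)
        Ce = random_psd(rng, 30, rank=5)
        cross2 = float(np.sum(Ci * Ce)) ** 2
        mid = float(np.sum(Ci * Ci)) * float(np.sum(Ce * Ce))
        assert cross2 <= mid * (1 + 1e-12)
    for n in (10, 30, 50):
        # unit-variance, high-dimensional pair: the full chain holds
        Ci, Ce = np.eye(n), np.eye(n)
        cross2 = float(np.sum(Ci * Ce)) ** 2
        mid = float(np.sum(Ci * Ci)) * float(np.sum(Ce * Ce))
        right = 0.5 * (np.trace(Ci) + np.trace(Ce)) ** 2
        assert cross2 <= mid <= right


def test_highdim_approx_limits():
    # no input: reduces to the internal-only participation ratio
    res = highdim_input_approx(10.0, 0.0, 4.0, 0.0, n_neurons=30)
    assert res.raw == pytest.approx(100.0 / 4.0)
    assert res.method == "cumulant_highdim"
    # identity traces: substituted cross sqrt(2) N exceeds the true N,
    # so the approximate denominator exceeds the true one
    N = 20
    true_denom = N + N + 2 * N
    approx = highdim_input_approx(N, N, N, N, n_neurons=N)
    approx_denom = (2 * N) ** 2 / approx.raw
    assert approx_denom > true_denom


def test_leading_eigenvector_weighting(rng):
    """The leading Schur direction of a Perron-dominated matrix is its
    Perron vector, and weighted tables accept it."""
    from motifdim.motifs import leading_eigenvector
    G = random_subcritical(rng, 25, radius=0.6)
    u = leading_eigenvector(G, 1)[0]
    lam = np.abs(np.linalg.eigvals(G)).max()
    # invariant direction: G u is parallel to u with the Perron eigenvalue
    ratio = (G @ u) @ u
    assert abs(abs(ratio) - lam) < 1e-8
    st = measure_motifs(G, 2, u=u)
    # weighted first chain moment is the Rayleigh quotient
    assert st.moments["chain"][1] == pytest.approx(ratio, rel=1e-10)


def test_statistics_json_roundtrip(rng):
    G = random_subcritical(rng, 8, radius=0.4)
    st = measure_motifs(G, 3)
    st2 = MotifStatistics.from_json(st.to_json())
    for key in st.moments:
        assert np.allclose(st.moments[key], st2.moments[key])
        assert np.allclose(st.cumulants[key], st2.cumulants[key])
    assert dim_from_cumulants(st2).raw == pytest.approx(
        dim_from_cumulants(st).raw)
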