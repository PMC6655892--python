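"""Ensemble studies: dimensionality sweeps, cumulant regressions, stimuli.

Reproduces the package's headline analyses:

* ``run_sonet_ensemble`` -- ensembles of SONET networks with sampled motif
  biases; per network the exact linear-response dimensionality, its
  second-order cumulant prediction, the average correlation <C>/c0 and the
  measured cumulant statistics.
* ``regress_dim_on_cumulants`` -- ordinary least squares of dimensionality
  (relative to an ER reference) on the six connectivity regressors:
  connection-density offset, second-order chain, convergent and divergent
  cumulants, and the two trace-cumulant sums.
* ``stimulus_sweep`` -- response dimensionality against stimulus strength
  or stimulus dimensionality, exact and in both cumulant approximations.
* ``run_ei_ensemble`` -- balanced excitatory/inhibitory ensembles and the
  regression of dimensionality on inhibitory-block cumulants.
* ``dim_vs_correlation`` -- binned dimensionality-versus-average-correlation
  summaries.
* ``make_fixture`` -- tiny networks with brute-force expected values for
  testing.

Every experiment is a pure function of its configuration and master seed;
per-network child seeds are drawn from the master stream and recorded, and
unstable draws are dropped with their count reported, never silently.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd

from .exceptions import MotifDimError, ParameterError
from .linear_response import EffectiveNetwork, StimulusModel, propagator
from .motifs import (_resummed, dim_from_cumulants, dim_with_input,
                     er_closed_form, highdim_input_approx, measure_motifs,
                     traces_from_cumulants)
from .networks import SonetParams, balance_ei, generate_er, generate_sonet

__all__ = [
    "ALPHA_RANGES", "PRESETS", "EnsembleResult", "RegressionResult",
    "run_sonet_ensemble", "regress_dim_on_cumulants", "stimulus_sweep",
    "run_ei_ensemble", "dim_vs_correlation", "make_fixture",
    "REGRESSOR_NAMES",
]

#: motif-bias sampling ranges of the reference SONET ensembles
ALPHA_RANGES = {
    "alpha_recip": (-1.0, 4.0),
    "alpha_conv": (0.0, 1.0),
    "alpha_div": (0.0, 1.0),
    "alpha_chain": (-1.0, 1.0),
}

#: named ensemble configurations; "*-small" are scaled-down fast presets
PRESETS = {
    "methods-d": dict(n_networks=500, n_neurons=1000, p_range=(0.01, 0.1)),
    "methods-e": dict(n_networks=500, n_neurons=1000, p_range=(0.078, 0.082)),
    "methods-i": dict(n_networks=500, n_neurons=1000, p_range=(0.027, 0.033),
                      ei=True),
    "methods-d-small": dict(n_networks=150, n_neurons=1000,
                            p_range=(0.01, 0.1)),
    "methods-e-small": dict(n_networks=100, n_neurons=500,
                            p_range=(0.078, 0.082)),
    "methods-i-small": dict(n_networks=150, n_neurons=1000,
                            p_range=(0.027, 0.033), ei=True),
}

REGRESSOR_NAMES = ["dp", "kch2", "kconv", "kdiv", "ktr2", "ktr4"]


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    """OLS fit of dimensionality against cumulant regressors."""

    coefficients: dict
    r_squared: float
    baseline: str
    n_records: int
    condition_number: float


@dataclasses.dataclass(frozen=True)
class EnsembleResult:
    """Ensemble records plus bookkeeping.

    ``records`` has one row per retained (stable) network; ``n_dropped``
    counts unstable draws, ``n_failed`` infeasible generator draws.
    """

    records: pd.DataFrame
    n_dropped: int
    n_failed: int
    config: dict


def _exact_summary(net: EffectiveNetwork) -> dict:
    """Exact trace quantities of C_int from one propagator solve."""
    D = propagator(net)
    c0 = net.c0
    trc = c0 * float(np.sum(D * D))
    M = D.T @ D
    trc2 = c0 * c0 * float(np.sum(M * M))
    col = D.sum(axis=0)
    mean_c = c0 * float(col @ col) / net.n_neurons ** 2
    n = net.n_neurons
    return {
        "trC": trc, "trC2": trc2,
        "dim_exact": (trc * trc / trc2) / n,
        "avg_correlation": mean_c / c0,
    }


def _cumulant_record(G: np.ndarray, c0: float) -> dict:
    """Second-order cumulant statistics and the dimensionality they predict."""
    st = measure_motifs(G, max_order=2)
    k = st.cumulants
    rec = {
        "kch1": float(k["chain"][1]),
        "kch2": float(k["chain"][2]),
        "kconv": float(k["convergent"][1, 1]),
        "kdiv": float(k["divergent"][1, 1]),
        "krecip": float(k["reciprocal"][2]),
        # the two trace-cumulant sums of the Tr C and Tr C^2 series
        # (all order-1 and order-2 entries beyond the universal 1 - 1/N)
        "ktr2": float(k["trace"].sum() - k["trace"][0, 0]),
        "ktr4": float(k["trace4"][1:].sum()),
    }
    try:
        rec["dim_cumulant"] = dim_from_cumulants(st, c0).normalized
    except MotifDimError:
        rec["dim_cumulant"] = np.nan
    return rec


def _sample_params(rng: np.random.Generator, p_range, alpha_ranges) -> SonetParams:
    a = {name: float(rng.uniform(*alpha_ranges[name])) for name in ALPHA_RANGES}
    return SonetParams(p=float(rng.uniform(*p_range)), **a)


def run_sonet_ensemble(n_networks: int, n_neurons: int, p_range=(0.01, 0.1),
                       alpha_ranges: dict | None = None, c0: float = 1.0,
                       gain: float = 10.0, seed: int = 0,
                       weight: float | None = None) -> EnsembleResult:
    """Ensemble of excitatory SONET networks with sampled motif biases.

    Per network: exact dimensionality (normalized), its order-2 cumulant
    prediction, average correlation, measured cumulants and spectral radius.
    Networks with spectral radius >= 1 are dropped and counted.
    """
    if alpha_ranges is None:
        alpha_ranges = ALPHA_RANGES
    rng = np.random.default_rng(seed)
    rows = []
    n_dropped = n_failed = 0
    i = -1
    # draw until the requested ensemble size is reached; infeasible motif
    # combinations (rejected by the strict sampler, as the reference SONET
    # algorithm does) and unstable networks are redrawn and counted
    while len(rows) < n_networks and i < 10 * n_networks:
        i += 1
        child = int(rng.integers(2 ** 31))
        params = _sample_params(rng, p_range, alpha_ranges)
        try:
            conn = generate_sonet(n_neurons, params, weight=weight,
                                  seed=child, strict=True)
        except MotifDimError:
            n_failed += 1
            continue
        net = EffectiveNetwork.from_connectivity(conn, gain=gain, c0=c0)
        if not net.stable:
            n_dropped += 1
            continue
        row = {"network_id": i, "seed": child, "p": params.p,
               "p_hat": conn.density(),
               "alpha_recip": params.alpha_recip,
               "alpha_conv": params.alpha_conv,
               "alpha_div": params.alpha_div,
               "alpha_chain": params.alpha_chain,
               "spectral_radius": net.spectral_radius}
        row.update(_exact_summary(net))
        row.update(_cumulant_record(net.G, c0))
        rows.append(row)
    if not rows:
        raise MotifDimError("empty ensemble: every draw was unstable or "
                            "infeasible")
    cfg = dict(n_networks=n_networks, n_neurons=n_neurons, p_range=p_range,
               alpha_ranges=alpha_ranges, c0=c0, gain=gain, seed=seed,
               weight=weight)
    return EnsembleResult(records=pd.DataFrame(rows), n_dropped=n_dropped,
                          n_failed=n_failed, config=cfg)


def regress_dim_on_cumulants(records: pd.DataFrame,
                             baseline: tuple[int, float] | None = None,
                             regressors: list[str] | None = None,
                             p_column: str = "p_hat",
                             gain: float = 10.0) -> RegressionResult:
    """OLS of dimensionality against the six connectivity regressors.

    ``baseline`` is the ER reference (N, p_ER); the regressand is the
    normalized dimensionality minus the ER closed-form value at p_ER and the
    density regressor is ``p - p_ER``.  Regressors are left unstandardized
    so the coefficients are directly comparable to the analytic Taylor
    sensitivities.  A large design condition number triggers a collinearity
    warning -- expected for the two trace cumulants, which are tightly
    correlated by construction.
    """
    import statsmodels.api as sm

    if regressors is None:
        regressors = REGRESSOR_NAMES
    if len(records) < 2 * len(regressors):
        raise ParameterError("need at least twice as many records as "
                             "regressors")
    df = records
    if baseline is not None:
        n_ref, p_ref = baseline
        # effective coupling of the reference: rho = gain * (1/N) * N * p
        rho_ref = gain * p_ref
        y = df["dim_exact"] - er_closed_form(n_ref, rho_ref).normalized
        base_desc = f"er:N={n_ref},p={p_ref}"
    else:
        p_ref = float(df[p_column].mean())
        y = df["dim_exact"]
        base_desc = "none"
    X = pd.DataFrame(index=df.index)
    for name in regressors:
        if name == "dp":
            X["dp"] = df[p_column] - p_ref
        else:
            X[name] = df[name]
    Xc = sm.add_constant(X)
    fit = sm.OLS(np.asarray(y, dtype=float), np.asarray(Xc)).fit()
    cond = float(np.linalg.cond(np.asarray(Xc)))
    if cond > 1e8:
        warnings.warn(f"regression design is ill-conditioned (condition "
                      f"number {cond:.3g}); coefficients of correlated "
                      "regressors are individually unreliable", stacklevel=2)
    coefs = {"const": float(fit.params[0])}
    coefs.update({name: float(v) for name, v in zip(X.columns, fit.params[1:])})
    return RegressionResult(coefficients=coefs, r_squared=float(fit.rsquared),
                            baseline=base_desc, n_records=len(df),
                            condition_number=cond)


def stimulus_sweep(net: EffectiveNetwork, mode: str, grid,
                   seed: int = 0, c_xi: float = 0.05,
                   total_strength: float = 2.5, orthonormal: bool = True,
                   max_order: int = 2) -> pd.DataFrame:
    """Response dimensionality along a stimulus grid.

    Modes (``grid`` entries are numbers of factors, except for
    ``vary_strength_one_factor`` where they are strengths):

    * ``vary_factors_fixed_per_factor``: N_inp factors each of strength
      ``c_xi`` -- input dimension and total power grow together.
    * ``vary_strength_one_factor``: one factor of growing strength.
    * ``vary_factors_fixed_total``: N_inp factors with total strength
      sqrt(sum c_i^2) = total_strength * c0 split evenly.

    Factors are drawn once and nested along the grid; by default they are
    orthonormalized (an input with N factors then spans N dimensions
    exactly, so the full-grid endpoint recovers the internal
    dimensionality).  With ``orthonormal=False`` independent random unit
    vectors are used; note N of them carry a Marchenko-Pastur eigenvalue
    spread, capping the input's own participation ratio near N/2.
    Each grid point reports the exact decomposed dimensionality and the
    low- and high-dimensional-input cumulant approximations, all normalized
    by N.
    """
    modes = ("vary_factors_fixed_per_factor", "vary_strength_one_factor",
             "vary_factors_fixed_total")
    if mode not in modes:
        raise ParameterError(f"mode must be one of {modes}")
    net.require_stable()
    N = net.n_neurons
    c0 = net.c0
    grid = list(grid)
    if mode == "vary_strength_one_factor":
        n_max = 1
    else:
        n_max = int(max(grid))
        if n_max < 1:
            raise ParameterError("grid must request at least one factor")
    stim_all = StimulusModel.random(N, n_max, 1.0, seed=seed,
                                    orthonormal=orthonormal)
    F = stim_all.factors

    D = propagator(net)
    trci = c0 * float(np.sum(D * D))
    M = D.T @ D
    trci2 = c0 * c0 * float(np.sum(M * M))
    B = D @ F.T                      # Delta xi_i
    E = D.T @ B                      # Delta^T Delta xi_i
    bb = B.T @ B                     # Gram of the propagated factors

    # internal cumulant traces (for the approximations)
    st_int = measure_motifs(net.G, max_order)
    trci_th, trci2_th = traces_from_cumulants(st_int, c0)
    st_ext = [measure_motifs(net.G, max_order, u=F[i]) for i in range(n_max)]

    g2 = net.g ** 2
    rows = []
    for x in grid:
        if mode == "vary_strength_one_factor":
            k, c = 1, np.array([float(x)])
        elif mode == "vary_factors_fixed_per_factor":
            k = int(x)
            c = np.full(k, c_xi)
        else:
            k = int(x)
            c = np.full(k, total_strength * c0 / math.sqrt(max(k, 1)))
        if k == 0:
            k, c = 0, np.zeros(0)
        # exact external traces
        tce = g2 * float(np.sum(c * np.diag(bb)[:k]))
        sub = bb[:k, :k] * np.sqrt(c)[None, :] * np.sqrt(c)[:, None]
        tce2 = g2 * g2 * float(np.sum(sub * sub))
        cross = c0 * g2 * float(np.sum(c * np.sum(E[:, :k] ** 2, axis=0)))
        dim_exact = (trci + tce) ** 2 / (trci2 + tce2 + 2 * cross) / N

        low = dim_with_input(st_int, st_ext[:k], c0, c, g=net.g)
        # external theory traces for the high-dimensional-input bound
        te = te2 = 0.0
        for st_f, ci in zip(st_ext[:k], c):
            r, Df, Vf, _, _ = _resummed(st_f)
            t = g2 * ci * r * r * (1.0 + Vf)
            te += t
            te2 += t * t
        high = highdim_input_approx(trci_th, te, trci2_th, te2, n_neurons=N)
        rows.append({"param": float(x), "n_factors": k,
                     "strength_per_factor": float(c[0]) if k else 0.0,
                     "dim_exact": dim_exact,
                     "dim_lowdim": low.normalized,
                     "dim_highdim": high.normalized})
    return pd.DataFrame(rows)


def run_ei_ensemble(n_networks: int, n_neurons: int,
                    p_range=(0.027, 0.033), frac_inhib: float = 0.1,
                    g_scale: float | None = None,
                    alpha_ranges: dict | None = None, c0: float = 1.0,
                    seed: int = 0) -> tuple[EnsembleResult, RegressionResult]:
    """Balanced E-I SONET ensemble and the inhibitory-cumulant regression.

    Networks are SONET graphs at excitatory connectivity sampled
    perturbatively around p = 0.03 with Methods-d motif ranges; a random
    ``frac_inhib`` of neurons is made inhibitory with outgoing magnitude
    (N_E/N_I) x excitatory, and the synaptic scale promoted to the
    strong-coupling default 1.25/sqrt(N).  The effective connectivity is the
    balanced matrix itself (gain folded into the synaptic scale).

    The normalized dimensionality is regressed on the six second-order
    cumulant statistics of the inhibitory-to-inhibitory block.

    ``frac_inhib = 0`` degenerates to the purely excitatory ensemble with
    the standard 1/N + gain-10 convention (delegates to
    :func:`run_sonet_ensemble`).
    """
    import statsmodels.api as sm

    if frac_inhib == 0.0:
        res = run_sonet_ensemble(n_networks, n_neurons, p_range,
                                 alpha_ranges, c0=c0, seed=seed)
        reg = regress_dim_on_cumulants(res.records,
                                       baseline=(n_neurons,
                                                 float(np.mean(p_range))))
        return res, reg
    if alpha_ranges is None:
        alpha_ranges = ALPHA_RANGES
    rng = np.random.default_rng(seed)
    rows = []
    n_dropped = n_failed = 0
    i = -1
    while len(rows) < n_networks and i < 10 * n_networks:
        i += 1
        child = int(rng.integers(2 ** 31))
        params = _sample_params(rng, p_range, alpha_ranges)
        try:
            conn = generate_sonet(n_neurons, params, seed=child, strict=True)
            bal = balance_ei(conn, frac_inhib=frac_inhib, g_scale=g_scale,
                             seed=(child + 1) % 2 ** 31)
        except MotifDimError:
            n_failed += 1
            continue
        net = EffectiveNetwork(G=bal.weights, c0=c0, g=1.0)
        if not net.stable:
            n_dropped += 1
            continue
        inhib = np.flatnonzero(bal.population == "I")
        G_ii = bal.weights[np.ix_(inhib, inhib)]
        st_ii = measure_motifs(G_ii, max_order=2)
        k = st_ii.cumulants
        row = {"network_id": i, "seed": child, "p": params.p,
               "p_hat": conn.density(),
               "p_ii": float((G_ii != 0).sum()
                             / (len(inhib) * (len(inhib) - 1))),
               "spectral_radius": net.spectral_radius,
               "kch1_ii": float(k["chain"][1]),
               "kch2_ii": float(k["chain"][2]),
               "kconv_ii": float(k["convergent"][1, 1]),
               "kdiv_ii": float(k["divergent"][1, 1]),
               "ktr2_ii": float(k["trace"].sum() - k["trace"][0, 0]),
               "ktr4_ii": float(k["trace4"][1:].sum())}
        row.update(_exact_summary(net))
        row.update(_cumulant_record(net.G, c0))
        rows.append(row)
    if not rows:
        raise MotifDimError("empty ensemble: every draw was unstable or "
                            "infeasible")
    df = pd.DataFrame(rows)
    regressors = ["kch1_ii", "kch2_ii", "kconv_ii", "kdiv_ii", "ktr2_ii",
                  "ktr4_ii"]
    X = sm.add_constant(np.asarray(df[regressors], dtype=float))
    fit = sm.OLS(np.asarray(df["dim_exact"], dtype=float), X).fit()
    coefs = {"const": float(fit.params[0])}
    coefs.update({n: float(v) for n, v in zip(regressors, fit.params[1:])})
    reg = RegressionResult(coefficients=coefs,
                           r_squared=float(fit.rsquared),
                           baseline=f"ei:p={np.mean(p_range):.3f}",
                           n_records=len(df),
                           condition_number=float(np.linalg.cond(X)))
    cfg = dict(n_networks=n_networks, n_neurons=n_neurons, p_range=p_range,
               frac_inhib=frac_inhib, g_scale=g_scale, c0=c0, seed=seed)
    return EnsembleResult(records=df, n_dropped=n_dropped, n_failed=n_failed,
                          config=cfg), reg


def dim_vs_correlation(records: pd.DataFrame, bins=12) -> pd.DataFrame:
    """Median normalized dimensionality per average-correlation bin."""
    if len(records) < 10:
        raise ParameterError("need at least 10 records")
    corr = np.asarray(records["avg_correlation"], dtype=float)
    dim = np.asarray(records["dim_exact"], dtype=float)
    edges = np.histogram_bin_edges(corr, bins=bins) if np.isscalar(bins) \
        else np.asarray(bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (corr >= lo) & (corr < hi)
        if not sel.any():
            continue
        rows.append({"corr_lo": lo, "corr_hi": hi,
                     "corr_center": 0.5 * (lo + hi),
                     "median_dim": float(np.median(dim[sel])),
                     "n": int(sel.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tiny fixtures with independently computed expectations
# ---------------------------------------------------------------------------

def _brute_force_expected(G: np.ndarray, c0: float) -> dict:
    """Loop-based covariance/dimensionality oracle (no linear_response code)."""
    N = G.shape[0]
    D = np.linalg.inv(np.eye(N) - G)
    C = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            for k in range(N):
                C[i, j] += c0 * D[i, k] * D[j, k]
    lam = np.linalg.eigvalsh(0.5 * (C + C.T))
    return {"C_int": C, "dim_raw": float(lam.sum() ** 2 / (lam ** 2).sum()),
            "trC": float(lam.sum()), "trC2": float((lam ** 2).sum())}


def _brute_force_moments(G: np.ndarray) -> dict:
    """Triple-loop motif moments (scaled normalization) for N <= ~25."""
    N = G.shape[0]
    u = np.full(N, 1.0 / math.sqrt(N))
    G2 = G @ G
    out = {"chain1": 0.0, "chain2": 0.0, "div11": 0.0, "conv11": 0.0,
           "trace11": 0.0, "trace20": 0.0}
    for i in range(N):
        for j in range(N):
            out["chain1"] += u[i] * G[i, j] * u[j]
            out["chain2"] += u[i] * G2[i, j] * u[j]
            out["trace11"] += G[i, j] * G[i, j] / N
            out["trace20"] += G[i, j] * G[j, i] / N
            for k in range(N):
                out["div11"] += u[i] * G[i, k] * G[j, k] * u[j]
                out["conv11"] += u[i] * G[k, i] * G[k, j] * u[j]
    return out


def make_fixture(kind: str, seed: int = 0):
    """Small (N <= 20) networks bundled with brute-force expected values.

    Returns ``(EffectiveNetwork, expected)`` where ``expected`` holds the
    exact internal covariance, dimensionality and motif moments computed by
    explicit loops, independent of the package's vectorized code paths.
    """
    if kind == "chain2":
        G = np.array([[0.0, 0.0], [0.5, 0.0]])
        net = EffectiveNetwork(G=G, c0=1.0, g=1.0)
        expected = _brute_force_expected(G, 1.0)
        expected["propagator"] = np.array([[1.0, 0.0], [0.5, 1.0]])
        expected["C_int_hand"] = np.array([[1.0, 0.5], [0.5, 1.25]])
        return net, expected
    if kind == "er_small":
        conn = generate_er(10, 0.3, seed=seed)
        net = EffectiveNetwork.from_connectivity(conn, gain=2.0)
        return net, _brute_force_expected(net.G, 1.0)
    if kind == "sonet_small":
        conn = generate_sonet(20, SonetParams(p=0.25, alpha_recip=2.0,
                                              alpha_conv=0.5,
                                              alpha_chain=0.5), seed=seed)
        net = EffectiveNetwork.from_connectivity(conn, gain=0.6)
        expected = _brute_force_expected(net.G, 1.0)
        expected["moments"] = _brute_force_moments(net.G)
        return net, expected
    if kind == "ei_small":
        conn = generate_er(20, 0.4, seed=seed)
        bal = balance_ei(conn, frac_inhib=0.25, g_scale=0.05, seed=seed)
        net = EffectiveNetwork(G=bal.weights, c0=1.0, g=1.0)
        expected = _brute_force_expected(net.G, 1.0)
        expected["population"] = bal.population
        return net, expected
    raise ParameterError(f"unknown fixture kind {kind!r}")
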