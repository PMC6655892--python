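"""Random connectivity generators and empirical motif statistics.

Directed, weighted synaptic connectivity matrices ``W`` with the convention
that ``W[i, j]`` is the strength of the synapse from neuron ``j`` onto neuron
``i`` (so matrix powers accumulate multi-step paths ending at the row index).
Self-connections are always forbidden.

Four graph families are provided:

* Erdos-Renyi (``generate_er``): every ordered pair connected independently
  with probability p.
* SONET (``generate_sonet``): an ER-like ensemble whose four second-order
  motif frequencies (reciprocal, convergent, divergent, chain) are biased
  away from the p^2 baseline by parameters alpha.  Sampled here by
  thresholding a correlated latent Gaussian field ("dichotomized Gaussian"):
  per-edge noise plus per-node in/out factors, a symmetric pair factor, and
  a node-level in/out correlation realize any feasible combination of the
  four pairwise latent correlations exactly.  With all alphas zero the
  construction reduces to iid Bernoulli edges, i.e. exactly ER.
* Watts-Strogatz small world and Barabasi-Albert scale free
  (``generate_small_world`` / ``generate_scale_free``), via networkx,
  symmetrized to directed matrices.

``balance_ei`` converts a purely excitatory matrix into a balanced
excitatory/inhibitory network: a random fraction of neurons becomes
inhibitory with outgoing weight magnitude scaled so the mean synaptic input
per neuron cancels, and the overall synaptic scale is promoted to the
strong-coupling 1/sqrt(N) regime.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import owens_t
from scipy.stats import norm

from .exceptions import FeasibilityError, ParameterError, ValidationError

__all__ = [
    "ConnectivityMatrix",
    "SonetParams",
    "generate_er",
    "generate_sonet",
    "generate_small_world",
    "generate_scale_free",
    "balance_ei",
    "motif_frequencies",
]


@dataclasses.dataclass
class ConnectivityMatrix:
    """An N x N synaptic weight matrix with structural metadata.

    Invariants: zero diagonal; finite entries; columns of inhibitory neurons
    are <= 0 and columns of excitatory neurons are >= 0.
    """

    weights: np.ndarray
    population: np.ndarray  # per-neuron label, "E" or "I"
    generator: str = "unknown"
    seed: int | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        W = self.weights
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValidationError(f"weights must be square, got {W.shape}")
        if not np.all(np.isfinite(W)):
            raise ValidationError("weights contain non-finite entries")
        if np.any(np.diag(W) != 0.0):
            raise ValidationError("self-connections are forbidden (nonzero diagonal)")
        self.population = np.asarray(self.population)
        if self.population.shape != (W.shape[0],):
            raise ValidationError("population labels must be one per neuron")
        exc = self.population == "E"
        if np.any(W[:, exc] < 0):
            raise ValidationError("excitatory columns must be nonnegative")
        if np.any(W[:, ~exc] > 0):
            raise ValidationError("inhibitory columns must be nonpositive")

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        """Binary adjacency (presence of a synapse, any sign)."""
        return (self.weights != 0.0).astype(np.int8)

    def density(self) -> float:
        """Fraction of ordered off-diagonal pairs that carry a synapse."""
        n = self.n_neurons
        return float(np.count_nonzero(self.weights)) / (n * (n - 1))


@dataclasses.dataclass(frozen=True)
class SonetParams:
    """Connection probability and second-order motif biases.

    A motif bias ``alpha_x`` requests the corresponding two-edge pattern to
    occur with probability ``p^2 (1 + alpha_x)`` instead of the independent
    baseline ``p^2``.
    """

    p: float
    alpha_recip: float = 0.0
    alpha_conv: float = 0.0
    alpha_div: float = 0.0
    alpha_chain: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError(f"connection probability p={self.p} not in [0, 1]")
        for name in ("alpha_recip", "alpha_conv", "alpha_div", "alpha_chain"):
            a = getattr(self, name)
            if a < -1.0:
                raise FeasibilityError(
                    f"{name}={a} < -1 would require negative motif probability")


def _default_weight(n: int) -> float:
    # Per-synapse weight 1/N: with gain g=10 an ER network has spectral
    # radius ~ 10 p, approaching 1 at p = 0.1.
    return 1.0 / n


def _labels(n: int) -> np.ndarray:
    return np.full(n, "E", dtype="<U1")


def generate_er(n_neurons: int, p: float, weight: float | None = None,
                seed: int | None = None) -> ConnectivityMatrix:
    """Erdos-Renyi directed graph: each ordered pair connected w.p. ``p``."""
    if n_neurons < 2:
        raise ParameterError("need at least 2 neurons")
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"connection probability p={p} not in [0, 1]")
    w = _default_weight(n_neurons) if weight is None else float(weight)
    rng = np.random.default_rng(seed)
    A = rng.random((n_neurons, n_neurons)) < p
    np.fill_diagonal(A, False)
    return ConnectivityMatrix(
        weights=A * w, population=_labels(n_neurons),
        generator="er", seed=seed, meta={"p": p, "weight": w})


# ---------------------------------------------------------------------------
# SONET sampling via a dichotomized Gaussian
# ---------------------------------------------------------------------------

def _orthant_prob(theta: float, lam: float, p: float) -> float:
    """P(X > theta, Y > theta) for standard bivariate normal with corr lam.

    Uses Owen's T closed form: P = p - 2 T(theta, sqrt((1-lam)/(1+lam)))
    with p = Phi(-theta); exact to machine precision and fast.
    """
    if lam >= 1.0:
        return p
    if lam <= -1.0:
        return max(0.0, 2.0 * p - 1.0)
    a = math.sqrt((1.0 - lam) / (1.0 + lam))
    return p - 2.0 * float(owens_t(theta, a))


_LAT_MAX = 0.999999


def _latent_corr(alpha: float, p: float, theta: float, name: str) -> float:
    """Latent correlation that makes the joint edge probability p^2 (1+alpha).

    Targets at (or numerically below) the perfectly anticorrelated floor are
    clamped to the extreme correlation; targets at or above the single-edge
    probability p are unreachable for any correlation and raise.
    """
    if alpha == 0.0:
        return 0.0
    target = p * p * (1.0 + alpha)
    if target >= p:
        raise FeasibilityError(
            f"{name}={alpha}: requested motif probability p^2(1+alpha)="
            f"{target:.4g} >= p={p:.4g} is unreachable")
    if target <= _orthant_prob(theta, -_LAT_MAX, p):
        return -_LAT_MAX
    if target >= _orthant_prob(theta, _LAT_MAX, p):
        return _LAT_MAX
    return float(brentq(lambda l: _orthant_prob(theta, l, p) - target,
                        -_LAT_MAX, _LAT_MAX, xtol=1e-12))


def generate_sonet(n_neurons: int, params: SonetParams,
                   weight: float | None = None,
                   seed: int | None = None,
                   strict: bool = False) -> ConnectivityMatrix:
    """Sample a SONET graph with the requested second-order motif biases.

    The latent field for edge j -> i is

        X_ij = a eps_ij + b u_i + c v_j + d s_ij w_{ij}

    with iid standard normal ``eps``, per-node in-factor ``u`` and out-factor
    ``v`` (correlated rho at the same node), a symmetric pair factor ``w``
    and a global sign ``s`` on its lower triangle.  An edge exists when
    ``X_ij`` exceeds the p-quantile threshold.  The four pairwise latent
    correlations (b^2 convergent, c^2 divergent, b c rho chain,
    2 b c rho +/- d^2 reciprocal) are solved from the alphas through the
    exact bivariate-normal orthant probability.

    When the chain target exceeds the sqrt(conv * div) bound the node-factor
    variances are minimally inflated to accommodate it, which raises the
    realized convergent/divergent frequencies above their targets; downstream
    theory always consumes *measured* motif statistics, so this only widens
    the ensemble.  A variance budget violation (b^2+c^2+d^2 > 1) raises
    :class:`FeasibilityError`.
    """
    if n_neurons < 3:
        raise ParameterError("need at least 3 neurons for second-order motifs")
    p = params.p
    w = _default_weight(n_neurons) if weight is None else float(weight)
    rng = np.random.default_rng(seed)

    if p == 0.0 or p == 1.0:
        return dataclasses.replace(
            generate_er(n_neurons, p, w, seed), generator="sonet",
            meta={"params": dataclasses.asdict(params), "weight": w})

    theta = float(norm.ppf(1.0 - p))
    lam_conv = _latent_corr(params.alpha_conv, p, theta, "alpha_conv")
    lam_div = _latent_corr(params.alpha_div, p, theta, "alpha_div")
    lam_ch = _latent_corr(params.alpha_chain, p, theta, "alpha_chain")
    lam_rec = _latent_corr(params.alpha_recip, p, theta, "alpha_recip")

    if lam_conv < 0 or lam_div < 0:
        # equicorrelation of ~N variables: negative values are infeasible
        bad = "alpha_conv" if lam_conv < 0 else "alpha_div"
        raise FeasibilityError(f"{bad} < 0 requires negative equicorrelation "
                               "across a node's edges, which is infeasible")

    if lam_conv + lam_div > 0.9:
        raise FeasibilityError(
            "alpha_conv and alpha_div jointly exceed the latent variance "
            f"budget (required node-factor variance {lam_conv + lam_div:.3f})")

    b2, c2 = lam_conv, lam_div
    if lam_ch != 0.0:
        bound = math.sqrt(b2 * c2)
        if bound < abs(lam_ch):
            if strict:
                raise FeasibilityError(
                    f"alpha_chain={params.alpha_chain}: required latent "
                    f"chain correlation {lam_ch:.3f} exceeds the "
                    f"sqrt(conv*div) bound {bound:.3f} set by alpha_conv/"
                    "alpha_div")
            # inflate the node factors (minimally) so b*c can carry lam_ch
            if b2 == 0.0 and c2 == 0.0:
                b2 = c2 = abs(lam_ch)
            elif b2 == 0.0:
                b2 = lam_ch * lam_ch / c2
            elif c2 == 0.0:
                c2 = lam_ch * lam_ch / b2
            else:
                infl = abs(lam_ch) / bound
                b2 *= infl
                c2 *= infl
    # cap node-factor variance, realizing an extreme chain bias only as far
    # as the budget allows (realized values are recorded in meta)
    cap = 0.9
    if b2 + c2 > cap:
        shrink = cap / (b2 + c2)
        b2 *= shrink
        c2 *= shrink
    b, c = math.sqrt(b2), math.sqrt(c2)
    rho_uv = 0.0 if b * c == 0.0 else float(np.clip(lam_ch / (b * c), -1.0, 1.0))

    resid = lam_rec - 2.0 * b * c * rho_uv
    sign = 1.0 if resid >= 0.0 else -1.0
    if strict and abs(resid) > 1.0 - b2 - c2:
        raise FeasibilityError(
            f"alpha_recip={params.alpha_recip}: required pair-factor "
            f"variance {abs(resid):.3f} exceeds the remaining latent "
            f"budget {1.0 - b2 - c2:.3f}")
    d2 = min(abs(resid), 1.0 - b2 - c2)

    a2 = 1.0 - b2 - c2 - d2

    n = n_neurons
    X = math.sqrt(a2) * rng.standard_normal((n, n))
    if b2 > 0 or c2 > 0:
        u = rng.standard_normal(n)
        v = rho_uv * u + math.sqrt(max(0.0, 1.0 - rho_uv ** 2)) * \
            rng.standard_normal(n)
        X += b * u[:, None] + c * v[None, :]
    if d2 > 0:
        pair = rng.standard_normal((n, n))
        upper = np.triu(pair, 1)
        X += math.sqrt(d2) * (upper + sign * upper.T)

    A = X > theta
    np.fill_diagonal(A, False)
    return ConnectivityMatrix(
        weights=A * w, population=_labels(n),
        generator="sonet", seed=seed,
        meta={"params": dataclasses.asdict(params), "weight": w,
              "latent": {"b2": b2, "c2": c2, "d2": d2, "rho_uv": rho_uv,
                         "recip_sign": sign}})


def generate_small_world(n_neurons: int, p: float, rewiring: float,
                         seed: int | None = None,
                         weight: float | None = None) -> ConnectivityMatrix:
    """Watts-Strogatz ring lattice with rewiring, symmetrized to directed.

    The (even) ring degree is ``round(p * n)`` so the directed connection
    density approximates ``p``; rewiring preserves the edge count.
    """
    import networkx as nx

    k = int(round(p * n_neurons))
    if k < 2:
        raise ParameterError(
            f"p*n = {p * n_neurons:.2f} < 2: ring-lattice degree too small")
    if not 0.0 <= rewiring <= 1.0:
        raise ParameterError("rewiring probability must be in [0, 1]")
    w = _default_weight(n_neurons) if weight is None else float(weight)
    g = nx.watts_strogatz_graph(n_neurons, k, rewiring, seed=seed)
    A = nx.to_numpy_array(g, dtype=float)
    np.fill_diagonal(A, 0.0)
    return ConnectivityMatrix(
        weights=(A > 0) * w, population=_labels(n_neurons),
        generator="smallworld", seed=seed,
        meta={"p": p, "rewiring": rewiring, "weight": w, "ring_degree": k})


def generate_scale_free(n_neurons: int, p: float, seed: int | None = None,
                        weight: float | None = None) -> ConnectivityMatrix:
    """Barabasi-Albert preferential attachment at total density ~ p.

    The attachment count m solves m (N - m) = p N^2 / 2 (undirected edge
    budget); the smaller quadratic root is taken so m << N.
    """
    import networkx as nx

    N = n_neurons
    disc = N * N - 2.0 * p * N * N
    if disc < 0:
        raise ParameterError(f"density p={p} too large: no real attachment count")
    m = int(round((N - math.sqrt(disc)) / 2.0))
    if m < 1:
        raise ParameterError(f"density p={p} too small: attachment count m < 1")
    w = _default_weight(N) if weight is None else float(weight)
    g = nx.barabasi_albert_graph(N, m, seed=seed)
    A = nx.to_numpy_array(g, dtype=float)
    np.fill_diagonal(A, 0.0)
    return ConnectivityMatrix(
        weights=(A > 0) * w, population=_labels(N),
        generator="scalefree", seed=seed, meta={"p": p, "m": m, "weight": w})


def balance_ei(conn: ConnectivityMatrix, frac_inhib: float = 0.1,
               g_scale: float | None = None, mode: str = "row",
               seed: int | None = None) -> ConnectivityMatrix:
    """Turn an excitatory graph into a balanced E-I network.

    A random ``frac_inhib`` of the neurons is relabelled inhibitory and the
    sign of their outgoing columns flipped.  The excitatory per-synapse
    magnitude is set to ``g_scale`` (default the strong-coupling scale
    1.25/sqrt(N)); inhibitory magnitudes are then fixed by the balance mode:

    * ``"row"`` (default): magnitude (N_E/N_I) x excitatory, so the mean
      excitatory and inhibitory input per neuron cancel on average.
    * ``"block"``: magnitude chosen so the mean absolute weight of the I->I
      block equals that of the E->E block (the literal <G_EE> = <G_II>
      reading); with a homogeneous graph this leaves magnitudes equal and
      the network unbalanced on average.

    The adjacency (which pairs are connected) is taken from ``conn``
    unchanged, so the E-E block differs from the input only by the overall
    magnitude rescaling.
    """
    if not 0.0 < frac_inhib < 1.0:
        raise ParameterError("frac_inhib must be strictly between 0 and 1")
    n = conn.n_neurons
    n_i = int(round(frac_inhib * n))
    if n_i < 1:
        raise ParameterError(f"frac_inhib={frac_inhib} selects no inhibitory "
                             f"neuron at N={n}")
    if mode not in ("row", "block"):
        raise ParameterError(f"unknown balance mode {mode!r}")
    w_e = 1.25 / math.sqrt(n) if g_scale is None else float(g_scale)
    if seed is None:
        seed = None if conn.seed is None else (conn.seed + 0x5EED) % (2 ** 31)
    rng = np.random.default_rng(seed)
    inhib = rng.choice(n, size=n_i, replace=False)

    W = conn.adjacency.astype(float) * w_e
    if mode == "row":
        ratio = (n - n_i) / n_i
    else:
        ratio = 1.0
    W[:, inhib] *= -ratio

    pop = _labels(n)
    pop[inhib] = "I"
    return ConnectivityMatrix(
        weights=W, population=pop,
        generator=conn.generator + "+ei", seed=conn.seed,
        meta={**conn.meta, "frac_inhib": frac_inhib, "w_exc": w_e,
              "inhib_ratio": ratio, "balance_mode": mode, "ei_seed": seed})


def motif_frequencies(conn: ConnectivityMatrix | np.ndarray) -> dict[str, float]:
    """Empirical connection and second-order motif frequencies.

    Frequencies are probabilities over ordered tuples of distinct neurons:
    ``p`` over ordered pairs; ``recip`` the probability that an ordered pair
    is connected both ways; ``conv``/``div``/``chain`` the probability that
    an ordered triple (i, j, k) realizes two edges sharing a target, a
    source, or forming a two-step path.  For an ER graph each of the motif
    frequencies concentrates on ``p^2``.
    """
    if isinstance(conn, ConnectivityMatrix):
        A = conn.adjacency.astype(np.int64)
    else:
        A = (np.asarray(conn) != 0).astype(np.int64)
        np.fill_diagonal(A, 0)
    n = A.shape[0]
    pairs = n * (n - 1)
    triples = n * (n - 1) * (n - 2)
    n_edges = int(A.sum())
    row = A.sum(axis=1)  # in-degree (edges into i)
    col = A.sum(axis=0)  # out-degree
    recip_pairs = int(np.sum(A * A.T))
    conv = int(np.sum(row * (row - 1)))
    div = int(np.sum(col * (col - 1)))
    chains = int(np.sum(A.dot(A))) - recip_pairs  # paths k->j->i with i != k
    return {
        "p": n_edges / pairs,
        "recip": recip_pairs / pairs,
        "conv": conv / triples,
        "div": div / triples,
        "chain": chains / triples,
    }
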