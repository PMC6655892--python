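"""Motif moments, motif cumulants, and resummed covariance predictions.

The zero-frequency covariance of a linear spiking network expands as a sum
over pairs of synaptic paths; grouping paths by the local connectivity
pattern they trace out ("motifs") turns functions of the covariance into
series over motif *moments*, and rewriting moments in terms of *cumulants*
-- the part of a motif not explained by its sub-motifs -- lets the whole
series be resummed in closed form from a handful of low-order measurements.

Five motif families enter: chains (concatenated paths), divergent pairs
(shared source), convergent pairs (shared target), reciprocal pairs, and
trace motifs (path pairs that start and end on the same neurons, which are
what Tr C and Tr C^2 are made of).

Normalization.  With a unit-norm weight vector u (uniform u = 1/sqrt(N) by
default) the tables store the "scaled" statistics

    chain[n]          = u^T G^n u
    divergent[m, n]   = u^T G^m (G^T)^n u
    convergent[m, n]  = u^T (G^T)^m G^n u
    reciprocal[s]     = Tr(G^s)                       (s = total order)
    trace[n, m]       = Tr(G^n (G^T)^m) / N
    trace4[s]         = sum_{n+m+p+q=s} Tr(G^n (G^T)^m G^p (G^T)^q) / N

These carry the N-power factors of the resummation built in (for a uniform
weight vector, ``scaled = N^{m+n} mu`` where mu is the conventionally
normalized moment; :meth:`MotifStatistics.moment` converts).  For an ER
network every scaled statistic of total order s concentrates on rho^s with
rho = N <G> the effective coupling.

Cumulants.  Chain/divergent/convergent cumulants are defined by the
order-by-order composition relation (every composition of the path lengths
into segments contributes the product of segment cumulants); the trace
cumulants are defined by subtracting, order by order, the part of the trace
moments predicted by the resummed chain/divergent/convergent factorization.
This makes the order-zero trace cumulant exactly 1 - 1/N and makes the
truncated trace formulas telescope to the exact Tr C and Tr C^2 as the
truncation order grows.

The resummed predictions (chain sum S, divergent sum D, convergent sum V,
trace sums T2, T4; r = 1/(1 - S)):

    <C>     = (c0 / N) r^2 (1 + D)
    Tr C    = c0  [ r^2 (1 + D)(1 + V) + N T2 ]
    Tr C^2  = c0^2[ r^4 (1 + D)^2 (1 + V)^2 + N T4 ]
    Dim(C)  = (Tr C)^2 / Tr C^2
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math

import numpy as np

from .dimensionality import DimensionalityResult
from .exceptions import DivergenceError, ParameterError, ValidationError

__all__ = [
    "MotifStatistics",
    "TaylorCoefficients",
    "motif_moments",
    "moments_to_cumulants",
    "measure_motifs",
    "er_cumulants",
    "mean_covariance_from_cumulants",
    "traces_from_cumulants",
    "dim_from_cumulants",
    "er_closed_form",
    "taylor_coefficients",
    "dim_with_input",
    "highdim_input_approx",
    "leading_eigenvector",
]


# ---------------------------------------------------------------------------
# truncated power-series helpers (1-D in total order; 2-D in (left, right))
# ---------------------------------------------------------------------------

def _p_mul(a: np.ndarray, b: np.ndarray, K: int) -> np.ndarray:
    return np.convolve(a, b)[:K + 1]

def _p_inv(a: np.ndarray, K: int) -> np.ndarray:
    """Reciprocal series of a, a[0] must be nonzero."""
    a = np.asarray(a, dtype=float)
    out = np.zeros(K + 1)
    out[0] = 1.0 / a[0]
    for n in range(1, K + 1):
        hi = min(n, len(a) - 1)
        out[n] = -np.dot(a[1:hi + 1], out[n - 1::-1][:hi]) / a[0]
    return out

def _total_order_mask(K: int) -> np.ndarray:
    idx = np.arange(K + 1)
    return (idx[:, None] + idx[None, :]) <= K

def _p2_mul(A: np.ndarray, B: np.ndarray, K: int) -> np.ndarray:
    from scipy.signal import convolve2d
    out = convolve2d(A, B)[:K + 1, :K + 1]
    out[~_total_order_mask(K)] = 0.0
    return out

def _collapse(A: np.ndarray, K: int) -> np.ndarray:
    """Collapse a 2-D graded table to 1-D by total order."""
    out = np.zeros(K + 1)
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if i + j <= K:
                out[i + j] += A[i, j]
    return out


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

_TABLE_KEYS = ("chain", "divergent", "convergent", "reciprocal", "trace", "trace4")


@dataclasses.dataclass
class MotifStatistics:
    """Tables of motif moments and cumulants up to a truncation order.

    ``moments`` and ``cumulants`` are dicts with keys ``chain`` (1-D, index
    = path length), ``divergent``/``convergent``/``trace`` (2-D, indices =
    the two path lengths, masked to total order <= max_order),
    ``reciprocal`` and ``trace4`` (1-D, index = total order).  Entries hold
    the scaled statistics described in the module docstring.
    """

    n_neurons: int
    max_order: int
    moments: dict | None = None
    cumulants: dict | None = None
    weight_vector: np.ndarray | None = None

    def moment(self, motif_type: str, index) -> float:
        """Moment in the conventional literature normalization.

        For chain/divergent/convergent statistics of total order s this is
        ``scaled * N^(2-s)`` (only meaningful for the uniform weight
        vector); reciprocal and trace entries are returned as stored.
        """
        return self._lookup(self.moments, motif_type, index)

    def cumulant(self, motif_type: str, index) -> float:
        return self._lookup(self.cumulants, motif_type, index, scaled=True)

    def _lookup(self, table, motif_type, index, scaled=False):
        if table is None:
            raise ValidationError("table not populated")
        arr = table[motif_type]
        idx = (index,) if np.isscalar(index) else tuple(index)
        if arr.ndim == 1:
            val = float(arr[sum(idx)])  # 1-D families are keyed by total order
        else:
            val = float(arr[idx])
        if scaled or motif_type in ("reciprocal", "trace", "trace4"):
            return val
        return val * self.n_neurons ** (2 - sum(idx))

    # -- aggregates consumed by the resummed formulas --------------------

    def _sums(self, order: int | None = None):
        if self.cumulants is None:
            raise ValidationError("cumulants not computed; call "
                                  "moments_to_cumulants first")
        K = self.max_order if order is None else int(order)
        if K > self.max_order:
            raise ParameterError(f"order {K} exceeds max_order {self.max_order}")
        k = self.cumulants
        S = float(k["chain"][1:K + 1].sum())
        idx = np.arange(self.max_order + 1)
        tot = idx[:, None] + idx[None, :]
        m2 = (tot <= K) & (idx[:, None] >= 1) & (idx[None, :] >= 1)
        D = float(k["divergent"][m2].sum())
        V = float(k["convergent"][m2].sum())
        T2 = float(k["trace"][tot <= K].sum())
        T4 = float(k["trace4"][:K + 1].sum())
        return S, D, V, T2, T4

    @classmethod
    def from_cumulants(cls, n_neurons: int, max_order: int = 2, *,
                       chain=(), divergent=(), convergent=(),
                       trace=(), trace4=()) -> "MotifStatistics":
        """Build a statistics object directly from (scaled) cumulant values.

        ``chain`` maps order -> value; the 2-D families map (n, m) -> value;
        ``trace``/``trace4`` additions are on top of the order-zero value
        1 - 1/N that any network carries.  Useful for analytic reference
        points (ER) and sensitivity analyses.
        """
        K = max_order
        k = _empty_tables(K)
        k["trace"][0, 0] = 1.0 - 1.0 / n_neurons
        k["trace4"][0] = 1.0 - 1.0 / n_neurons
        for n, val in dict(chain).items():
            k["chain"][n] = val
        for (n, m), val in dict(divergent).items():
            k["divergent"][n, m] = val
        for (n, m), val in dict(convergent).items():
            k["convergent"][n, m] = val
        for (n, m), val in dict(trace).items():
            k["trace"][n, m] += val
        for s, val in dict(trace4).items():
            k["trace4"][s] += val
        return cls(n_neurons=n_neurons, max_order=K, cumulants=k)

    def to_json(self) -> str:
        def enc(table):
            return None if table is None else {k: v.tolist()
                                               for k, v in table.items()}
        return json.dumps({
            "n_neurons": self.n_neurons, "max_order": self.max_order,
            "moments": enc(self.moments), "cumulants": enc(self.cumulants),
            "weight_vector": None if self.weight_vector is None
            else self.weight_vector.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "MotifStatistics":
        d = json.loads(text)
        def dec(table):
            return None if table is None else {k: np.asarray(v)
                                               for k, v in table.items()}
        wv = d.get("weight_vector")
        return cls(n_neurons=d["n_neurons"], max_order=d["max_order"],
                   moments=dec(d["moments"]), cumulants=dec(d["cumulants"]),
                   weight_vector=None if wv is None else np.asarray(wv))


def _empty_tables(K: int) -> dict:
    return {
        "chain": np.zeros(K + 1),
        "divergent": np.zeros((K + 1, K + 1)),
        "convergent": np.zeros((K + 1, K + 1)),
        "reciprocal": np.zeros(K + 1),
        "trace": np.zeros((K + 1, K + 1)),
        "trace4": np.zeros(K + 1),
    }


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def motif_moments(G: np.ndarray, max_order: int = 2,
                  u: np.ndarray | None = None) -> MotifStatistics:
    """Measure motif moments of an effective connectivity matrix.

    Chain/divergent/convergent statistics are quadratic forms in the weight
    vector and need only matrix-vector ladders; trace statistics need traces
    of products of matrix powers (computed from elementwise identities at
    the default ``max_order=2`` so no large matrix products are formed).
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValidationError(f"G must be square, got {G.shape}")
    K = int(max_order)
    if K < 1:
        raise ParameterError("max_order must be >= 1")
    N = G.shape[0]
    if u is None:
        uu = np.full(N, 1.0 / math.sqrt(N))
        stored_u = None
    else:
        uu = np.asarray(u, dtype=float)
        if uu.shape != (N,):
            raise ValidationError("weight vector must have one entry per neuron")
        if abs(np.linalg.norm(uu) - 1.0) > 1e-10:
            raise ValidationError("weight vector must have unit norm")
        stored_u = uu

    m = _empty_tables(K)

    # matrix-vector ladders: g_vecs[a] = G^a u, gt_vecs[a] = (G^T)^a u
    g_vecs = [uu]
    gt_vecs = [uu]
    for _ in range(K):
        g_vecs.append(G @ g_vecs[-1])
        gt_vecs.append(G.T @ gt_vecs[-1])
    for n in range(K + 1):
        m["chain"][n] = float(uu @ g_vecs[n])
    mask = _total_order_mask(K)
    for a in range(K + 1):
        for b in range(K + 1):
            if mask[a, b]:
                # u^T G^a (G^T)^b u = ((G^T)^a u) . ((G^T)^b u)
                m["divergent"][a, b] = float(gt_vecs[a] @ gt_vecs[b])
                # u^T (G^T)^a G^b u = (G^a u) . (G^b u)
                m["convergent"][a, b] = float(g_vecs[a] @ g_vecs[b])

    if K == 2:
        _trace_moments_order2(G, m)
    else:
        _trace_moments_general(G, m, K)
    return MotifStatistics(n_neurons=N, max_order=K, moments=m,
                           weight_vector=stored_u)


def _trace_moments_order2(G: np.ndarray, m: dict) -> None:
    """Trace/reciprocal moments to total order 2 via elementwise identities."""
    N = G.shape[0]
    trG = float(np.trace(G))
    trG2 = float(np.sum(G * G.T))   # Tr(G^2)
    trGGt = float(np.sum(G * G))    # Tr(G G^T)
    m["reciprocal"][2] = trG2
    t2 = m["trace"]
    t2[0, 0] = 1.0
    t2[1, 0] = t2[0, 1] = trG / N
    t2[1, 1] = trGGt / N
    t2[2, 0] = t2[0, 2] = trG2 / N
    t4 = m["trace4"]
    t4[0] = 1.0
    t4[1] = 4.0 * trG / N
    # tuples of (n,m,p,q) >= 0 summing to 2: four single-2 positions give
    # Tr(G^2); the six 1+1 placements give 4x Tr(G G^T) and 2x Tr(G^2)
    t4[2] = (6.0 * trG2 + 4.0 * trGGt) / N


def _trace_moments_general(G: np.ndarray, m: dict, K: int) -> None:
    N = G.shape[0]
    Gp = [np.eye(N)]
    for _ in range(K):
        Gp.append(Gp[-1] @ G)
    for s in range(2, K + 1):
        m["reciprocal"][s] = float(np.trace(Gp[s]))
    t2 = m["trace"]
    for a in range(K + 1):
        for b in range(K + 1 - a):
            # Tr(G^a (G^T)^b) = <G^a, G^b>_F
            t2[a, b] = float(np.sum(Gp[a] * Gp[b])) / N
    # products M2[(a, b)] = G^a (G^T)^b for the 4-index traces
    M2 = {}
    for a in range(K + 1):
        for b in range(K + 1 - a):
            if b == 0:
                M2[(a, b)] = Gp[a]
            elif a == 0:
                M2[(a, b)] = Gp[b].T
            else:
                M2[(a, b)] = Gp[a] @ Gp[b].T
    t4 = m["trace4"]
    for a, b, c, d in itertools.product(range(K + 1), repeat=4):
        s = a + b + c + d
        if s <= K:
            # Tr(M2[a,b] M2[c,d]) = sum(M2[a,b] * M2[c,d]^T)
            t4[s] += float(np.sum(M2[(a, b)] * M2[(c, d)].T)) / N


# ---------------------------------------------------------------------------
# moments -> cumulants
# ---------------------------------------------------------------------------

def moments_to_cumulants(stats: MotifStatistics) -> MotifStatistics:
    """Solve the composition relation for the cumulant tables.

    Chains: 1 + sum mu_n t^n = 1 / (1 - sum kappa_n t^n), i.e. every
    composition of a path into segments contributes the product of segment
    cumulants.  Divergent/convergent: the 2-D analogue with a joint cumulant
    at the shared node, so the full table satisfies
    T(s, t) = R(s) (1 + K2(s, t)) R(t) with R = 1/(1 - Kch).  Reciprocal:
    excess of the s-cycle strength over the open-chain moment of the same
    length.  Trace: graded subtraction of the resummed
    chain/divergent/convergent factorization (see module docstring); the
    order-zero trace cumulants come out as exactly 1 - 1/N.

    The inverse relation is exact: rebuilding the moment tables from the
    returned cumulants reproduces the inputs to machine precision.
    """
    if stats.moments is None:
        raise ValidationError("moments not populated")
    K = stats.max_order
    N = stats.n_neurons
    mom = stats.moments
    k = _empty_tables(K)

    # chains: K(t) = 1 - 1/(1 + M(t)) with M the moment series (M[0]=0)
    onepM = mom["chain"].copy()
    onepM[0] = 1.0
    inv = _p_inv(onepM, K)
    kch = -inv
    kch[0] = 0.0
    k["chain"] = kch

    # divergent / convergent: 1 + K2 = T (1 - Kch(s)) (1 - Kch(t))
    c1 = -kch.copy()
    c1[0] = 1.0  # series 1 - Kch
    CC = np.outer(c1, c1)
    for key in ("divergent", "convergent"):
        K2 = _p2_mul(mom[key], CC, K)
        K2[0, 0] -= 1.0
        K2[0, :] = 0.0
        K2[:, 0] = 0.0
        k[key] = K2

    # reciprocal: excess closed-path strength over the open chain moment
    k["reciprocal"] = mom["reciprocal"] - mom["chain"]
    k["reciprocal"][:2] = 0.0

    # trace: subtract the factorized prediction R(s) R(t) (1+Kd)(1+Kv)
    R1 = _p_inv(c1, K)
    RR = np.outer(R1, R1)
    RR[~_total_order_mask(K)] = 0.0
    oneKd = k["divergent"].copy(); oneKd[0, 0] += 1.0
    oneKv = k["convergent"].copy(); oneKv[0, 0] += 1.0
    fact2 = _p2_mul(RR, _p2_mul(oneKd, oneKv, K), K)
    k["trace"] = mom["trace"] - fact2 / N
    k["trace"][~_total_order_mask(K)] = 0.0

    # trace4: 1-D in total order; factorization r^4 (1+D)^2 (1+V)^2
    R2 = _p_mul(R1, R1, K)
    R4 = _p_mul(R2, R2, K)
    d1 = _collapse(oneKd, K)
    v1 = _collapse(oneKv, K)
    fact4 = _p_mul(R4, _p_mul(_p_mul(d1, d1, K), _p_mul(v1, v1, K), K), K)
    k["trace4"] = mom["trace4"] - fact4 / N

    return dataclasses.replace(stats, cumulants=k)


def measure_motifs(G: np.ndarray, max_order: int = 2,
                   u: np.ndarray | None = None) -> MotifStatistics:
    """Moments and cumulants in one call."""
    return moments_to_cumulants(motif_moments(G, max_order, u))


def er_cumulants(N: int, rho: float, max_order: int = 2) -> MotifStatistics:
    """The analytic cumulant table of an ER network at effective coupling rho.

    Only the first chain cumulant (scaled value rho = N <G>) and the
    order-zero trace cumulants 1 - 1/N are nonzero.
    """
    return MotifStatistics.from_cumulants(N, max_order, chain={1: rho})


def leading_eigenvector(G: np.ndarray, k: int = 1) -> np.ndarray:
    """Leading-|lambda| real Schur directions of G, unit-norm rows (k, N).

    These are the natural weight vectors for resumming motifs in networks
    whose activity is dominated by a few eigenmodes (e.g. balanced E-I
    networks).
    """
    from scipy.linalg import schur
    T, Z = schur(np.asarray(G, dtype=float), output="real")
    order = np.argsort(-np.abs(np.diag(T)))
    V = Z[:, order[:k]].T
    return V / np.linalg.norm(V, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# resummed predictions
# ---------------------------------------------------------------------------

def _resummed(stats: MotifStatistics, order: int | None = None):
    S, D, V, T2, T4 = stats._sums(order)
    if S >= 1.0:
        raise DivergenceError(S)
    return 1.0 / (1.0 - S), D, V, T2, T4


def mean_covariance_from_cumulants(stats: MotifStatistics, c0: float = 1.0,
                                   order: int | None = None) -> float:
    """<C> = (c0/N) r^2 (1 + D): chains and divergent motifs factor out."""
    r, D, _, _, _ = _resummed(stats, order)
    return c0 / stats.n_neurons * r * r * (1.0 + D)


def traces_from_cumulants(stats: MotifStatistics, c0: float = 1.0,
                          order: int | None = None) -> tuple[float, float]:
    """(Tr C, Tr C^2) from the resummed cumulant series.

    Equivalently Tr C = N <C> (1 + V) + c0 N T2 -- the trace is the average
    covariance dressed by convergent motifs plus the trace-motif series --
    and likewise for Tr C^2; the two forms are algebraically identical.
    """
    r, D, V, T2, T4 = _resummed(stats, order)
    N = stats.n_neurons
    trc = c0 * (r * r * (1.0 + D) * (1.0 + V) + N * T2)
    trc2 = c0 * c0 * ((r ** 4) * (1.0 + D) ** 2 * (1.0 + V) ** 2 + N * T4)
    return trc, trc2


def dim_from_cumulants(stats: MotifStatistics, c0: float = 1.0,
                       order: int | None = None) -> DimensionalityResult:
    """Participation ratio predicted from motif cumulants."""
    trc, trc2 = traces_from_cumulants(stats, c0, order)
    return DimensionalityResult(raw=trc * trc / trc2, method="cumulant_lowdim",
                                n_neurons=stats.n_neurons)


def er_closed_form(N: int, rho: float) -> DimensionalityResult:
    """Closed-form dimensionality of an ER network at effective coupling rho.

    With x = (1 - rho)^-2:  Dim = (x + N - 1)^2 / (x^2 + N - 1).
    Dim -> N as rho -> 0 (independent neurons) and -> 1 as rho -> 1-
    (activity collapses onto the dominant mode at the stability boundary).
    """
    if N < 1:
        raise ParameterError("N must be positive")
    if rho < 0.0:
        raise ParameterError("effective coupling rho must be nonnegative")
    if rho >= 1.0:
        raise DivergenceError(rho)
    x = (1.0 - rho) ** -2
    raw = (x + N - 1.0) ** 2 / (x * x + N - 1.0)
    return DimensionalityResult(raw=raw, method="closed_form_ER", n_neurons=N)


@dataclasses.dataclass(frozen=True)
class TaylorCoefficients:
    """First-order sensitivities of Dim(C) to motif cumulants at an ER point.

    ``alpha_ch``, ``alpha_div`` (= ``alpha_con`` identically) are negative
    for any r > 1: adding chains or divergent/convergent structure lowers
    the dimensionality.  ``alpha_TrC`` > 0 and ``alpha_TrC2`` < 0, but their
    sum -- the response to the tightly correlated pair of trace cumulants --
    is always positive: trace (reciprocal-built) motifs are the one channel
    through which dimensionality can rise.
    """

    alpha_ch: float
    alpha_div: float
    alpha_con: float
    alpha_TrC: float
    alpha_TrC2: float
    r: float
    reference_point: dict

    @property
    def net_trace_effect(self) -> float:
        return self.alpha_TrC + self.alpha_TrC2


def taylor_coefficients(N: int, chain_cumulants) -> TaylorCoefficients:
    """Sensitivity of Dim(C) to each second-order cumulant at an ER point.

    ``chain_cumulants`` is the series of scaled chain cumulants (the sum of
    which is the effective coupling rho for a plain ER network); r is the
    resummed chain factor 1/(1 - sum).  The coefficients are the exact
    partial derivatives of ``dim_from_cumulants`` with respect to the
    (scaled) divergent/convergent/chain/trace cumulant sums, using the exact
    trace values Tr C|ER = c0 (r^2 + N - 1), Tr C^2|ER = c0^2 (r^4 + N - 1).
    """
    ch = np.atleast_1d(np.asarray(chain_cumulants, dtype=float))
    S = float(ch.sum())
    if S >= 1.0:
        raise DivergenceError(S)
    r = 1.0 / (1.0 - S)
    T1 = r * r + N - 1.0
    T2 = r ** 4 + N - 1.0
    # d r / d kch = r^2 => d(r^2)/dkch = 2 r^3, d(r^4)/dkch = 4 r^5
    alpha_ch = 4.0 * r ** 3 * T1 / T2 - T1 * T1 * 4.0 * r ** 5 / (T2 * T2)
    alpha_div = 2.0 * r * r * T1 / T2 - T1 * T1 * 2.0 * r ** 4 / (T2 * T2)
    alpha_trc = 2.0 * N * T1 / T2
    alpha_trc2 = -N * T1 * T1 / (T2 * T2)
    return TaylorCoefficients(
        alpha_ch=alpha_ch, alpha_div=alpha_div, alpha_con=alpha_div,
        alpha_TrC=alpha_trc, alpha_TrC2=alpha_trc2, r=r,
        reference_point={"N": N, "r": r, "chain_sum": S})


# ---------------------------------------------------------------------------
# stimulus-driven predictions
# ---------------------------------------------------------------------------

def dim_with_input(stats_int: MotifStatistics,
                   stats_ext: list[MotifStatistics],
                   c0: float, strengths, g: float = 1.0,
                   order: int | None = None) -> DimensionalityResult:
    """Dimensionality of the driven response from weighted motif cumulants.

    ``stats_ext`` holds one cumulant table per input factor, measured with
    that factor as the weight vector; the per-factor external traces are
    resummed with the same functional form as the internal ones,

        Tr C_ext,i        = g^2 c_i r_i^2 (1 + V_i)
        Tr C_ext^2        ~ sum_i (Tr C_ext,i)^2
        Tr(C_int C_ext),i = c0 g^2 c_i r_i^4 (1 + D_i)^2 (1 + V_i)

    and combined with the internal traces through the decomposed
    participation-ratio formula.  The factor-diagonal form of Tr C_ext^2 is
    what makes this the *low-dimensional-input* approximation: interactions
    between different factors through the network are dropped.
    """
    strengths = np.atleast_1d(np.asarray(strengths, dtype=float))
    if len(stats_ext) != strengths.shape[0]:
        raise ValidationError("one weighted cumulant table per factor required")
    trci, trci2 = traces_from_cumulants(stats_int, c0, order)
    te = te2 = cross = 0.0
    for st, ci in zip(stats_ext, strengths):
        r, D, V, _, _ = _resummed(st, order)
        t = g * g * ci * r * r * (1.0 + V)
        te += t
        te2 += t * t
        cross += c0 * g * g * ci * r ** 4 * (1.0 + D) ** 2 * (1.0 + V)
    raw = (trci + te) ** 2 / (trci2 + te2 + 2.0 * cross)
    return DimensionalityResult(raw=raw, method="cumulant_lowdim",
                                n_neurons=stats_int.n_neurons)


def highdim_input_approx(TrCint: float, TrCext: float, TrCint2: float,
                         TrCext2: float,
                         n_neurons: int | None = None) -> DimensionalityResult:
    """High-dimensional-input approximation of the decomposed dimensionality.

    The cross term Tr(C_int C_ext) -- the one term mixing internal modes and
    input -- is replaced by the square root of its Cauchy-Schwarz/AM-GM
    upper bound:

        Tr(C_int C_ext)^2 <= Tr(C_int^2) Tr(C_ext^2)
                          <= (Tr C_int + Tr C_ext)^2 / 2

    i.e. cross <- (Tr C_int + Tr C_ext)/sqrt(2), disengaging the internal
    modes from the input contribution.
    """
    for name, v in (("TrCint", TrCint), ("TrCext", TrCext),
                    ("TrCint2", TrCint2), ("TrCext2", TrCext2)):
        if v < 0:
            raise ParameterError(f"{name} must be nonnegative")
    if TrCext == 0.0:
        # no input: the cross term vanishes identically
        cross = 0.0
    else:
        cross = (TrCint + TrCext) / math.sqrt(2.0)
    raw = (TrCint + TrCext) ** 2 / (TrCint2 + TrCext2 + 2.0 * cross)
    return DimensionalityResult(raw=raw, method="cumulant_highdim",
                                n_neurons=n_neurons)
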