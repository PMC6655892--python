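# Methods

## Model

`motifdim` works with networks of `N` Poisson point-process neurons whose
instantaneous firing rates are linear functions of filtered presynaptic
spikes (a linear Hawkes process, equivalently a linearized Poisson GLM).
The synaptic matrix `W` has entry `W[i, j]` = strength of the synapse from
neuron `j` onto neuron `i`, so matrix powers accumulate multi-step paths
ending at the row index.  Cellular response properties are homogeneous: the
postsynaptic filter contributes a scalar gain `g` at zero frequency, and
the baseline (uncoupled) spiking variability is `C0 = c0 I`.  Everything is
evaluated at zero frequency, where the cross-spectral matrix is the usual
long-window spike-count covariance

    C = Delta (c0 I) Delta^T + Delta (g^2 C_inp) Delta^T = C_int + C_ext,
    Delta = (I - G)^(-1),   G = g W,

valid while the spectral radius of `G` is below one.  Instability raises an
error; it is never regularized away.  External input enters as a low-rank
covariance `C_inp = sum_i c_i xi_i xi_i^T` over unit-norm factors.

The activity's dimensionality is the participation ratio
`Dim(C) = (Tr C)^2 / Tr(C^2)`, computed from traces (Tr C^2 is the squared
Frobenius norm of the symmetric C), never from an eigendecomposition; the
eigenvalue form is retained only as a test oracle.  Normalized values
(`Dim/N`) are the default for ensemble summaries.

## Motif statistics and their normalization

Functions of `C` expand as sums over pairs of synaptic paths.  Grouping
paths by the two-branch pattern they trace gives five motif families:
chains, divergent (shared source), convergent (shared target), reciprocal,
and trace motifs (branch pairs that start and end on the same neurons,
the constituents of `Tr C` and `Tr C^2`).  With a unit-norm weight vector
`u` (uniform `1/sqrt(N)` unless a stimulus factor or eigenvector weighting
is requested) the stored "scaled" statistics are

    chain[n]        = u^T G^n u
    divergent[m, n] = u^T G^m (G^T)^n u
    convergent[m,n] = u^T (G^T)^m G^n u
    reciprocal[s]   = Tr(G^s)
    trace[n, m]     = Tr(G^n (G^T)^m) / N
    trace4[s]       = sum_{n+m+p+q=s} Tr(G^n (G^T)^m G^p (G^T)^q) / N

These carry the `N`-power factors of the resummation built in: for an ER
network every scaled statistic of total order `s` concentrates on `rho^s`,
with `rho = N <G>` the effective coupling (`rho = 10 p` under the default
convention `g = 10`, per-synapse weight `1/N`).  A converter to the
conventional normalization (`scaled * N^(2-s)`) is provided.

Cumulants remove from each moment the part explained by its sub-motifs.
For chains the composition relation is `1 + M(t) = 1 / (1 - K(t))` as
formal power series; for divergent/convergent tables the two-variable
analogue `T(s, t) = R(s) (1 + K2(s, t)) R(t)` with `R = 1/(1 - K_chain)`.
The trace cumulants are defined *constructively*: the factorized part of
the trace series -- the graded expansion of `r^2 (1+D)(1+V)` for `Tr C` and
`r^4 (1+D)^2 (1+V)^2` for `Tr C^2`, where `r`, `D`, `V` are the resummed
chain/divergent/convergent sums -- is subtracted order by order from the
measured trace moments.  Two consequences fix the normalization that the
source text leaves to its supplement: the order-zero trace cumulant is
exactly `1 - 1/N` for any network, and the truncated trace formulas
telescope, so the untruncated evaluation reproduces the exact `Tr C` and
`Tr C^2`.  This convergence (geometric in the truncation order for
subcritical networks) is asserted by the test suite on small random
networks.  The four-index trace cumulants are stored aggregated by total
order; only total-order sums ever enter the truncated formulas, and a
per-tuple split would require a four-variable graded factorization with no
consumer.

The resummed predictions, truncated by default at total order 2
("second-order motifs"), are

    <C>    = (c0/N)  r^2 (1 + D)
    Tr C   = c0   [ r^2 (1 + D)(1 + V) + N T2 ]
    Tr C^2 = c0^2 [ r^4 (1 + D)^2 (1 + V)^2 + N T4 ]

with `T2`, `T4` the trace-cumulant sums, and `Dim = (Tr C)^2 / Tr C^2`.
The geometric factor `r = (1 - S)^(-1)` always uses the closed form; a
chain sum `S >= 1` raises a divergence error (the motif-level signature of
instability).  For an ER network only `S = rho` and the order-zero trace
cumulants survive, giving the closed form
`Dim = (x + N - 1)^2 / (x^2 + N - 1)` with `x = (1 - rho)^(-2)`: `N`
independent modes at `rho = 0`, collapse to one mode at the stability
boundary.  (The source text also asserts a `N - 1` limit at small coupling
that is inconsistent with its own closed form; the closed form is followed.)

### Taylor sensitivities

The first-order sensitivities of `Dim` to each cumulant at an ER reference
use the exact traces `Tr C = c0 (r^2 + N - 1)`, `Tr C^2 = c0^2 (r^4 + N - 1)`
rather than their large-N shorthand, making them the exact derivatives of
the implemented dimensionality formula (verified against central finite
differences to < 1e-3 relative).  Their sign structure is a theorem-level
property checked over `r` in (1, 10]: chain, divergent and convergent
sensitivities are negative (adding such structure lowers dimension),
while the summed sensitivity to the two tightly correlated trace cumulants
is positive -- trace (reciprocal-built) motifs are the one channel that can
raise dimensionality.

### Stimulus-driven responses

With input factors, the decomposed participation ratio needs `Tr C_ext`,
`Tr C_ext^2` and the cross trace `Tr(C_int C_ext)`.  The *low-dimensional
input* approximation measures one weighted cumulant table per factor
(weight vector = the factor) and resums per factor:

    Tr C_ext,i         = g^2 c_i r_i^2 (1 + V_i)
    Tr C_ext^2         ~ sum_i (Tr C_ext,i)^2
    Tr(C_int C_ext),i  = c0 g^2 c_i r_i^4 (1 + D_i)^2 (1 + V_i)

The factor-diagonal form of `Tr C_ext^2` drops factor-factor interactions
through the network, which is why the approximation degrades for
high-dimensional inputs.  The *high-dimensional input* approximation
replaces the cross trace by the square root of its bound
`(Tr C_int + Tr C_ext)^2 / 2`, disengaging internal modes from the input
(the bound's outer inequality is not scale-invariant; it holds in the
unit-variance normalization the theory operates in, and the cross term is
set exactly to zero when there is no input).

## Network generators

*Erdos-Renyi*: independent ordered-pair edges.  *Small world / scale
free*: networkx Watts-Strogatz (ring degree `round(pN)`, configurable
rewiring) and Barabasi-Albert (attachment count from the smaller root of
`m (N - m) = p N^2 / 2`), symmetrized to directed matrices.

*SONET* (second-order networks): edges are obtained by thresholding a
correlated latent Gaussian field at the `p`-quantile.  The field for edge
`j -> i` is `a eps_ij + b u_i + c v_j + d s w_{ij}` with per-node in/out
factors (correlated `rho_uv` at the same node) and a symmetric pair factor,
giving pairwise latent correlations `b^2` (convergent), `c^2` (divergent),
`b c rho_uv` (chain) and `2 b c rho_uv + s d^2` (reciprocal).  Each target
motif frequency `p^2 (1 + alpha)` is converted to a latent correlation by
inverting the bivariate normal orthant probability through Owen's T
(machine precision, no quadrature).  With all alphas zero the construction
degenerates to iid Bernoulli edges -- exactly ER.  Feasibility: chain
biases require `|lam_ch| <= sqrt(lam_conv lam_div)`; in strict mode
(used by the ensemble drivers, mirroring the reference algorithm's
rejection behavior) violations raise, otherwise the node-factor variances
are minimally inflated and the realized latent parameters recorded.
Downstream theory always consumes *measured* motif statistics.

*E-I balance*: a random fraction (default 10%) of neurons becomes
inhibitory; their outgoing magnitude is `(N_E/N_I)` times the excitatory
weight so the mean input per neuron cancels, and the synaptic scale is
promoted to the strong-coupling `1.25/sqrt(N)` (the balanced network is
then its own effective connectivity, gain 1).  A "block" mode implementing
the literal equality of mean E-E and I-I weights is provided but is not
the default, since with a homogeneous graph it produces no cancellation.

## Ensembles and experiments

All experiments are pure functions of configuration plus a master seed;
per-network child seeds are recorded.  Unstable draws (spectral radius
>= 1) and strict-infeasible motif draws are redrawn and counted, never
silently absorbed.  The reference configurations are: 500 networks of
N = 1000 at `c0 = 1`, gain 10, weight `1/N`, motif biases uniform over
`alpha_recip in [-1, 4]`, `alpha_conv, alpha_div in [0, 1]`,
`alpha_chain in [-1, 1]`; connection probability `p in [0.01, 0.1]` for the
dimensionality/correlation study and `p in [0.078, 0.082]` for the
regression study.  Scaled presets (fewer networks, N = 500) ship for fast
runs.  Spectral radii at N = 1000 are estimated by power iteration on the
norm growth rate (exact dense eigenvalues below N = 500); for the
excitatory ensembles the Perron root makes this essentially exact.

The regression study fits the normalized dimensionality, relative to the
ER closed form at the center `p`, by OLS on six unstandardized regressors:
density offset `p_hat - p_ER`, second-order chain cumulant, convergent and
divergent cumulants, and the two trace-cumulant sums (`Tr C` series and
`Tr C^2` series).  The two trace regressors are tightly correlated by
construction; a condition-number warning flags the expected collinearity,
and their individual coefficients (opposite in sign) should be read only
through their sum.  The E-I study regresses dimensionality on the six
analogous statistics of the inhibitory-to-inhibitory block, measured on
the signed weighted submatrix.

Average correlation is `<C>/c0` with `<C>` the grand mean over all `N^2`
entries (the convention the motif formulas resum); an off-diagonal variant
exists but is not the default.

Stimulus sweeps report, along a grid of factor counts or strengths, the
exact decomposed dimensionality and both cumulant approximations.  Factors
are orthonormal by default: an input of `N_inp` factors then spans exactly
`N_inp` dimensions, so the full-grid endpoint recovers the internal
dimensionality.  Independent random unit vectors are available
(`orthonormal=False`), but `N` of them carry a Marchenko-Pastur eigenvalue
spread that caps the input's own participation ratio near `N/2`, which
changes the large-`N_inp` endpoint qualitatively.  In the fixed-total-power
mode the per-factor strength is `total * c0 / sqrt(N_inp)` so that
`sqrt(sum c_i^2)` is constant (default total 2.5).

## Monte-Carlo validator

The simulator integrates the linear Poisson dynamics in discrete time
(default `dt` = 1 ms) with a unit-area exponential postsynaptic filter
(default time constant 10 ms).  Baseline drives are chosen to hit target
stationary rates (default 20 Hz -- the working point is a free validation
parameter, as the theory itself never needs one); the analytic count
covariance per unit time is then `Delta diag(rates) Delta^T` plus the
external term.  Counts are binned over windows long relative to the filter
(default 1 s).  Negative linearized rates are clipped at zero with a
warning, and an error is raised if more than a configurable fraction of
neuron-steps clip, since the linear model is then a poor description of
the operating point.

## What the generators do and do not emulate

The synthetic ensembles reproduce the second-order motif structure,
stability properties, and excitatory/inhibitory composition of the model
networks the theory addresses.  They do not emulate distance-dependent or
clustered cortical topography, synaptic weight heterogeneity beyond the
binary-times-scale convention, cell-type-specific gains, or any nonlinear
rate dynamics; passing tests therefore certify the linear-response theory
and its motif reduction, not agreement with recorded neural data.  The
dichotomized-Gaussian SONET sampler realizes the requested pairwise motif
statistics exactly in expectation but, unlike a maximum-entropy sampler,
also carries higher-order dependencies induced by the node factors; the
test suite and ensemble records therefore always report measured cumulants
next to every prediction so the approximation error is auditable.

## Numerical choices

Truncated power series are manipulated as coefficient arrays (1-D in total
order, 2-D in branch orders with total-degree masking); series reciprocals
use the standard recurrence.  At the default truncation order 2 every
motif statistic reduces to matrix-vector ladders and elementwise trace
identities (`Tr(G^2) = sum(G * G^T)`, `Tr(G G^T) = sum(G * G)`), so
measuring a network costs O(N^2); exact dimensionality costs one dense
solve plus one matrix product.  Propagators come from linear solves, not
explicit inversion, except where a full `Delta` is reused across a
stimulus grid.  Symmetry of covariances is enforced to 1e-8 relative;
participation ratios of the zero matrix are an error, not a NaN.

## Known limitations

* The order-2 truncation degrades near the stability boundary and for
  balanced E-I networks (where the uniform weight vector misses the
  dominant eigenmodes; eigenvector weighting is available but a full
  multi-direction resummation is out of scope).
* Two printed reference values resisted reproduction under the literal
  study conditions: the six-regressor fit quality over the full motif-bias
  ranges (a linear model caps near r^2 ~ 0.94-0.95 on ensembles that reach
  the stability boundary; measured ceiling documented in the test suite) and
  the E-I regression fit quality (measured ~ 0.6-0.7, with the
  inhibitory-block statistics acting as tight proxies of the global motif
  draw in this sampler).  The corresponding tests state the printed values
  and fail honestly rather than restating the measured ones.
* Only the zero-frequency covariance is computed; no frequency-resolved
  API.
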