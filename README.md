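# motifdim

Motif-cumulant theory of activity dimensionality in linear recurrent
spiking networks.

## The problem

How many degrees of freedom does the collective activity of a recurrent
spiking circuit explore, and what is it about the circuit's wiring that
sets this number?  `motifdim` answers this for networks of linearly
interacting Poisson neurons (linear Hawkes processes / linearized Poisson
GLMs), where the long-window spike-count covariance has the closed form

    C = Δ (c₀ I) Δᵀ + Δ (g² C_inp) Δᵀ = C_int + C_ext,   Δ = (I − G)⁻¹,

with effective connectivity `G = g W` (gain `g`, synaptic matrix `W`),
baseline variance `c₀`, and a low-rank input covariance
`C_inp = Σᵢ cᵢ ξᵢξᵢᵀ`.  Dimensionality is the participation ratio

    Dim(C) = (Tr C)² / Tr C² = (Σ λᵢ)² / Σ λᵢ²,

an effective count of explored activity modes between 1 and N.

The package's core result is a reduction of `Dim(C)` to *local* wiring
statistics: moments of two-branch connectivity motifs (chains, divergent,
convergent, reciprocal, and trace motifs), rewritten as cumulants and
resummed so that second-order measurements — quantities accessible to
multi-patch experiments — predict the global dimension.  For an
Erdős–Rényi network at effective coupling ρ = N⟨G⟩ the prediction
collapses to a closed form: with `x = (1 − ρ)⁻²`,

    Dim = (x + N − 1)² / (x² + N − 1),

falling from N (independent neurons) to 1 at the stability boundary.
Intended users are computational neuroscientists studying
connectivity–dynamics relationships and anyone needing a controlled
random-graph testbed (SONET second-order ensembles, small-world,
scale-free, balanced E-I) with exact linear-response answers.

## Worked example

```python
import numpy as np
from motifdim import (generate_sonet, SonetParams, EffectiveNetwork,
                      internal_covariance, participation_ratio,
                      measure_motifs, dim_from_cumulants, er_closed_form)

conn = generate_sonet(1000, SonetParams(p=0.05, alpha_recip=2.0,
                                        alpha_chain=0.3), seed=7)
net = EffectiveNetwork.from_connectivity(conn, gain=10.0, c0=1.0)

exact = participation_ratio(internal_covariance(net))
stats = measure_motifs(net.G, max_order=2)
theory = dim_from_cumulants(stats, c0=1.0)
er = er_closed_form(1000, rho=10 * conn.density())

print(f"spectral radius      {net.spectral_radius:.3f}")
print(f"exact dimension      {exact.raw:7.1f}  ({exact.normalized:.3f} of N)")
print(f"cumulant prediction  {theory.raw:7.1f}  ({theory.normalized:.3f} of N)")
print(f"ER closed form       {er.raw:7.1f}  ({er.normalized:.3f} of N)")
```

Output:

```
spectral radius      0.598
exact dimension        964.9  (0.965 of N)
cumulant prediction    974.0  (0.974 of N)
ER closed form         993.8  (0.994 of N)
```

The network explores ~965 of its 1000 possible modes.  The order-2 motif
cumulants predict this within 1%, while the ER closed form at the same
density overshoots by a factor of six in lost dimensions (6 vs 35): the
extra reciprocal/chain structure (alpha_recip = 2, alpha_chain = 0.3)
measurably lowers the dimensionality of the activity without changing the
connection count — the central point of the theory.

A CLI mirrors the library for shell use:

```bash
motifdim generate --model sonet --n 1000 --p 0.05 --alphas 2,0,0,0.3 \
         --seed 7 --out net
motifdim covariance --net net --gain 10 --out cov.h5
motifdim dim --cov cov.h5
motifdim ensemble --preset methods-d --scale small --seed 1 --out records.csv
```

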