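# restime

Bayesian nonparametric analysis of residence times from contact time
series, with kinetic mapping back onto the trajectory.

## The problem

Molecular-dynamics simulations of proteins in membranes (or with any
small-molecule partner) produce long series of binding and unbinding
events: a ligand enters the contact cutoff of a residue, stays for a
time *t*, and leaves.  The durations of these events rarely follow a
single exponential — brief "flicker" contacts from cutoff fluctuations
coexist with rare, long-lived specific binding.  The quantity of
interest is usually the **slowest** timescale, and fitting a
two-exponential curve to the survival function begs the question of how
many processes there really are.

`restime` treats the observed residence times t = {t₁, …, t_Ω} as draws
from a K-term exponential mixture (the hyperexponential distribution)

```
p(t | π, λ) = Σₖ πₖ λₖ exp(−λₖ t)
```

and infers the posterior over the weights π, rates λ, and a latent
per-event indicator zₙ by Gibbs sampling with conjugate conditional
posteriors:

- zₙ | π, λ, t  ∝  πₖ λₖ exp(−λₖ tₙ)   (categorical)
- π | z  ~  Dirichlet(γ + Ω)           (Ωₖ = events in component k)
- λₖ | z, t  ~  Gamma(αₖ + Ωₖ, βₖ + Tₖ) (Tₖ = total duration in k)

With γₖ = 1/K and K set well above the expected number of processes,
the finite mixture behaves like a Dirichlet-process prior: the data
decide how many components carry weight, so the number of kinetic
processes is learned rather than assumed.  Post-processing fixes the
label-switching degeneracy by clustering posterior samples in
(log λ, log π) space with a Gaussian mixture, discards diffuse noise
clusters, and reports per-cluster MAP rates and residence times
τ = 1/λ with 95% credible intervals.  Because the sampler also stores
the indicators, every binding event (and hence every trajectory frame)
gets posterior membership probabilities p_{n,k′} over the clusters —
the *kinetic mapping* — from which probability-weighted 3D ligand
densities per timescale are computed.

Intended users: anyone analyzing MD contact kinetics (protein–lipid,
protein–ligand, ion binding) who wants rigorous error bars on the
slowest residence time and a way to see *which* frames belong to it.

## Worked example

```sh
python examples/02_infer_residence_times.py
```

draws 5000 waiting times from a known two-component mixture
(π = (0.95, 0.05), λ = (5, 0.1) ns⁻¹), runs a short chain and prints:

```
K' = 3 clusters, 2 after noise removal:
  cluster 0: lambda =   5.043 /ns (4.892, 5.212)   tau =    0.20 ns (0.19, 0.20)   pi = 0.953
  cluster 1: lambda =   0.091 /ns (0.075, 0.109)   tau =   10.64 ns (9.13, 13.40)   pi = 0.042

slowest process: tau = 10.6 ns
```

Both true rates fall inside their credible intervals; the third, diffuse
cluster was flagged as noise and removed.  The other examples cover
event extraction from distance series (`01_contact_events.py`) and
kinetic mapping with weighted densities (`03_kinetic_mapping.py`).

A command-line interface mirrors the library
(`restime contacts | gibbs | cluster | map | density | synth | diff | run`);
`restime run --events events.csv --outdir out` performs the full
per-residue pipeline and writes chain archives, a cluster report, a
residence-time fingerprint table and a reproducibility manifest.

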