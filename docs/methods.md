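# Methods

## Model overview

`clusterdose` treats dose deposition around a cluster of ionised
nanoagents as a linear superposition problem, in direct analogy with the
electrostatic potential of a set of point charges. The "charge" of agent
`i` is its ionisation count `nᵢ`; the "potential" is the agent's radial
dose distribution (RDD) kernel, the orientation-averaged dose deposited
in water at distance `r` from the agent per ionisation event. The local
energy enhancement at a field point `r⃗` is

    L(r⃗) = Σᵢ nᵢ · RDD(g(|r⃗ᵢ − r⃗|)) / D,

the ratio of nanoagent-deposited energy to the uniform background dose
`D`. Superposition is exact if the agents do not perturb each other's
electron transport; the two perturbations that do exist are handled as
follows:

* **Scattering** by non-activated agents is neglected outright. The
  packed cluster is quasi-spherically symmetric, so scattering mostly
  redistributes energy within a shell rather than between shells, and
  the quantities of interest here are shell-integrated.
* **Extra energy loss** in the gold/water mixture is folded into an
  effective distance `g(r) = r_np + k·l_in + l_out`, where `r_np` is the
  source-agent radius, `l_in` the part of the straight source-to-field
  path inside the cluster but outside the source agent, `l_out` the
  remainder, and `k` the asymptotic ratio of electron stopping power in
  the mixture to that in water. The kernel already includes attenuation
  inside the source agent, so the `r_np` segment is never scaled. A
  line-integral reference (`effective_distance_line_integral`) integrates
  an arbitrary local stopping-ratio profile along the path and reduces
  exactly to the closed form for a uniform in-cluster ratio; it exists as
  a testing oracle, not a production path.

`k` has no hidden default: it depends on the gold loading and must be
supplied (``k = 1`` disables the correction and is flagged in the log).
Field points *inside* the source agent are evaluated at their Euclidean
distance with no correction, since the derivation of `g` assumes the
electron exits the agent; some rule is needed there because interior
dose maps are legitimate output.

## Kernels

Kernels are radius-binned tables (Gy per ionisation per bin). The
standard binning spans 0 nm to 1 cm in four segments (1 nm bins to
300 nm, 97 nm bins to 10 µm, 1 µm bins to 100 µm, 110 µm bins to 1 cm;
580 bins), resolving the short-range Auger-electron structure while
keeping the long tail cheap. Each bin is represented by the geometric
mean of its edges (arithmetic mean for the first bin, whose lower edge
is 0) because the kernels are near power-laws.

Continuous evaluation interpolates linearly in log(r)–log(dose) between
representative points — preserving power-law decay without negative
overshoot — with three special cases: below the first point the first
value is held constant; segments with a zero endpoint fall back to
linear interpolation on the raw values (log space cannot represent 0);
beyond the outer edge of the last non-zero bin the kernel is 0, and
between the last representative point and that edge the last value is
held (a constant hold avoids an artificial cliff inside the final bin).

No simulated kernel tables ship with the package; kernels from particle
transport codes can be read from delimited text
(`r_lo_nm, r_hi_nm, dose_gy_per_ionisation` with `#` metadata lines).
The synthetic family

    kernel(r) = A·r⁻²·exp(−r/λ)·(1 + Σⱼ hⱼ·exp(−(r−cⱼ)²/2wⱼ²)),  r ≤ r_max

emulates the qualitative shape of simulated nanoparticle kernels: an
`r⁻²` geometric dilution (electrons spreading over 4π), an exponential
attenuation scale λ, and Gaussian bumps standing in for the discrete
penetration depths of Auger-electron groups. Without bumps the shell
integral `∫ kernel·4πr² dr = 4πAλ(e^(−a/λ) − e^(−b/λ))` is closed-form
and anchors the quadrature tests. What the synthetic family does *not*
emulate: per-primary normalisation, statistical noise in simulated
kernels, and any dependence of kernel shape on cluster environment — so
tests passing on synthetic kernels validate the machinery, not any
specific agent's absolute dose values.

## Cluster packing

Agents are packed by random sequential addition: candidate centres drawn
uniformly in the ball of radius `R_cluster − r_agent` (whole agent inside
the cluster), rejected on overlap with any accepted centre (pairwise
distance < 2·r_agent). At the fill factors of interest (≤ 30%, typically
10%) RSA realises the intended uniform placement; near jamming it would
not, and the spec of the packing deliberately caps the fill factor. The
agent count is `round(fill · R³/r_agent³)`; the fill factor counts
whole-agent (core + coating) volume, since coatings exclude volume for
other agents. Overlap queries use a uniform cell grid (cell = one agent
diameter, 27-neighbourhood search), which is exactly equivalent to the
naive all-pairs check and is tested against it. The attempt budget is
1000 attempts per agent; exhaustion raises an error reporting progress.

Two small systematic effects of the construction are worth knowing:
centres are confined to the allowed ball, so the ensemble-average gold
density has a plateau slightly above `fill·(r_core/r_agent)³` and dips
within one agent radius of the cluster surface; and RSA rejection biases
centre positions measurably at a few percent fill when sample sizes are
large (the uniformity test is therefore run at 1% fill, where the bias
is below detection at the test's sample size).

## Activation sampling

Each agent's ionisation count in a dose `D` is Poisson with mean
`rate·D`; agents with zero events are pruned. When the per-agent mean is
at most 1e-3 (double-event probability < 5e-7 per agent) the binomial
single-event path is statistically indistinguishable: draw the number of
activated agents from `Binomial(N, 1 − e^(−μ))`, give each one event.
Above that threshold the binomial path refuses and directs to the
Poisson path. For clusters of more than 200 000 agents (e.g. 1.56
million 1 nm agents at 10% fill) the full centre list is never
materialised: only the activated agents receive coordinates, drawn
uniformly in the allowed ball (`sample_sparse_realization`); at
single-event activation levels the probability that two activated agents
overlap is negligible.

The closed form `P(any agent ≥ 2 events) = 1 − (e^(−μ)(1+μ))^N`
(per-agent mean μ = cluster mean / N) is evaluated in log space. For the
reference 711-agent cluster at 10 events/Gy it gives 0.0673.

## Shell statistics and sensitive-volume integrals

`S₁(r)` and `S₂(r)` are surface integrals of `L` and `L²` over spheres
centred on the cluster, estimated by the equal-weight average over a
Vogel (spherical Fibonacci) spiral of `n = 1000` points (configurable)
times `4πr²`. For a central source the estimate is exact by symmetry;
for off-centre sources 1000 points agree with dense random quadrature to
better than 2%. `⟨L⟩` is reported as the *surface* average `S₁/(4πr²)`
(the natural companion of the surface integrals; a ball average would
mix shells).

The cell model is a spherical cell (default radius 15 µm) with a
concentric nucleus (default 7 µm) and the cluster centre at distance `d`
from the cell centre. With no preferred cluster orientation, volume
integrals over a target reduce to `I = ∫ S(r)·Ω(r)/4π dr`, with `Ω(r)`
the analytic sphere-in-ball solid angle:

    Ω = 4π                      if d + r ≤ R        (sphere inside ball)
    Ω = 0                       if r ≥ d + R or d ≥ r + R   (disjoint)
    Ω = 2π(1 − (d²+r²−R²)/2dr)  otherwise           (spherical cap)

continuous in `r`; cytoplasm = cell − nucleus. The quadrature is
trapezoidal on the shell-table radii, split at the contact radii
`|d ± R|` of each ball where Ω is kinked (a sharp step when `d = 0`), so
nucleus, cytoplasm and whole-cell integrals share one grid and are
exactly additive. The radial domain starts at the cluster radius — the
cluster interior is taken as biologically inert — with an
`include_cluster_interior` switch to start at 0 for the alternative
assumption. Standard placement presets `d ∈ {7500, 11000, 14500, 26000}`
nm cover just-outside-the-nucleus, mid-cytoplasm, near-membrane and
outside-the-cell scenarios.

Local-effect-model outputs: expected lethal lesions
`⟨N⟩ = αD + βD² + (αD·I₁ + βD·I₂ + 2βD²·I₁)/V_sens` and
`DEF = I₁(α + 2βD)/(V_sens(α + βD))`, the relative lesion enhancement
with `I₂` neglected (it is orders of magnitude below `I₁` in practice;
the identity `DEF = (⟨N⟩(I₁, I₂=0) − ⟨N⟩₀)/⟨N⟩₀` is tested to machine
precision). Multiple clusters per cell scale the per-cluster integrals
linearly and are left to the caller.

## Pipeline, determinism and problem sizes

The pipeline is a pure function of (config, root seed): per-realization
seeds are drawn from a generator seeded with the root seed, cluster
packing and activation use those sub-seeds, and reruns produce
byte-identical tables. Only descriptive statistics are reported — mean
and population standard deviation over the ensemble — because the spread
*across* clusters is itself the quantity of interest, not an error bar
on the mean.

Defaults mirror the reference scenario used throughout the package:
500 nm cluster radius,
10% fill, 1 Gy, 1000 surface points, 100-cluster ensembles, 7/15 µm
nucleus/cell radii. The shipped test suite and the acceptance script use
smaller ensembles (3–10 clusters) and coarser surface quadrature where
the check is about invariance or determinism rather than statistical
convergence; the packing and solid-angle oracles run at full size (100
seeds, 10⁶ Monte-Carlo samples).

## Known limitations

* No secondary scattering, track structure, radical chemistry or time
  dependence; the formalism is purely geometric superposition.
* RDD kernels are inputs; the package does not compute them, and the
  synthetic family is qualitative only.
* Monodisperse spherical agents in a spherical cluster; no aggregation
  physics or polydispersity.
* The auranofin preset's gold mass fraction defaults to the molecular
  value (~0.29); the effective value for a transport-derived nano-object
  model may differ and should be set in the config.
* The binomial path requires the single-event regime; it refuses rather
  than approximate outside it.
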