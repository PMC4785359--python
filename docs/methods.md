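# Methods

## Model and reduction

The circuit is a single autoregulated gene. Transcription runs at a basal
rate `k_m0` and at `k_m0 + k_ma` when the promoter is bound (by a monomer
pair for the cooperative motif, by a dimer for the dimer motif); mRNA,
monomers and dimers decay at `γ_m`, `γ_p`, `γ_p2`; translation produces
`b = k_p/γ_m` proteins per mRNA on average. A system-size parameter `Ω`
scales molecule numbers at fixed concentrations, so the same scaled circuit
can be studied at any copy number.

Three timescale assumptions collapse the network to one variable, the
scaled total protein `x = ρ + 2ρ₂` (concentrations in units of `K`, time in
protein lifetimes):

1. mRNA turns over fast (`γ_m ≫ γ_p`): translation becomes a burst process;
2. the monomer–dimer pool equilibrates fast: `ρ₂ = cρ²`, `c = K/K₁`;
3. the promoter equilibrates fast: occupancy `ρ²/(1+ρ²)`.

The resulting drift is `Φ(x) = S₀ + S_a ρ²/(1+ρ²) − ρ − 2αρ²` with
`α = d·c` (`d = γ_p2/γ_p`); the dimer-decay constant is implemented as this
product, validated by the `α → 0` cooperative limit and by simulation
agreement. The noise intensity sums propensity × squared stoichiometry over
the three effective reactions: bursty synthesis (events of size `q` at rate
`F/q`, contributing `q·F`), monomer decay (weight 1) and dimer decay
(weight 4, two protein units per event):
`θ(x) = [qF + ρ + 4αρ²]/(2N)`. The weight 4 follows from the stoichiometry
argument and is checked against simulated stationary variances. `θ` is
exact only at fixed points (where the linear-noise variance it implies,
`C = −θ/Φ′`, matches the full network); carrying the same form everywhere
is the interpolating assumption that makes the pseudo-potential
`Ψ' = −Φ/θ` integrable. Promoter-state noise is excluded from `θ`
(fast-promoter assumption); the simulator keeps promoter kinetics explicit
precisely so that assumption can be probed.

## Effective stoichiometry

`q` is defined operationally: the value for which the reduced model's
stationary variance equals the full network's fluctuation–dissipation
variance of total protein (`fdt.match_q`, a scalar root solve around a
Lyapunov solve). For constitutive expression the match has the closed form
`q = 1 + 2b/(1 + γ_p/γ_m)`, hence `q = 1 + 2b` under rapid mRNA decay; the
package uses `1 + 2b` as the default and `match_q` as the numeric check.
A consequence worth noting: the spec-level claim "reduced variance with
`q = 1+2b` matches the full model within 1%" holds from `γ_m/γ_p ≈ 100`
upward (at ratio 50 and `b = 10` the deviation is 1.8%); tests therefore
use ratio 100.

## Linearization choices

`fdt.linearize` always eliminates the promoter adiabatically: its
equilibrium occupancy (and the occupancy gradient) enters the transcription
row of the Jacobian, and — promoter binding being non-sequestering — it
contributes nothing to the diffusion matrix of (M, P, P2). An explicit
promoter species was considered and dropped: every variance comparison in
the package operates in the fast-promoter regime, and the stochastic
simulator already exposes the finite-speed physics.

## Escape times

Three estimators share one `PotentialProfile` (uniform grid from 0, Simpson
cumulative integration of `−Φ/θ`, gauge `Ψ(x_L) = 0`; the upper boundary is
placed where `Ψ` exceeds `Ψ(x_H) + 30`, beyond double-precision relevance):

* **quadrature** — the exact nested mean-first-passage integrals
  (reflecting at 0, absorbing at the opposite stable state), evaluated
  entirely in log space (cumulative log-sum-exp) so deep wells never
  overflow; overflow of the final time (log Γ > 700) raises rather than
  saturates;
* **parabolic** — the saddle-point formula
  `Γ = 2π e^{ΔΨ}/(θ(x_s)√(Ψ″(x_s)|Ψ″(x_M)|))`; second derivatives come
  from quadratic fits over ±5% of the inter-fixed-point distance (robust
  near flat extrema, accurate to ~0.1%);
* **constant-noise** — `θ` frozen at the origin well, the classical
  comparison baseline.

Times are in protein lifetimes throughout; divide by `γ_p` for absolute
time. Root finding for fixed points sign-scans 2000 log-spaced points up to
`x_max = 2·g(S₀+S_a)` (`g(ρ) = ρ + 2cρ²`, a bound valid for both motifs)
with Brent refinement at 1e-12 relative tolerance; roots closer than 1e-6
relative are merged and flagged marginal, since escape theory is
meaningless at a vanishing barrier. The bistability boundary solves
`Φ = Φ′ = 0`, which at fixed double-root location is *linear* in
`(S₀, S_a)` for both motifs and is therefore solved exactly rather than
iteratively.

## Exact simulator and its kinetic conventions

The Gillespie kernels (numba) simulate transcription, mRNA decay,
translation, monomer decay, dimerization/dissociation, dimer decay and
promoter binding/unbinding. Three conventions matter, because barrier
heights multiply concentration-level biases by `N` and exponentiate them:

* **Cooperative promoter = concerted pair binding** (`k_on P(P−1)`,
  `k_off/k_on = (KΩ)²`), the limit of two sequential sites with strongly
  asymmetric affinities. A resolved single-bound intermediate at affinity
  ratio 100 depresses occupancy by a few percent and destabilized the high
  state several-fold in early experiments; the concerted limit realizes
  the exact Hill-2 occupancy the reduced model assumes.
* **Promoter speed**: each activation delivers a transcription burst of
  ~`N·S_a/κ` proteins (`κ` = promoter_timescale). Presets choose
  `κ ≳ 2·N·S_a` so this stays below one molecule; at slower `κ` the extra
  promoter noise visibly accelerates switching (that knob is deliberately
  exposed).
* **Dimer-pool equilibrium**: dimerization uses
  `k₁ = (k₋₁ + γ_p2)/K₁`, so the *stationary* pool satisfies `p₂ = p²/K₁`
  exactly at any finite exchange speed — otherwise the pool runs
  `γ_p2/(k₋₁+γ_p2)` low, which the feedback amplifies exponentially.
  A separate `dimer_timescale` decouples (cheap) pool exchange from
  (accuracy-critical) promoter speed.

Promoter binding is non-sequestering (one promoter among hundreds of
molecules). First-passage replicates start at the integer-rounded origin
fixed point, relax for 5 lifetimes confined to the origin basin (restart on
saddle crossing), then run to absorption at the opposite stable point — the
same boundary conditions the quadrature integrates. Censored replicates are
recorded, never dropped.

## Presets and problem sizes

The source material constrains but does not print its parameter points, so
presets are reconstructions: `fig2-cooperative` (S₀ = 0.08, S_a = 2.0) with
`fig3-low80/low160` the same point at `N = 800/1600` (low state 80/160
proteins, barriers ≈ 18/12 and 37/23 — the deep regime where only the
analytic estimators are practical, with switching rates down to ~1e-9 per
lifetime); `fig2-dimer-alpha05/alpha1` with `d = 0.1` (decay-rate ratio 10)
and `c = 5/10`.

The `bench-*` presets exist because exact first-passage sampling at desk
scale needs moderate, balanced barriers (ΔΨ ≈ 4–6, escape times 1e3–2e4
lifetimes) and wells spanning hundreds of molecules (small jump-size
corrections to the diffusion approximation). Both sit near the cusp of
their bistable region: `bench-cooperative` (S₀ = 0.13, S_a = 1.8,
N = 1100) and `bench-dimer` (S₀ = 0.08, S_a = 3.5, α = 0.5 realized as
c = 0.3, d = 5/3 to keep the simulated dimer pool sparse — the reduced
model depends on `c` and `α` only, and its fidelity in `c` is tested
separately). Test sample sizes (200/20 and 60/40 replicates; 50 per point
for the system-size scan) keep the stochastic test tier around ten minutes
on one core while leaving mean estimates at ≤15% standard error.

## What the generator does and does not emulate

Synthetic data are SSA trajectories of the full network: they contain
promoter, mRNA, dimerization and copy-number noise exactly as modeled, so
passing tests show the *reduction and escape theory* are consistent with
the *network as specified*. They do not contain extrinsic noise (rate
fluctuations), cell division/partitioning, or slow chromatin states; no
claim about real expression data follows beyond the model's scope.

## Numerical tolerances and degenerate inputs

Grid default 4001 points (profile discretization error ≪ 1% of Γ);
Lyapunov solves are residual-checked to 1e-10; boundary rows satisfy
`|Φ| < 1e-10`, `|Φ′| < 1e-8`; non-bistable parameters raise before any
escape computation; `θ ≤ 0` or non-finite anywhere on a grid raises. The
fluctuation–dissipation sign convention: the code stores the plain Jacobian
`J` (drift `+Jx`), so the one-dimensional identity reads `C = −D/(2J)`.

## Known limitations

The Fokker–Planck description of a jump process is itself an approximation:
with translational bursts of size `q` the true master-equation escape
exponent deviates from `∫Φ/θ`, and on the benchmark points the residual
mismatch between exact simulation and quadrature is 10–40% (well inside the
factor-2 agreement the comparisons assert, but systematic — low→high
escapes run slightly fast, as burst tails cross barriers more easily than
diffusion). At low-state occupancies of a few molecules the continuum
theory degrades further; presets avoid that regime. WKB/large-deviation
corrections and multivariate escape paths are out of scope.
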