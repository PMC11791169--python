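# Methods

## Models

**Gene-expression network.** DNA binding sites `D` bind a repressor `P` at
propensity `(kf/omega) D P` and unbind at `kb` per complex; each free site
transcribes mRNA `M` at `kp`; `M` degrades at `kd`. A DNA molecule with two
sites can be tracked explicitly (states `D00, D01, D10, D11`, transcription
at `2kp, kp, kp, 0`) or through the number of free sites only
(`D = 2 D00 + D01 + D10`). The two descriptions generate identical mRNA
statistics because every propensity depends on the occupancy count, not on
which site is occupied; the package keeps both and tests their equivalence
distributionally (Kolmogorov-Smirnov on terminal mRNA, plus matched means).
The activating variant moves transcription from `D` to the complex `D:P`.

**Spatial model.** A 1-D domain of length `L` is split into `K` compartments
of size `h = L/K` (2-D: a rectangle into `K1 x K2` cells). Reactions run
independently per compartment with system size `omega = 1` per compartment;
free protein hops to each lattice neighbour at `d = delta / h^2` (4-neighbour
stencil in 2-D); boundaries are reflecting (edge compartments simply lack the
outward hop). This is the standard compartment/lattice realisation of the
reaction-diffusion master equation, and it remains an *exact* jump process —
hops are ordinary first-order channels, so the direct-method SSA applies
unchanged. The matched well-mixed model uses the same rate constants with
`omega = K` and the space-summed initial condition.

**Default geometry and rates** (gene-expression scenarios): `L = 10` um
(a mammalian nucleus), `K = 30` (so `h = 1/3` um; doubling K leaves the
statistics unchanged, see below), `kf/omega = 5000 /s`, `kb = 100 /s`
(per-compartment `Kd = 0.02`: tight binding), `kp = 50 /s`, `kd = 0.001 /s`,
horizon 50 s. Diffusion `delta = 20` um^2/s ("fast", hop rate 180 /s,
typical of nuclear proteins) or `0.2` um^2/s ("slow", hop rate 1.8 /s, the
PER2 regime). Note `h` is kept exact (`1/3`), not the rounded 0.33 um, so
the fast hop rate is exactly 180 /s. The activating variant uses
`kf/omega = 700 /s`, `kb = 900 /s`.

**Initial conditions.** DNA is immobile at the centre compartment
(compartment 15 of 30, by convention). Presets: uniform protein (1 per
compartment, total 30) with one site; the same with slow diffusion;
peripheral protein accumulation (5 per compartment outside the central ten,
1 inside; total 110) with one site; two sites with uniform protein. The
sparse init syntax (`D@15=1`, `P@11-20=1`, `P@*=5`) applies wildcards first
so explicit entries override them.

## QSSA reductions

When binding/unbinding is fast relative to everything else, the free-site
count inside a compartment equilibrates conditional on the totals
`D_T = D + D:P` and `P_T = P + D:P`. The reduced state per compartment is
`(D_T fixed, P_T, M)`; transcription fires at `kp * D_q`, protein hops (and,
in the oscillator, degrades) at rate proportional to the expected *free*
protein `P_q = P_T - (D_T - D_q)`, and each event moves one unit of total
protein. Propensities are real-valued expectations while states stay
integer; expected free proteins are clamped to `[0, P_T]`.

* **slQSSA**: `D_q` is the exact stationary mean of the binding birth-death
  chain. It is evaluated by a term-ratio recursion (no factorials), and a
  separate closed-form specialization exists for `D_T <= 3`. The printed
  source for the two/three-site closed form is internally inconsistent, so
  the closed forms here are derived directly from the general stationary
  ratio and tested for algebraic identity with it.
* **stQSSA**: `D_q` is the root of
  `x^2 - (D_T - P_T - Kd) x - Kd D_T = 0` with `0 <= x <= D_T`. The
  expression is sometimes printed with the opposite sign on the radical,
  which is negative for all admissible inputs; the nonnegative branch is
  the standard total-QSSA choice and the one implemented.

`Kd` in reduced spatial models is the per-compartment value
`kb / (kf/omega)` with `omega = 1`.

**Oracle.** The reversible-binding chain with `n` bound complexes has birth
rate `(kf/omega)(D_T-n)(P_T-n)` and death rate `kb n`; its stationary law
follows from detailed balance, computed in log space. The slQSSA agrees
with this oracle to 1e-10 over `D_T <= 4`, `P_T <= 12`,
`Kd in {1e-3, 0.02, 1, 1e3}` (asserted). The stQSSA's relative error versus
the oracle has a ridge at `D_T ~ P_T` for tight binding; at
`D_T = P_T = 1`, `Kd = 0.02` it returns 0.1318 against the exact 0.0196
(relative error ~5.7).

## Oscillator

Whole-cell domain: 30 compartments of `h = 1` um, nucleus = compartments
11-20, DNA with two binding sites at compartment 15. Free sites produce `P`
at `kp = 10 /s` per site; each new protein appears at the cell periphery and
diffuses back (hop rate `d = 1.8 /s`); binding `kf/omega = 1e4 /s`,
unbinding `kb = 100 /s` (so per-compartment `Kd = 0.01`; an override exists
because the source quotes 0.02 alongside rate constants implying 0.01 — the
rate constants win here); free protein degrades at `kd = 0.01 /s`
everywhere; bound protein is protected (the model never degrades the
complex). Horizon 5000 s, sampled at 1 s. Peripheral delivery is realised
as two production channels of rate `kp D / 2` targeting compartments 1 and
K — distributionally identical to a fair coin flip per event and symmetric,
so no drift. Production draws on the total free-site count (not per side).
The hop rate 1.8 /s is adopted from the methods' explicit value; the
figure-level diffusion coefficient 0.2 um^2/s would give 0.2 /s at this
`h` and is not used.

## Period estimation

For each run the total protein (bound included) over the last 2500 s of the
5000 s horizon enters the normalised autocorrelation
`C(s) = <[x(t+s)-xbar][x(t)-xbar]> / <[x(t)-xbar]^2>`, computed with
per-lag overlap normalisation (so a pure sinusoid yields a pure cosine,
`C(0) = 1` exactly) and lags cut at half the window. `C(s)` is fitted with
`exp(-s/tau) cos(2 pi s / T)` by bounded least squares
(`T in [2 ds, window]`, `tau in (0, 10 window]`), initialised at the
dominant spectral peak of `C` and `tau = window/4`. A fit is accepted when
it converges, explains at least 20% of the autocorrelation variance
(R^2 >= 0.2), and resolves at least ten samples per period — the last
condition rejects pure-noise fits that lock onto grid-scale wiggles.
Failures are flagged and counted, never silently dropped or returned.

## Simulation kernel

Gillespie direct method: exponential waiting time from the total propensity,
channel selection by cumulative-sum search in declaration order. After each
event only propensities reading a changed state entry are recomputed (a
reverse dependency map built at compile time); the running total is re-summed
every 4096 events to bound floating-point drift. Zero total propensity
jumps straight to the end of the grid (no busy-waiting). Sampling is
zero-order hold: each grid time records the last state at or before it.
One seeded legacy Mersenne-Twister stream per run; ensemble run `r` uses
`base_seed + r`, so enlarging an ensemble extends rather than reshuffles it.
The default sampling grid is 0.1 s for the 50 s scenarios and 1 s for the
5000 s oscillator (the underlying jump process is exact regardless of the
grid; the grid only controls the output resolution).

## Lattice-refinement convention

Refining the lattice at fixed physics requires rescaling the bimolecular
propensity: halving the compartment volume doubles the local concentration,
so the doubled-resolution scenario uses `kf/omega = 10^4 /s` at `K = 60`
(i.e. `kf/omega` scales with `1/h`), keeping the homogenised dissociation
constant fixed. With this convention the K = 30 and K = 60 statistics agree
within Monte Carlo error in the fast-diffusion regime. In the
diffusion-limited, tight-binding regime a residual `h`-dependence of the
mean of order 10% remains — a known property of lattice
reaction-diffusion master equations with bimolecular reactions, where the
effective binding rate depends on compartment size near the
diffusion-limited regime. The refinement check is therefore run under fast
diffusion, where the claim is unambiguous.

## Ensemble sizes and test design

The published comparisons use 1,000 runs per ensemble. The test suite and
the acceptance script scale this to 100-1,000 runs depending on the cost of
the scenario, with statistical acceptance thresholds expressed in standard
errors (3 SE two-sided for equality claims; one-sided z or Mann-Whitney at
p < 0.01 for ordering claims) so that conclusions do not depend on the
ensemble size chosen. Seeds are fixed throughout; identical
(system, initial state, seed) triples reproduce bit-identical trajectories.

## What the synthetic scenarios do and do not capture

The scenarios are the study conditions themselves (they are simulations, not
fits to data): point-localised DNA, uniform or step-profile initial protein,
reflecting boundaries, a single diffusing species. They do not emulate
crowding, nuclear substructure, active transport, 3-D geometry, or
transcription bursting beyond the binding-site mechanism. Passing tests
establish the numerical claims about these models — not that the models
describe any particular cell type quantitatively.

## Known limitations

* QSSA-reduced models are hybrid approximations: propensities use expected
  counts, so they are no longer exact realisations of any master equation;
  their accuracy is exactly what the comparisons measure.
* The stQSSA is included deliberately as the cautionary baseline; nothing
  prevents its use where its validity conditions fail locally.
* The RDME bimolecular `h`-sensitivity above means "spatial SSA" results at
  a single `K` in the diffusion-limited tight-binding regime carry a
  lattice-convention dependence of order 10%.
* Wall-clock speed-ups of the reduced models (the binding/unbinding channels
  dominate event counts in the slow-diffusion scenarios) are real but
  hardware-dependent; they are reported informally and never asserted by
  tests.
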