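# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `polyphase`, in the spirit of a simulation paper's methods
section. Everything quantitative stated here is computed by the test suite
or the acceptance script; nothing is quoted from elsewhere.

## Energy model

The chain is a bead-spring homopolymer in implicit solvent. Non-bonded
monomer pairs `(i, j)` with `i > j + 1` interact through a 12–6
Lennard-Jones potential truncated at `r_c = 2.5σ` and shifted by
`V_shift = V_LJ(r_c) ≈ −0.016317 ε` so the potential is continuous at the
cutoff. Bonded neighbors feel a FENE spring plus the same shifted LJ term;
the logarithmic barrier confines bonds to `(r₀ − R, r₀ + R)` with
`R = 3/7 r₀`, and any Monte Carlo proposal that would leave that interval
has infinite energy and is rejected. Note that next-nearest pairs
`(i, i+2)` *are* included in the non-bonded sum. Semiflexibility enters as
`κ(1 − cos θ)` per interior bond angle, with `θ` measured between
successive bond vectors so that a straight chain has `θ = 0` — with the
reference angle at zero, stiff chains favor long straight segments, which
is the intended physics.

Parameters, reduced units (`k_B = ε = r₀ = 1`):

| parameter | value | meaning |
|---|---|---|
| `σ` | `2^(−1/6)` | LJ length; potential minimum at `r₀` |
| `r_c` | `2.5σ` | non-bonded cutoff |
| `R` | `3/7` | FENE range |
| `K` | `98/5` | FENE stiffness |
| `κ` | 0, 1, 2 | bending stiffness (study values) |
| `θ₀` | 0 | reference bond angle |

`energy_delta` re-evaluates only interactions touching moved monomers and
agrees with full recomputation to 1e−9 relative; walkers additionally
resynchronize with a full recomputation every 10⁴ sweeps to cap float
drift (measured drift after hundreds of sweeps is ~1e−15).

For gradient-based minimization (`energy_and_grad`, used by the annealing
polish and by test oracles) the FENE barrier is continued by a
value-and-slope-matched quadratic beyond `|r − r₀| ≥ R(1 − 10⁻⁶)`, so line
searches never encounter an infinite value; all minima of interest lie far
inside the interval, where the two functions are identical.

## Replica-exchange sampler

Replicas run at a geometric temperature ladder on `[0.1, 5.0]` (geometric
spacing roughly equalizes neighbor overlap when `C_V` varies slowly; the
ladder is fully configurable). One sweep is N single-monomer displacement
attempts with uniform proposals in a cube of edge `r_d`. Every 20–70
displacement sweeps (linear in thread index: cold threads pivot rarely,
since pivots almost never succeed in compact states) a sweep of pivot
rotations is made: the tail beyond a random monomer rotates rigidly about
an axis drawn uniformly on the sphere, by an angle uniform in `[0, 2π)`.
Neighboring threads attempt conformation swaps every 1500 sweeps with the
standard exchange probability, alternating even/odd pairings.

The walker first equilibrates, then `r_d` is tuned per thread by
multiplicative feedback `r_d ← r_d·exp[0.1(acc − ½)]` over 60 blocks of 50
sweeps toward the 50% acceptance target, and frozen before measurements
(tuning after equilibration matters: the optimal step size of a collapsed
globule differs from an extended coil's). Threads straddling a sharp
transition can fluctuate between phases and end a few points off target;
this is logged as a warning and is physically expected. One measurement
(energy, `R²_gyr`) is taken per sweep. Each thread owns an RNG spawned
from the master seed, so runs are bit-reproducible.

The displacement sweep's inner loop is compiled with numba when available
(~30× wall-time speedup); a numpy fallback implements the identical
update, so results never depend on the accelerator, only timing does.

## Ground-state search

Simulated annealing cools a walker through a geometric schedule
(default T = 2 → 0.01 in 50 stages, 200 sweeps each), mixing displacement,
pivot and *reptation* (slithering-snake) moves; reptation detaches one end
monomer and re-attaches it beyond the opposite end, which is the only move
in the set that can re-thread a chain through a compact cluster. Every
restart's best state is polished by L-BFGS on the smooth energy, and the
overall best then enters a threading-refinement stage: a Metropolis walk at
T = 0.005–0.01 over reptation + local-minimization steps. This matters
because a collapsed N=13 cluster supports many near-degenerate threadings
(center monomer at a chain end vs. interior, different surface paths)
within ~10⁻² ε of each other; the refinement reliably reaches the global
threading (E = −43.0273 for N=13, κ=0, reproducible to ~2·10⁻⁶ across
seeds), which single-monomer and pivot moves cannot do at low temperature.
Reptation proposals are not exactly detailed-balanced (the re-attachment
bond length is drawn from a narrow window); they are used only in the
optimization stages, never in the measurement sampler.

## Multi-histogram reweighting

The per-thread histograms are combined by iterating the standard
multi-histogram equations to a fixed point. `ĝ(E)` spans hundreds of
orders of magnitude, so every accumulation uses log-sum-exp. Convergence is
declared when every `ln Z_k` changes by less than 1e−7 (configurable);
10⁵ iterations is the cap, with a warning and the residual on expiry.
Bins with zero total counts are excluded rather than interpolated — no
entropy is fabricated. If the thread histograms do not overlap into one
connected energy range, the estimator is ill-posed and `wham_iterate`
raises, identifying the disconnected thread groups. Observable reweighting
stores per-bin conditional means of `R²_gyr` accumulated during sampling;
`d⟨O⟩/dT = β²(⟨OE⟩ − ⟨O⟩⟨E⟩)` is used for the structural fluctuation
curve, which the tests cross-check against finite differences and against
closed-form Gaussian moments.

## Microcanonical analysis

`S(E) = ln ĝ(E)` (additive constant fixed by normalizing `max ln ĝ = 0`;
all derivatives are invariant under that choice). Smoothing uses a single
Bernstein–Bézier curve over the full window with the data as control
polygon — the canonical smoothing in this literature, chosen because the
Bernstein operator preserves the monotonicity and convexity of the data,
so smoothing can never *create* backbending. Derivatives come from the
hodograph (finite differences of control points), evaluated in the log
domain for stability at degree of several hundred.

Numerical properties worth knowing:

* Control abscissae are made exactly uniform (integer-stride decimation
  for binned data); non-uniform control spacing makes `E(t)` non-affine
  and injects spurious wobble into second and third derivatives.
* Smoothing strength scales with control density, so dense data is
  decimated to `decimate` points (default 100) before fitting. The
  operator bias is O(1/n): on a cubic the smoothed third derivative is
  exactly `(1 − 1/n)(1 − 2/n)` times the true one. Extremum *locations*
  shift by O(window/n); with the default settings this is below one
  control-grid spacing.
* Jackknife bands measure run-to-run scatter only — they do not contain
  the (shared) smoothing bias. Bands are therefore interpretable when the
  smoothing is weak enough that its bias is subdominant to the sampling
  noise; with strong decimation of very precise data the bias dominates
  and coverage degrades. Choose `decimate` accordingly.

Detection scans the energy window where at least two runs have support
(histogram edges are noisy). A least-sensitive inflection point of a curve
is operationalized as a local extremum of its derivative, found by strict
peak detection with a relative prominence floor of 1e−8 to suppress
float-level wiggles. Classification applies, in order: (1) first order —
positive-valued minimum of `β`; (2) independent second order —
negative-valued maximum of `γ`; (3) dependent second order —
positive-valued minimum of `γ` above an identified first-order transition;
(4) independent third order — positive-valued minimum of `δ`;
(5) dependent third order — negative-valued extremum of `δ` above an
independent lower-order transition (the theory fixes only the sign for
this case; the implementation accepts either extremum kind and flags the
record). All records require `β(E_tr) > 0`. Every qualifying extremum is
reported, ranked by signal strength within each order — real systems carry
several transitions, and pruning is the analyst's job, aided by two
safeguards: a signal only counts when its extremal value exceeds one
jackknife standard error (without bands, records are flagged
`unvalidated`), and a first-order candidate whose associated `γ` peak
straddles zero within one standard error is reported as first order with a
`borderline` flag rather than forced into a binary call — the
first-vs-second-order boundary is genuinely soft at intermediate
stiffness.

The statsmodels-style front end `MicrocanonicalAnalysis(dos_runs).fit()`
bundles smoothing, jackknife and classification and returns a results
object with `curves`, `transitions`, `summary()` and `plot()`.

## Synthetic fixtures

The analytic density-of-states families exist so that every downstream
stage has inputs with exact ground truth:

* `gaussian`: `ln g = −E²/(2s²)` on a window with `E < 0` so `β > 0`;
  closed forms `⟨E⟩ = −βs²`, `C_V = β²s²` check the canonical machinery,
  and the monotone derivative hierarchy checks the no-false-positive
  behavior of the classifier.
* `first_order_toy`: `β = b₀ + c(E−E_t)²` — a planted positive β-minimum.
* `second_order_toy`: `γ` is a negative-valued Lorentzian peak, integrated
  to `β` and `S` in closed form.
* `third_order_toy`: `δ = d₀ + c(E−E_t)²` with `γ < 0` and `β > 0`
  enforced, planting only the third-order signal.
* `composite`: built from `δ = k(v−a)(v−b)` with `b/3 < a < b`, which
  yields an independent first-order transition and a dependent
  second-order companion at higher energy, in one smooth closed form.

Constructors validate physicality (`β > 0` everywhere; negative `γ` peak
value) and raise otherwise. Seeded random parameterizations draw from
documented ranges chosen once so the planted structure is well conditioned
for detection (sharp enough extrema, window margins proportional to the
feature scale); the Lorentzian/cubic tails of these families also imply
genuine secondary records under the rules (e.g. the `δ` dip that
accompanies any `γ` peak is a dependent third-order signal), so recovery
tests assert that planted records are found, not that nothing else is.

Canonical histograms are drawn i.i.d. (multinomial) from the discretized
Boltzmann distribution of the fixture — deliberately not Markov-chain
sampling, so WHAM's error behavior is exactly interpretable and isolated
from sampler autocorrelation. What these fixtures do *not* emulate: the
actual polymer's density of states, autocorrelated Markov-chain noise, and
WHAM's correlated bin errors. Passing the synthetic pipeline therefore
validates the analysis chain, not the sampler — the sampler has its own
oracles (dimer bond-length quadrature, exchange-invariance, ergodicity
checks, basin-hopping ground states).

## Study pipeline and scales

`run_study` loops over stiffness values; per κ it runs `n_runs`
independent replica-exchange simulations (seeds spawned from the master
seed), one WHAM estimate per run, jackknife-combined curves, transition
classification, annealing-refined ground state, and the structural
analysis (pair distribution at `r_t = 0.01`, contact maps at cutoff 1.2
with bonded pairs excluded, streak counts with a ≥3-contact threshold for
calling a hairpin or helix motif). Every artifact is written per
(κ, run) for the raw histograms and per κ for analysis products, plus a
study-level transition table; the energy-shift convention
(`ΔE = E − E_min^(κ)`, with the `E_min` used) is recorded in the report.
An analytic fixture can be injected in place of the simulation stage,
which is how the pipeline itself is tested end to end.

Shipped scales: `smoke` (N=13, 8 threads, 2 runs — minutes), `desk`
(N=30, 16 threads — an afternoon), `paper` (N=55, 48 threads, 2·10⁶
measurement sweeps, 10 runs — hours to days on a multicore workstation;
this is the scale at which the flexible chain's freezing transition
appears as a first-order backbending signal distinct from the Θ collapse,
and at which the κ=2 chain's freezing signal is absent). The tests and
the worked example use the small scales; the large-scale study is a
supported configuration, not a CI job.

## Known limitations

* No dihedral/torsion potential, solvent particles, or periodic boundaries
  — the model is a free chain in implicit solvent.
* Transition detection is capped at third order by design.
* Pivot moves always rotate the tail section; for very long chains a
  head/tail choice would mix faster.
* The jackknife bands exclude smoothing bias (see above); with fewer than
  two independent runs no bands exist and records are flagged.
* Reptation breaks strict detailed balance and is confined to the
  optimization stages.
* The `(i, i+2)` non-bonded inclusion follows the energy definition
  literally; for compact states these pairs sit near `r ≈ 1` and do
  contribute.
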