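# polyphase

Conformational phase behavior of flexible and semiflexible coarse-grained
polymers: replica-exchange Monte Carlo sampling, multi-histogram estimation
of the density of states, and generalized microcanonical inflection-point
classification of phase transitions up to third order.

## Who this is for

Researchers studying structure formation in finite polymeric systems —
collapse (Θ) and freezing transitions of bead-spring chains, and how bending
stiffness reshapes them. Finite systems have no thermodynamic limit, so
peaks in canonical response functions are ambiguous transition signals; the
microcanonical route classifies transitions directly from the density of
states at any system size.

## Model

A chain of N identical monomers with total energy

```
E(X) = Σ_{i>j+1} V_NB(r_ij)  +  Σ_i V_B(r_i,i+1)  +  Σ_l V_bend(θ_l)
```

* **Non-bonded:** 12–6 Lennard-Jones, `V_LJ(r) = 4ε[(σ/r)¹² − (σ/r)⁶]`,
  truncated at `r_c = 2.5σ` and shifted by `V_shift = V_LJ(r_c)` so it is
  continuous there. `σ = 2^(−1/6) r₀` puts the minimum at the equilibrium
  bond length `r₀`.
* **Bonded:** FENE spring plus the same shifted LJ term,
  `V_B(r) = −½ K R² ln[1 − ((r−r₀)/R)²] + V_LJ(r) − V_shift`, with
  `R = (3/7) r₀` and `K = (98/5) ε/r₀²`; bond lengths are confined to
  `(r₀ − R, r₀ + R)`.
* **Bending:** `V_bend(θ) = κ[1 − cos(θ − θ₀)]` per interior bond angle,
  with `θ = 0` for a straight chain and `θ₀ = 0`. `κ = 0` is the flexible
  chain; `κ = 1, 2` are the semiflexible variants.

Reduced units throughout: `k_B = ε = r₀ = 1`.

## Method

1. **Sampling** (`polyphase.sampler`): replica-exchange Metropolis MC over a
   temperature ladder `T ∈ [0.1, 5.0]`; single-monomer displacement moves in
   a cubic box whose edge is tuned to ≈50% acceptance before measurements,
   pivot rotations of the chain tail, neighbor swaps every 1500 sweeps.
   Canonical energy histograms `h(E; T_k)` are accumulated per thread.
2. **Reweighting** (`polyphase.reweighting`): the histograms are combined
   into one density-of-states estimate by iterating
   `ĝ(E) = Σ_k h(E;T_k) / Σ_k M_k Z_k⁻¹ e^(−E/T_k)`,
   `Z_k = Σ_E ĝ(E) e^(−E/T_k)` to a fixed point (all algebra in the log
   domain). Canonical curves — `⟨E⟩(β)`, `C_V = β²(⟨E²⟩−⟨E⟩²)`, reweighted
   `⟨R²_gyr⟩` and `d⟨R²_gyr⟩/dT` — follow from `ĝ`.
3. **Classification** (`polyphase.microcanonical`): the entropy
   `S(E) = ln ĝ(E)` is smoothed with a high-degree Bernstein–Bézier curve
   (data as control polygon, derivatives from the hodograph) and scanned for
   *least-sensitive inflection points*: a positive minimum of `β = dS/dE`
   marks a first-order transition, a negative-valued peak of `γ = dβ/dE` an
   independent second-order one, a positive minimum of `δ = dγ/dE` an
   independent third-order one, with dependent companions at higher energy.
   Uncertainties are leave-one-out jackknife bands over independent runs; a
   signal counts only if it exceeds its band.
4. **Structure** (`polyphase.structure`): radius of gyration, pair
   distribution `P(r)` at threshold `r_t = 0.01`, contact maps
   (`r_ij < 1.2`, bonded pairs excluded) and hairpin/helix streak counts for
   lowest-energy conformations found by parallel tempering and refined by
   simulated annealing.

## Worked example

A scaled-down study of the flexible 13-mer (three independent
replica-exchange runs, 12 temperature threads — a few minutes on one core):

```python
import polyphase as pp

cfg = pp.StudyConfig(
    kappas=(0.0,), n_monomers=13, n_threads=12, t_min=0.2, t_max=3.0,
    sweeps=40_000, equilibration=4_000, n_runs=3, bin_width=0.25,
    seed=1, anneal_restarts=2,
)
report = pp.run_study(cfg)
res = report.per_kappa[0.0]
print(round(res.e_min, 4))
print(res.results.summary())
```

prints

```
-43.0272
Microcanonical inflection-point analysis
========================================================================
runs: 3    energy window: [-41.875, 29.625]
E_min (shift reference): -43.0272
significance rule: |signal| > 1 SE
------------------------------------------------------------------------
      E_tr        dE   beta_tr  order    character     signal      flags
   -33.206      9.82     2.836      2  independent     -0.107          -
   -31.597     11.43     2.655      3    dependent    -0.0126          -
   -11.219     31.81     0.746      3  independent   0.000378          -
     3.349     46.38     0.104      3  independent    0.00246          -
    20.598     63.63     0.160      3    dependent     -0.014          -
    23.726     66.75     0.292      3    dependent    -0.0781          -
========================================================================
```

Reading the output: `E_min = −43.0272` is the ground-state energy of the
13-mer — an icosahedral cluster (one chain end at the center, twelve shell
monomers; `res.contacts` has the full 30 non-bonded contacts). The dominant
record is the second-order signal at `β_tr ≈ 2.8` where the short chain
collapses and orders in one step; the weak third-order records at high
energy (small `signal` values) are fluctuation-level structure in the
random-coil regime. For N = 55 the collapse and freezing separate, and the
freezing transition of the flexible chain becomes first order.

The same study runs from the shell:

```bash
polyphase report --preset smoke --kappa 0 --seed 1 --out study_out/
polyphase simulate --n 13 --kappa 0 --threads 8 --out hists.h5
polyphase reweight hists.h5 --out dos.csv
polyphase analyze dos.csv --e-min -43.027
polyphase anneal --n 13 --kappa 0 --out ground.xyz
polyphase structure ground.xyz
```

Presets `smoke` (N=13), `desk` (N=30) and `paper` (N=55, production sweep
counts, 48 threads, 10 runs — hours to days on a workstation) scale the
same pipeline.

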