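# Methods

## Model

A single population of `N(t)` diploid individuals reproduces each generation
by self-fertilization with probability `σ(t)` and by outcrossing otherwise.
At equilibrium under partial selfing the inbreeding coefficient is
`F = σ/(2−σ)`, which rescales the neutral machinery in two distinct ways:

- effective population size: `N_σ = N/(1+F)`, hence `θ_σ = 4Nμ/(1+F)`;
- effective recombination rate: `r_σ = r(1−F)`, hence
  `ρ_σ = 4Nr(1−F)/(1+F)`.

Because recombination is reduced by `(1−F)` *on top of* the size reduction,
a change in selfing rate is not equivalent to any change in population size:
it changes the ratio `ρ_σ/θ_σ = r(1−F)/μ` through time. All rate functions
are piecewise constant and right-continuous in time-before-present; a
`TransitionScenario` (one stepwise change in `σ` at `t_σ`, one in `N` at
`t_N`) expands to at most three epochs.

The observable consequence is carried by T_MRCA-segments: maximal runs of
contiguous sites in a sample of size two sharing one common ancestor,
delimited by consequential recombination events. For a pair with coalescence
time `s`, the probability that an effective recombination event occurred is

```
p(rec | s) = 1 − exp(−∫₀ˢ 2 (1−σ_k) (2−σ_k)⁻² r_k dk)
```

implemented in closed form as a sum over epochs
(`recomb_prob_given_tmrca`). Segments older than a transition to selfing
coalesced in the high-recombination outcrossing phase: they are short, and
they cluster spatially along the chromosome.

### A note on hazard conventions

The analytic expression above is kept exactly in the printed form. The
sequential simulator instead uses the physically explicit pair hazard
`h(k) = 2 r(k) (1−F(k))` (two branches, each exposed to the effective
per-generation rate `r(1−F)`), which at `σ = 0` gives the textbook `2 r s`
for a pair with tmrca `s`. The two expressions differ by the factor
`2(2−σ_k)`; the analytic operation and the simulator are therefore
calibrated against *different* oracles (quadrature of the printed integrand,
and the forward Wright-Fisher model, respectively) and are deliberately not
reconciled against each other.

## Simulators

**Sequential pair simulator** (`simulate_pair`). Exact SMC' in real time.
The first tmrca is drawn from the inhomogeneous pairwise coalescent with
rate `λ(t) = (1+F(t))/(2N(t))`; given tmrca `s`, the distance to the next
breakpoint is exponential with per-bp rate `∫₀ˢ h(k) dk`. At a breakpoint
the detachment height `u` is drawn with density ∝ `h(u)` on `[0, s)`, and
the detached lineage re-coalesces at rate `2λ(t)` while both the other
branch and its own stump are available (`t < s`; hitting the stump is a
silent event) and at `λ(t)` with the root above `s`. Silent events do not
emit segment boundaries, so adjacent equal-age pieces are merged and
segments correspond to consequential recombination only. Breakpoints are
continuous, floored to integer bp on emission; zero-length pieces are
dropped. `σ = 1` is supported (zero hazard, one segment).

**Multi-sample simulator** (`simulate_sample`). Uses msprime through the
time change `dτ = (1−F(t)) dt`: in rescaled time the recombination rate is
the constant raw `r`, and the effective size is `Ñ(τ) = N(1−F)/(1+F)`
(entered as ploidy-1 population sizes `2Ñ`). Node times are mapped back
through the inverse piecewise-linear change, after which mutations are laid
down at the constant real-time rate `μ` with a binary mutation model on a
discrete genome; invariant columns are dropped. The time change degenerates
as `F → 1`, so this route refuses `σ > 0.999` and defers to the pair
simulator. The hybrid discrete-time treatment of the first generations used
in some coalescent studies is not reproduced: the statistics computed here
do not involve the long-range identity-by-descent tracts that motivate it,
and the forward oracle provides the fidelity check.

**Forward Wright-Fisher oracle** (`simulate_wf_oracle`). An explicit diploid
forward simulation (offspring selfed with probability `σ`, otherwise
produced by two distinct parents; crossovers Poisson with rate `rL` per
meiosis) recording the full pedigree, gamete phases and crossover positions.
Sampled haplotype pairs are traced backwards through the record; genome
intervals coalesce when both lineages hit the same ancestral haplotype
copy. If parts of the genome have not coalesced by the founder generation
(probability ≈ `exp(−G/2N_σ)` with the enforced burn-in `G ≥ 10N`), the
trace continues with on-the-fly per-generation draws of the same
reproduction mechanism — still the exact discrete-time model, merely not
pre-recorded. Scale guards (`N ≤ 2000`, `L ≤ 100 kb`) keep this usable as a
test oracle only.

## Summary statistics

- **Unfolded SFS**: counts of sites at derived-allele count `1..n−1`, kept
  as raw counts (observed and simulated data share the sequence length by
  construction).
- **LD-decay**: haplotype `r² = D²/(p_A(1−p_A)p_B(1−p_B))` from at most
  10,000 randomly chosen SNPs, binned by physical distance at breakpoints
  6105, 11379, 21209, 39531, 73680, 137328, 255958, 477066, 889175 bp
  (pairs closer than the first breakpoint are excluded); at most 200,000
  pairs are evaluated. Empty bins are encoded as 0 with a parallel 0/1
  missingness flag.
- **TM_win**: pairwise differences summed in non-overlapping windows of
  `ω = 10 kb`, classified against frozen diversity-class edges, and the
  matrix of adjacent-window class transitions recorded (row-major, as
  proportions of all adjacent pairs). Per dataset the matrices of up to 15
  seed-chosen haplotype pairs are averaged. The class edges default to the
  12.5%…87.5% percentiles of pooled window counts from a prior-predictive
  pilot batch; the pilot simulates only a sample of size two per draw, which
  gives the same pairwise window-count law at a fraction of the cost. Edges
  are frozen into the reference table so observed and simulated data are
  always classified identically — a requirement for ABC comparability.
- Multi-locus datasets are summarized per locus and averaged element-wise.

## ABC

Reference tables pair prior draws with summary vectors. Statistics are
centred/scaled per column (zero-variance columns dropped), and a PLS map
(default 20 components) is fitted by regressing parameters — on their
sampling scale, i.e. log10 for log-uniform priors — on the normalized
statistics. Parameter posteriors come from plain rejection: Euclidean
distance on PLS scores, accepting the closest `tolerance` fraction, ties at
the cutoff broken by row order. Model choice pools both tables and rejects
jointly; since per-table PLS maps are fitted against different parameter
sets and span incomparable spaces, model-choice distances use the pooled
mean/sd-normalized statistics without PLS. `P(model 1 | obs)` is the
accepted fraction from model 1 and `BF` its odds; a zero count caps `BF` at
`n_accepted + 1` (flagged). A transition is called when `BF ≥ √10 ≈ 3.16`.

Posterior point estimates follow the averaged-density convention: per
replicate a Gaussian KDE (Scott bandwidth, on the sampling scale) is
evaluated on a fixed grid spanning the prior support, densities are averaged
across replicates and the mode is the grid argmax; the 95% credibility
interval is the 2.5/97.5% quantile range of pooled accepted values.
Degenerate acceptances (all values equal) short-circuit to a point estimate.

Default priors (declared, config-overridable): `N` parameters log-uniform on
[10³, 10⁶]; `t_σ`, `t_N` log-uniform on [10², 10⁶] generations; `σ_ANC`
uniform [0, 0.2]; `σ_PRES` uniform [0.8, 0.999]; model 2's constant `σ`
uniform [0, 0.999]. Default tolerance 1%; default table size 10⁴ per model
for desk runs (the published application used 1.3×10⁵). No regression
adjustment is applied after rejection.

## Test-scale study conditions

The validation experiments in the test suite run at reduced dimensions
chosen once: `n = 8` haplotypes, two 500-kb loci, `μ = r = 10⁻⁸`,
reference tables of 5,000 rows per model (pilot batch 300), tolerance 0.02
(~100 accepted), PLS-20, and priors matched to the scaled-down regime
(`N` log-uniform [5×10³, 5×10⁴]; times log-uniform [10², 10⁵]). Parameter
recovery uses 30 datasets drawn from the prior; model choice uses 25
datasets at each of `t_σ ∈ {5,000; 20,000; 80,000}` with the pseudo-observed
data simulated at `N = 40,000`, `σ: 0.1 → 0.99`. The forward-oracle
concordance check uses `N = 500`, 50-kb sequences and 500 pairs per selfing
rate. The pairwise-diversity calibration uses 100 replicate 1-Mb pairs.

## What the synthetic data does and does not emulate

The generator produces phased, fully polarized, error-free haplotypes under
neutrality, with uniform mutation and recombination rates along the genome
and free recombination between loci. Real data additionally carry phasing
and polarization errors, missing genotypes, accessibility masks, rate
heterogeneity along the genome, background selection and population
structure. Passing tests therefore demonstrate the statistical machinery
under the model's own assumptions; they do not certify robustness to those
violations (the masking and accessibility records in the I/O layer exist to
mitigate, not remove, this gap).

## Numerical choices and edge cases

- Time grids for segment ages use `−8 N_ref ln(1 − i/m)` (natural log),
  default `m = 20`; ages of exactly 0 (possible only in external input) map
  to bin 0; zero-count rows of TM_true are emitted as zero rows and flagged,
  not smoothed — downstream use is descriptive.
- Bin and class assignments are half-open `[lower, upper)` throughout.
- Mutation overlay on pair segments is infinite-sites on integer positions;
  collisions are dropped (bias ≲0.3% at the diversities used here).
- All randomness flows through a single integer seed (`RngState`), with
  child streams derived via `SeedSequence`; identical seeds give
  byte-identical outputs on every simulator route.
- VCF ingestion keeps biallelic SNPs only, converts 1-based positions to
  0-based region-relative coordinates, and splits phased diploids into
  `_A`/`_B` haplotypes; unphased diploids require an explicit flag.

## Known limitations

- No selection, migration, structure or seed dormancy; gradual selfing
  trajectories must be approximated by multiple epochs.
- The multi-sample route cannot represent `σ > 0.999`.
- TM_win class edges and LD pair sampling are declared defaults, not
  published values; inference is conditional on the frozen edges.
- The forward oracle is restricted to toy scales by design.
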