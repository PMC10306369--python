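# selfkit

Tools for detecting and dating evolutionary transitions from outcrossing to
predominant self-fertilization from whole-genome polymorphism data.

## The problem

Most selfing species appear to be of recent origin, but dating the switch
from outcrossing is hard: it usually relies on a single locus controlling
the mating system. A transition leaves a genome-wide signature instead. In a
population of `N` diploids selfing at rate `σ`, the inbreeding coefficient
`F = σ/(2−σ)` rescales the population mutation rate to
`θ_σ = 4Nμ/(1+F)` but the population recombination rate to
`ρ_σ = 4Nr(1−F)/(1+F)`: recombination is suppressed *more* than diversity.
A change of `σ` at time `t_σ` therefore changes the ratio `ρ_σ/θ_σ` through
time, which no population-size history can mimic.

The observable imprint is carried by T_MRCA-segments — stretches of a
chromosome pair sharing one common ancestor, delimited by effective
(consequential) recombination events, whose probability given a coalescence
time `s` is

```
p(rec | s) = 1 − exp(−∫₀ˢ 2 (1−σ_k)(2−σ_k)⁻² r_k dk).
```

Segments that coalesced in the ancestral outcrossing phase are short and
spatially clustered. `selfkit` simulates this model (an exact sequential
SMC' pair simulator, an msprime-based multi-sample simulator via a selfing
time-rescaling, and a forward Wright-Fisher oracle used to validate both),
summarizes data into the unfolded SFS, binned LD-decay and a
window-diversity transition matrix (TM_win: pairwise diversity in 10-kb
windows, classified, with adjacent-window transition proportions), and runs
rejection ABC with PLS-reduced statistics to

1. test whether a transition to selfing occurred, against a competing pure
   population-size-change model, via Bayes factors (detection at
   `BF ≥ √10`), and
2. estimate its age `t_σ` (posterior mode of averaged densities, 95%
   credibility interval).

It is written for population geneticists working on mating-system evolution
in species with phased polymorphism data (the approach was developed for
*Arabidopsis thaliana*-scale data).

## Worked example

Detect and date a transition in simulated data (runs in a few minutes; the
validation experiments in the test suite use larger reference tables):

```python
from selfkit import (RngState, SimDims, PriorSpec, ParamPrior,
                     build_reference_table, fit_pls, abc_reject,
                     model_choice, posterior_summary)
from selfkit.abc import params_to_scenario, simulate_dataset, summarize_dataset

dims = SimDims(n=8, L=500_000, n_loci=2, mu=1e-8, r=1e-8)
prior1 = PriorSpec(1, {                      # transition model
    "N": ParamPrior("loguniform", 5e3, 5e4),
    "sigma_anc": ParamPrior("uniform", 0.0, 0.2),
    "sigma_pres": ParamPrior("uniform", 0.8, 0.999),
    "t_sigma": ParamPrior("loguniform", 1e2, 1e5),
})
prior2 = PriorSpec(2, {                      # size-change model
    "N_pres": ParamPrior("loguniform", 5e3, 5e4),
    "N_anc": ParamPrior("loguniform", 5e3, 5e4),
    "sigma": ParamPrior("uniform", 0.0, 0.999),
    "t_N": ParamPrior("loguniform", 1e2, 1e5),
})

table1 = build_reference_table(1, prior1, dims, 2000, RngState(1), n_pilot=200)
table1 = fit_pls(table1, 20)
table2 = build_reference_table(2, prior2, dims, 2000, RngState(2),
                               class_edges=table1.class_edges)

# pseudo-observed dataset: N=20,000, sigma 0.1 -> 0.99 at t_sigma = 5,000
truth = {"N": 20_000.0, "sigma_anc": 0.1, "sigma_pres": 0.99, "t_sigma": 5_000.0}
alns = simulate_dataset(params_to_scenario(1, truth, dims), dims, RngState(3))
obs = summarize_dataset(alns, dims, table1.class_edges, RngState(4))

mc = model_choice(obs, table1, table2, tolerance=0.025)
print(f"P(transition model) = {mc.p_model1:.2f}, BF = {mc.bayes_factor:.2f}, "
      f"detected = {mc.transition_detected}")
post = abc_reject(obs, table1, tolerance=0.025)
summ = posterior_summary([post], "t_sigma")
print(f"t_sigma: mode = {summ['mode']:.0f} generations, "
      f"95% CI = ({summ['ci95'][0]:.0f}, {summ['ci95'][1]:.0f})")
```

Output:

```
P(transition model) = 0.63, BF = 1.70, detected = False
t_sigma: mode = 5041 generations, 95% CI = (1964, 60288)
```

The age estimate lands on the true 5,000 generations. The Bayes factor
leans toward the transition model but stays below the `√10` detection
threshold at this demonstration scale — model choice needs denser reference
tables than point estimation; with the 5,000-row tables used in the test
suite the same configuration detects recent transitions in the large
majority of datasets.

A `selfkit` command-line interface wraps the same functionality
(`selfkit simulate`, `stats`, `reftable`, `choose-model`, `infer`,
`validate`, `fixtures`; see `selfkit --help`), reading scenarios, dataset
dimensions and priors from a YAML configuration, VCF haplotypes and BED
masks for observed data, and writing reference tables as TSV + JSON
sidecars.

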