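# dolsim

Individual-based evolutionary simulation of **division of labor in
cooperatively breeding vertebrates**.

Cooperative breeders (meerkats, cichlids, many birds) live in groups where a
single dominant breeder monopolizes reproduction and *totipotent* subordinate
helpers — fully capable of breeding later in life — assist by performing
different tasks. `dolsim` models how helping effort, dispersal, and a
dominance-dependent task-choice rule coevolve when helpers can gain fitness
two ways: *indirectly* through kin (kin selection, KS) and *directly* through
the survival advantage of living in a larger group (group augmentation, GA).
It is aimed at evolutionary ecologists who want to re-run, extend, or stress
the model's scenario contrasts.

## The model

A fixed habitat of `N_b` territories holds one asexual haploid breeder each,
plus subordinates and a pool of group-less floaters. Each individual carries
seven loci: α (helping effort), β (dispersal propensity), β₀/β_R (an optional
dispersal reaction norm), γ₀/γ_R (task-choice reaction norm) and a neutral
marker used to estimate relatedness. Phenotypes:

- help `H = max(0, α)`, fixed for life;
- dispersal `D = β`, bounded in [0, 1];
- task choice: a subordinate of dominance `R` defends with probability
  `T = 1 / (1 + exp(γ_R·R − γ₀))`, else works;
- dominance `R = max(0, t − y_h·H_work)` with age `t` — work costs future
  breeding prospects, defense costs immediate survival.

Each breeding cycle: (1) breeders produce Poisson(`K`) offspring, with
`K = k₀ + k_h·S/(1+S)` saturating in the previous cycle's group help `S`; in
the division-of-labor (DoL) condition each task's contribution is truncated
at `H_max = S/2 + k_m`, so productivity requires a balanced task split;
(2) subordinates disperse with probability `D`, and dispersers either settle
in a random group or float; (3) subordinates choose tasks and help;
(4) individuals survive logistically — e.g. helpers with
`S_H = (1−m)/(1 + exp(−x₀ + x_h·H_defense − x_n·N))` — where `m` is the
environmental harshness and `x_n·N` the group-size benefit; (5) vacant
breeding positions go to a lottery over the group's subordinates and a
sampled set of floater bidders, weighted by dominance. Mutation perturbs
each locus with probability μ by Normal(0, σ_μ).

Scenario switches isolate the two benefit routes: `KS_ONLY` removes the
group-size survival benefit (`x_n = 0`); `GA_ONLY` cross-fosters philopatric
newborns between groups, erasing kin structure. Within-group relatedness is
measured as the OLS slope of helper on breeder neutral-marker values.

## Worked example

A group-augmentation-only population in a benign environment (`m = 0.1`),
200 territories, 5000 cycles:

```text
# example.cfg
N_b = 200
n_cycles = 5000
m = 0.1
x_h = 5.0
benefit_mode = GA_ONLY
fecundity_mode = DOL
seed = 42
```

```bash
dolsim run --config example.cfg --out demo --thin 500
```

Tail of `demo/timeseries.tsv`:

```text
 cycle  mean_dispersal  mean_help  group_size_mean  n_floaters  survival_overall  relatedness
  3500        0.084425   0.004876            8.450          36          0.896623     0.014347
  4000        0.062360   0.005656            9.365          29          0.903563    -0.009983
  4500        0.045687   0.007392            9.135          13          0.901519    -0.003680
  5000        0.041787   0.003857            9.545          11          0.892608    -0.063878
```

Even with kin structure erased (relatedness fluctuating around 0), dispersal
collapses toward philopatry (0.04 by cycle 5000), groups grow to ~9.5
members, and realized survival approaches its ceiling `1 − m = 0.9`: the
direct survival benefit of large groups alone selects for staying and
helping. The same command with `benefit_mode = KS_ONLY` gives the opposite
syndrome — dispersal stays above 0.9 and groups stay near size 1.

The scenario grid of the headline experiments (benefit mode × fecundity mode
× harshness × defense cost, replicated) runs through `dolsim grid` /
`dolsim summarize`, which write per-cell `replicate_summary_*.tsv` and an
aggregated `grid_table.tsv`.

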