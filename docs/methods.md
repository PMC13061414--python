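# Methods

`dolsim` simulates the evolution of helping, dispersal, and task
specialization in a cooperatively breeding population with overlapping
generations. This note records the model's assumptions, the numerical and
design choices the implementation makes where the verbal model is open, and
what the scaled-down runs used in testing can and cannot show.

## Model summary and assumptions

A habitat of `N_b` territories each holds at most one breeder. Reproduction
is asexual and haploid with complete reproductive skew; subordinates never
reproduce directly, but every individual can become a breeder. There is no
explicit space beyond group membership, no sex, no enforcement of help, no
body-condition carry-over between cycles: the only persistent individual
state is the genome, age, role, and group membership.

Seven loci evolve: helping effort α, dispersal β, a dispersal reaction norm
(β₀, β_R; off by default), the task reaction norm (γ₀, γ_R), and a neutral
marker. All loci are unbounded reals whose phenotypes are clamped at
expression, with one exception: β lives directly on the probability scale
and is truncated to [0, 1] at inheritance. This matters: because selection
in several scenarios pushes dispersal against its upper bound, an unbounded
β drifts neutrally above 1 and pins the phenotype at exactly 1, which
extinguishes philopatry (and with it every helper-dependent statistic).
With a bounded gene, the stationary state under boundary selection is a
mutation–selection layer just below 1, giving the dispersal means in the
0.88–0.97 range the model is known for.

The breeding cycle applies, in order: reproduction (Poisson fecundity from
the previous cycle's help), dispersal, task choice and help accumulation,
survival, and a dominance-weighted lottery for vacant breeding positions;
survivors then age by one cycle. Newborns enter at age 1, decide dispersal
in their birth cycle, and face the survival step like everyone else.

Dispersal is one decision with two stages: a subordinate leaves with
probability D; a leaver then either settles in a uniformly random territory
(probability 1 − D) or becomes a floater. Floaters wait: they re-enter
groups only by winning a breeding vacancy. Alternatives in which standing
floaters re-try settlement every cycle make the helper pool mostly recycled
old floaters, which suppresses within-group relatedness and pushes the
helper/floater dominance ratio to ~1; the one-shot rule instead makes
helpers predominantly young natal kin, matching the model's characteristic
relatedness and rank-ratio signatures.

## Parameters

| symbol | meaning | default |
|---|---|---|
| y_h | dominance cost of work tasks | 0.1 |
| x_h | survival cost of defense | 5 (studied at 3/5/7) |
| x_n | survival benefit of group size | 3 (0 in KS-only) |
| x_0 | survival intercept | 1.5 |
| m | baseline mortality (harshness) | 0.2 (studied at 0.1–0.3) |
| f | groups a floater samples per vacancy round | 2 |
| k_m | slack from an even task split | 0.1 |
| k_h | fecundity gain of help | 1 |
| k_0 | baseline fecundity | 1 |
| μ | per-locus mutation rate | 0.05 |
| σ_μ | mutation step SD | 0.04 |
| N_b | territories | 5000 |
| n_cycles | run length | 200 000 |

Initial alleles are the ancestral state (α = 0, β = 1, β₀ = 1, β_R = 0,
γ₀ = 0, γ_R = 0); the neutral locus is drawn i.i.d. standard normal so the
relatedness regression has breeder-side variance from the start. The
founding population is one age-1 breeder per territory with no helpers or
floaters; the first cycles are a demographic transient that every summary
window excludes.

## Numerical and procedural choices

- **Draw-order contract.** All randomness flows through one generator in a
  documented per-phase order (see `dolsim/lifecycle.py`). The vectorized
  engine and the scalar per-individual reference engine consume the stream
  identically, so a seed fixes the run bit-for-bit in both — the strongest
  regression test the package has.
- **Fractional bidder counts.** The expected number of floaters bidding for
  a vacancy, `f·N_f/N_b`, is generally fractional; per-vacancy counts are
  Poisson with that mean, truncated (in territory order) when the pool runs
  out, and each floater bids at most once per cycle.
- **Weighted lottery.** Winner selection is Gumbel-max over log dominance
  weights — equivalent to sampling proportional to R, but expressible as
  one draw per candidate in a fixed order. If every candidate has R = 0 the
  lottery is uniform. Vacancies with no candidates stay vacant and are
  re-contested every cycle.
- **Task-draw dominance.** The task choice at the start of a cycle uses
  dominance before that cycle's work cost (R = age); the work cost applies
  to the same cycle's vacancy competition and is then forgotten (costs are
  not cumulative).
- **Group size in survival** counts breeder plus subordinates at the
  survival step, the same value for every member; floaters count nowhere.
- **Equilibrium summaries** average the final 10 % of recorded cycles.
  Relatedness over a window is additionally computed by pooling each
  recorded cycle's centered sums of squares and cross-products
  (`relatedness_pooled`): at reduced scale some cycles have only tens of
  breeder–helper pairs, and single-cycle regression slopes are then far too
  noisy to average meaningfully.
- **Equilibrium detection** (OLS slope and window-mean drift below a
  tolerance) is available but off by default; default runs use the fixed
  horizon.
- **Seeds.** Replicate seeds derive from `SeedSequence([master, cell,
  replicate])`, so grids are reproducible and parallelizable by cell.

## What the scaled-down runs show

Test-suite and acceptance runs use 500–1000 territories and 10k–100k cycles
instead of 5000 × 200k. The scenario contrasts that rest on strong selection
reproduce robustly at this scale: group-augmentation-only populations
evolve philopatry (dispersal → 0.01–0.05 in benign environments), large
groups (~9–10 members), survival near its ceiling, and relatedness
indistinguishable from zero under cross-fostering; kin-selection-only
populations keep dispersal above 0.9, groups near size 1, and substantial
positive relatedness (~0.4); with both benefit routes in harsh environments,
helping evolves together with γ_R > 0 — the defense-at-low-rank,
work-near-the-top polyethism signature.

Two harsh-environment kin-selection statistics do not reproduce reliably at
this scale. The joint onset of reduced dispersal and helping under KS-only
at m = 0.3 is a stochastic transition: replicates that undergo it settle at
dispersal ≈ 0.90 (the full model's value), but the waiting time is long and
variable at one-fifth population size, so some desk-scale replicates remain
in the pre-transition state (dispersal ≈ 0.97) for 100k cycles. Relatedly,
the rise of within-group relatedness with harshness is weak before that
transition; desk-scale KS runs show relatedness ≈ 0.4 in both benign and
harsh environments rather than a clear gradient. Conclusions about these
two quantities should be drawn from full-scale runs.

The synthetic world also idealizes real cooperative breeders in ways no
test can absolve: asexual haploid inheritance makes helper–breeder
relatedness clonal rather than sexual-family-structured, there is no
environmental stochasticity beyond demographic noise, and help amount
cannot respond plastically to group composition. Passing tests certify the
model's internal logic, not those biological simplifications.

## Known limitations

- The per-individual reference engine runs scalar Python loops and is
  orders of magnitude slower than the vectorized engine; it exists for
  correctness checks on toy populations, not production.
- Extinction is possible (and signalled with its cycle) for harsh
  configurations with small habitats; grid runs record rather than abort.
- The dispersal reaction-norm variant (β₀, β_R) shares the logistic form of
  the task norm for symmetry; the verbal model leaves its shape open.
- Relatedness is reported as missing when fewer than two breeder–helper
  pairs exist or the breeder-side variance is zero.
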