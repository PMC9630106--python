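# Methods

`stemtrace` implements a chain of inferences used to study deep genome
evolution on a dated species tree: probabilistic gene-tree/species-tree
reconciliation under a duplication–transfer–loss (DTL) model, likelihood-based
root evaluation with an approximately unbiased (AU) test, ancestral
gene-content reconstruction, ordination of gene-content disparity, and
Bayesian relaxed-clock dating with soft fossil calibrations and
transfer-derived relative node-order constraints. This note records the
models, the numerical choices, and the judgement calls made where the design
was genuinely open.

## The dated DTL model

A gene family evolves down a rooted ultrametric species tree with node ages
in Ma. Each gene lineage, independently, undergoes

* duplication at rate δ (per lineage per Myr): two lineages continue on the
  same species branch;
* horizontal transfer at rate τ: a copy moves to a recipient branch drawn
  uniformly among the species branches alive at the event time, excluding the
  donor (the donor keeps its copy);
* loss at rate λ: the lineage ends.

At speciations a lineage enters both daughter branches. Because transfer
recipients are restricted to contemporaneous branches, every reconciliation
is time-consistent: no gene can be transferred into the past.

A family originates once. The default origination policy places the origin on
a branch with probability proportional to branch duration, at a uniform time
on the branch (density 1/T over the tree's total branch length T); a
root-origin policy (one ancestral copy entering both root children) is also
available. The likelihood conditions, by default, on the family being
observed in at least one sampled genome, since gene-family clusters are
built from observed genes; the unconditioned likelihood is available for
closed-form checks.

### Likelihood computation

The species tree is discretized into time slices whose boundaries include
every node age (default 3 slices per inter-node interval). Two quantities are
propagated from the tips (age 0) rootward per slice step of height `h`:

* `E[e]`, the probability that a lineage on branch `e` leaves no sampled
  descendants, with update
  `E ← E + h(λ − (δ+τ+λ)E + δE² + τ·E·Ē)` where `Ē` is the mean extinction
  probability over the other live branches, and `E(parent) = E(left)E(right)`
  at speciations;
* `P[γ, e]`, the probability that a lineage on `e` realizes exactly the
  observed clade γ of the gene tree. Within a step, γ can pass unchanged
  (factor `1 − h(δ+τ+λ)` plus the "ghost" terms `2δhE·P`,
  `τh(Ē·P + E·M)` with `M` the mean of `P` over other branches, in which an
  event creates a copy that goes extinct), split by a duplication
  (`δh·Σ_splits q·P(γ₁)P(γ₂)`), or split by a transfer
  (`τh·Σ_splits q·(P(γ₁,e)M(γ₂) + P(γ₂,e)M(γ₁))`). At speciations the clade
  resolves into the two children in either orientation, or passes whole into
  one child while the other side's lineage dies.

When the evidence is a sample of gene trees (e.g. bootstrap replicates), the
split weights `q` are conditional clade probabilities (CCPs) estimated from
the sample, so the likelihood is amalgamated over gene-tree topologies;
a single tree degenerates to indicator CCPs. CCPs are estimated from the
trees as rooted; unrooted amalgamation over all rootings of the input trees
is not implemented.

The scheme is first-order in `h`: the log-likelihood converges linearly as
the grid refines, which the tests exploit (deltas between successive grid
doublings must shrink). Steps where `h(δ+τ+λ)` would exceed 0.1 are
subdivided internally so transition probabilities stay positive. Partial
likelihoods are rescaled when they underflow, with the log scale factor
carried separately; on small instances the float64 result agrees with an
extended-precision (float128) rerun to better than 1e-10 relative.

The per-family implementation was validated against an independent
brute-force enumeration of reconciliations (explicit embeddings of the gene
tree into the sliced species tree, with explicit loss events in extinct
sub-lineages, up to a small event budget) on 3-tip instances, and against
Monte-Carlo frequencies from the forward simulator.

### Rate estimation and event sampling

ML rates maximize the summed family log-likelihood over (δ, τ, λ) by
Nelder–Mead in log-rate space, either pooled across families or per family.
The fit never returns a point worse than its initialization.

Reconciliations are drawn by stochastic backtracking of the stored dynamic
program: at each step the realized term (no event, duplication, transfer,
speciation resolution, or a ghost event) is sampled proportionally to its
contribution, and extinct sub-lineages are unfolded into explicit loss
events. Copy numbers at nodes count all lineages, including those destined
for extinction, so in every sampled reconciliation

    copies(child) = copies(parent) + duplications + incoming transfers
                    + originations − losses     (per branch, exactly).

Expected per-branch counts are means over samples. Transfers are tallied as
gains on the recipient branch; donations are reported separately so the
bookkeeping balances.

Families given only as tip copy numbers use a profile likelihood: a linear
birth–death process on the copy count along each branch (matrix exponentials
on a truncated count space, default 10 copies), with the same origination and
ascertainment treatment. Transfers are not modelled in profile mode.

## Rooting

Candidate roots are branches of the unrooted species tree; each induces a
rooted topology. Candidate ids are the smaller side of the branch's tip
bipartition, which is stable across serialization. Alternative rootings are
scaled to time by inheriting the ages of clades shared with a reference
dated tree; clades that exist only under the alternative root get midpoint
ages between their nearest dated ancestor and their oldest dated descendant.
This interpolation is an explicit choice: how such clades should be dated is
underdetermined, and any smooth completion that respects the order
constraints would serve.

The root scan reconciles every family under every dated candidate (shared,
per-candidate, or per-family rates) and compares summed log-likelihoods.
Families that fail under any candidate are dropped from all candidates so the
comparison stays paired.

The AU test resamples per-family log-likelihood rows (RELL) at relative
sample sizes 0.5–1.4 (step 0.1, 1000 replicates per scale by default),
records per-scale bootstrap proportions of each candidate being best, fits
signed distance `d` and curvature `c` by probit-weighted least squares over
scales, and reports `p_AU = 1 − Φ(d − c)`. Proportions of exactly 0 or 1 are
continuity-corrected to half a count. Candidates exactly tied at the maximum
share the win fractionally; a deterministic lowest-id tie-break was
considered and rejected because it makes duplicated candidates asymmetric
(the first twin would absorb every tied win), breaking the symmetry that
identical columns must receive identical p-values. Calibration was verified
under an exchangeable permutation null: the rejection rate of a designated
candidate at α = 0.05 stays inside the 99% binomial envelope.

The high-DTL filtering scan ranks families by their total fitted DTL rate,
removes the top fraction, and re-ranks the candidates from the remaining
likelihood rows — a robustness check that poorly modelled families are not
driving the root signal.

## Gene content and disparity

Branchwise tables sum expected events and copy numbers over families; rates
per Myr divide by branch duration; branches whose expected copy number drops
below the parent's are flagged as reduced. Presence at a node is called when
the expected copy number reaches a threshold (default 0.5 copies — the
natural rounding point of an expected count; the choice is exposed). Tip
columns can be overridden with observed counts. Shared-family counts between
nodes are simple intersections of presence profiles.

Disparity uses Euclidean distances between presence/absence profiles
(distance √k for profiles differing in k families), embedded by non-metric
MDS: SMACOF with isotonic regression minimizing Kruskal stress-1, best of 20
starts (default). Starts are initialized from the classical (Torgerson) MDS
solution plus Gaussian jitter; fully random starts converge to poor local
optima often enough to fail even a unit square. Tips and ancestral nodes are
ordinated jointly. Layouts add parent–child segments and per-clade convex
hulls; clades with fewer than three distinct points degenerate with a
warning.

## Dating

Node ages on a fixed rooted topology are sampled from the posterior
proportional to

    MVN branch-length likelihood × calibration priors × node-age kernel
    × lognormal rate prior × hyperpriors × relative-constraint indicator.

The phylogenetic likelihood is approximated by a multivariate normal over
branch lengths, with mean and covariance estimated from a posterior sample
of branch lengths (substitutions/site); the covariance is ridged minimally
to positive definiteness when the sample is small. A branch's implied length
is rate × duration. Branch rates are iid lognormal with mean μ and log-sd σ.
Two hyperprior profiles are provided: exponential(mean 1) on μ and σ (the
default), and gamma hyperpriors (shape 2/scale 10 on μ, shape 1/scale 10 on
σ). The gamma parameterization is taken as shape/scale as printed, but a
shape/rate spelling is accepted in configuration, since the two conventions
are easy to conflate and a scale of 10 implies implausibly fast mean rates
for substitution data; the ambiguity is surfaced rather than resolved.

The node-age prior is a uniform kernel conditional on the root age (density
`root_age^−(n−2)` on the order-constrained simplex), the birth = death = 1
special case; a conditional birth–death kernel is available behind a flag.
The root age must be calibrated, fixed, or given an explicit prior.

Calibrations are soft-bounded uniforms: mass 1 − 2p on [min, max] (p = 0.01
per side by default), an exponential upper tail and a power-function lower
tail, both continuous with the plateau and integrating to exactly p (when
the plateau is too low for a decreasing power tail to carry mass p, a
uniform lower tail is used instead). Minimum-only calibrations place an
exponential body (scale = min) above the minimum. The realized tail
probabilities are audited by prior-only MCMC. The tail shapes are a design
choice; only the tail masses are fixed by the soft-bound convention.

Relative node-order constraints (MRCA(older) strictly predates
MRCA(younger)) are hard: proposals violating them are rejected, and the
constraint digraph is checked for cycles before sampling. An HGT justifies
such a constraint because the donor lineage must exist before the recipient
clade diversifies; alternative recipient placements are expressed as
alternative constraint rows.

Sampling is random-walk Metropolis with proposals executed in random order
each iteration: per-node age slides (reflected within the parent/children
bracket), a root-age multiplier, per-branch rate multipliers, and
hyperparameter multipliers. Age and root moves rescale the rates of the
adjacent branches so branch lengths are preserved (with the corresponding
Jacobian); without this compensation the sampler must crawl along the
age–rate ridge induced by a tight length likelihood and effective sample
sizes collapse. Metropolis coupling runs chains
at inverse temperatures 1/(1 + 0.1k) with one adjacent-pair swap per
iteration; a single chain is plain Metropolis–Hastings. Burn-in defaults to
25% of iterations; only cold-chain samples are returned, and every retained
sample satisfies the topology order and all hard constraints by
construction.

Posterior-as-prior combination fits per-node gamma densities (by moments) to
marginal age posteriors; the fitted priors can be supplied to a second run,
which reproduces the first stage's marginals when no other information is
added. Diagnostics report autocorrelation-based ESS (via ArviZ) with a
configurable floor (default 200) and rank-normalized R-hat across
independent runs.

## Synthetic data

The simulator provides every input with known ground truth:

* **Species trees** — forward birth–death simulation from one lineage,
  stopped when the standing count first reaches the requested tip number,
  with the present placed an exponential waiting time later (so the youngest
  divergence has positive age); extinct replicates are redrawn. This
  conditions on the tip count by stopping, which is simpler than GSA
  sampling and adequate for fixtures; early lineage growth matches the
  unconditioned Yule expectation, which the tests check.
* **Gene families** — exact Gillespie simulation of the DTL process down the
  dated tree, with the complete event ledger, tip copy numbers, and the true
  gene tree (leaves labelled `species_index`). Replaying a ledger reproduces
  the tip counts exactly, and every transfer connects branches that overlap
  at the event time. Per-family random streams derive from
  (seed, family index), so generation is order-independent.
* **Branch-length pseudo-posteriors** — iid lognormal branch rates (the
  dating model's assumption) times branch durations, with mean-one lognormal
  sampling noise per posterior draw.

Default study conditions used by the acceptance checks: 500 families at
(δ, τ, λ) = (0.002, 0.001, 0.004)/Myr on 10-tip trees for rate and
gene-content recovery; 20 replicates of 200 families on 16-tip trees for
root recovery; 10-tip trees with 200 length-posterior draws (rate spread
σ = 0.3, noise 5%), three ±15% calibrations and one relative constraint for
dating recovery. Birth rate 0.02/Myr puts root ages near 100 Ma, a
Phanerozoic-like depth. What the simulator does not emulate: gene-tree
estimation error (true gene trees stand in for bootstrap samples, so CCP
amalgamation is exercised but not stressed), rate heterogeneity across
branches of the species tree, incomplete lineage sorting, gene conversion,
and genome-sampling artifacts. Passing recovery tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to model violation on real data.

## Problem sizes in the test suite

The acceptance checks run the study conditions above; the heaviest are root
recovery (20 replicates × ~29 candidates × ~180 families, 2 slices per
interval) and dating recovery (20 chains of 10,000 iterations). Unit tests
use 5–10-tip trees and tens of families. The slice resolution used in each
check is stated with the check; resolution is a numerical knob whose
convergence is itself under test, not a fitted quantity.

## Known limitations

* The DTL discretization is first-order; likelihood values carry a
  resolution-dependent bias (small relative to rate-recovery tolerances at
  3 slices per interval, and vanishing under refinement).
* Transfers are uniform over contemporaneous recipients; no distance- or
  rate-modulated transfer preference.
* Per-branch-homogeneous DTL rates; no family-specific origination weights.
* CCPs are taken from rooted tree samples; gene-tree uncertainty enters only
  through the sample supplied.
* The dating model shares the MVN approximation's limits: it is blind to
  non-Gaussian features of the branch-length posterior.
* The profile (copy-number-only) likelihood ignores transfers.
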