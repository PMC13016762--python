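# Methods

`asekit` estimates ancestral states of a single discrete character on fossil
time trees and evaluates the models used to do so. This note records the
models, the numerical choices, and the design decisions taken where more than
one defensible convention exists.

## Time-scaling fossil trees

Fossil phylogenies supply topology and tip ages (first/last appearance data,
FAD/LAD in Ma) but no branch durations. Tips are dated at their FAD — the
oldest plausible age, the convention of the standard a-posteriori scaling
tools — and every internal node starts at the age of its oldest descendant
tip, which necessarily creates zero-length branches along each oldest-tip
path. Two scalers repair them:

**equal.** If the root subtends a zero-length branch it is pushed back by
`root_length` (default 1 myr), consuming the stem; otherwise the stem of
`root_length` is kept above the root. Each remaining zero-length branch then
takes an equal share of the nearest preceding (ancestral) branch of positive
length: a donor of length *L* followed on the path by *k* zero-length
branches is divided into *k*+1 equal pieces. Two visit-order dialects are
provided, because historical implementations of the equal method differ in
exactly this way and produce distinct dated trees of identical topology:
`basal_first` resolves zero-length branches breadth-first from the root;
`legacy` resolves them in cladewise (depth-first input) order. Both
guarantee strictly positive branch lengths; neither is a reconstruction of
any particular historical implementation's internals.

**mbl.** Bottom-up, each parent is pushed back until every branch spans at
least `min_length` (default 1 myr). If the input topology already carries
branch lengths consistent with a dating that satisfies the minimum, those
node ages are kept (which makes the operation idempotent).

Both operations are idempotent on their own outputs and preserve the
identity *root age = root-to-tip path + tip age* for every tip. Trees are
not ultrametric: fossil tips end at their own ages.

## Model families

A model is a *rate template*: an integer matrix over model states where 0
forbids a transition and equal positive indices share a rate parameter.
Schemes: ER (one rate per sharing group), SYM (forward = backward), ARD
(all directions free).

* **Mk, unordered/ordered** — all transitions allowed, or only
  chain-adjacent states in the listed order. The 6-state feather coding is
  ordered scales — monofilament — basally joined — central filament —
  pennaceous — asymmetrical pennaceous, the developmental-complexity
  gradient. State-skipping in the ordered model is not allowed.
* **Embedded dependency (ED)** — a chain of nested binary characters
  (presence of feathers, then of each successive structural elaboration)
  amalgamated into one character over the observable complexity levels,
  with no hidden states. Each allowed transition corresponds to one
  underlying character event and inherits that event's parameter: gaining
  character *j*+1 drives upward moves out of level *j*; losing character
  *j'*+1 drives any move down to level *j'*. The **QL** variant lets a trait
  be born together with any of its dependent qualitative properties
  (upward jumps of any size); the **BD** variant forbids every transition
  implying two or more simultaneous trait "births" (upward jumps beyond one
  level), while losses stay unrestricted — losing the controlling trait
  makes the dependent ones inapplicable, which is one event, not several.
  The exact rate-sharing of the original amalgamation machinery is not
  published; this parameterization is the package's documented choice and
  the template is exposed for inspection. ED is implemented for chain
  hierarchies, the only form the feather codings use.
* **Structured Markov models (SMM)** — the full Cartesian product of the
  binary characters (2^m states; for the 6-state coding, 32 model states
  collapsing onto 6 observed states). Unobserved combinations are retained
  as hidden "liability" states: feather absence is represented by every
  vector whose controlling bit is 0, so e.g. the 4-state coding-2 space is
  {00, 01, 10, 11} with both 0x states observed as "scales". Only one
  character may change at a time. **ind** amalgamates the characters as
  independently evolving (a character's rates ignore the rest); **switch**
  gives a dependent character distinct rate parameters under each state of
  its controller. Schemes apply per component character, so for binary
  components ER and SYM produce the same template (they remain separate
  grid entries); ARD frees gain from loss. Which rates "switch" in the
  original implementation is unpublished; the choice here — the dependent
  character's own toggle rates switch on the controlling state — is
  documented and inspectable.
* **Hidden rates models (HRM)** — observed states duplicated across 2 or 3
  latent rate categories ("slow"/"fast" or slow/medium/fast). Within each
  category the base (unordered) support is re-indexed with
  category-specific parameters; category switches preserve the observed
  state and connect adjacent categories only (slow ↔ medium ↔ fast), with
  one switch parameter per adjacent pair under ER/SYM and per direction
  under ARD. The chain topology is pinned down by the overparameterized
  benchmark case: ARD HRM(3) on 6 observed states has 3×30 + 4 = 94 free
  parameters, equal to the tip count of the empirical tree it is known to
  saturate.

The full model grid on the 6-state coding is {unordered, ordered, ED,
SMM-ind, SMM-switch, HRM-2, HRM-3} × {ER, SYM, ARD} = 21 models; crossed
with three time-scaled trees it yields 63 tree/model combinations. The grid
uses ED-QL by default (`ed_variant` switches to BD).

## Likelihood and marginal estimation

Felsenstein pruning with per-branch transition matrices exp(Q·t). All
branch exponentials of one evaluation come from a single eigendecomposition
of Q (complex arithmetic, real part taken) when the eigenbasis is well
conditioned (‖V‖·‖V⁻¹‖ < 1e8), otherwise from per-branch
scaling-and-squaring; rows are clipped to [0, ∞) and renormalized. Partial
likelihood vectors are rescaled at every internal node with accumulated log
factors, keeping 32-state models stable across branch lengths of 0.1–100
myr.

Ambiguous tip codings (`a&b`) place 1 at every compatible observed state;
`?` is all ones; observed values are copied to all hidden preimages of the
observation map. Root priors: `flat` over model states (default),
`stationary` (left null vector of Q), or `fitzjohn` (normalized root
partials). The original study's toolchains default differently on this
point and do not state it; the choice is therefore explicit and
configurable, and is the main obstacle to digit-exact reproduction of
published tables.

Rates are fitted by bounded multi-start maximum likelihood on the log scale
(bounds 1e−9 to 100 events/myr, L-BFGS-B, default 10 starts: one heuristic
start at about one expected change per tree depth plus seeded log-uniform
draws). Fits are deterministic given the seed. AIC = −2 lnL + 2k;
AICc = AIC + 2k(k+1)/(n−k−1) with n = number of tips, flagged undefined
when n − k − 1 ≤ 0 (the ARD HRM(3) situation on ~94 tips).

Marginal ancestral estimates use the standard two-pass scheme (partials
from below times "outside" evidence from above, root prior included);
hidden states are collapsed onto observed states by summation. Tips with
(partially) known codes keep their own evidence by default
(`clamp_known_tips=True`, so a fully known tip is a point mass and an
ambiguous tip a posterior over its set); cross-validation re-estimates the
held-out tip from the rest of the tree alone. Ties in "highest marginal
state" are broken by state order, which affects only uncertainty
bookkeeping.

## Evaluation layer

* **Raw uncertainty** = 100·(1 − mean over internal nodes of the highest
  marginal probability); 0 when every node is certain; internal nodes only,
  since tip marginals are mostly clamped observations, and each internal
  node counts once. **Proportion of maximum** divides by 100·(1 − 1/k).
* **Mutual information** per node = log2 k − H(marginal) in bits, the
  reduction in uncertainty about the node contributed by tips and model;
  the unconditional entropy is fixed at log2 k (the model-set upper limit,
  identical for every node); totals are sums over internal nodes, with
  0·log2 0 := 0.
* **LOOCV**: per tip — drop the tip, refit the rates on the pruned tree
  (first optimizer start = full-data MLE, plus restarts), restore the tip
  as unknown, estimate its marginal under the saved rates, and score
  error = 1 − Σ predicted probability over the true state set (for an
  ambiguously coded tip, the sum over its set — consistent with "summed
  probability of the incorrect states"). The per-tip predictive
  log-likelihood is recorded alongside. Failed folds are flagged and
  excluded from the mean with a warning. The ingroup variant drops and
  scores only ingroup taxa, making trees with different outgroups
  comparable.
* **Weights**: Akaike weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_κ/2) on ΔAIC;
  LOOCV error weights w_i = (1−e_i)/Σ(1−e_j). Model averaging multiplies
  each combination's marginal table by its weight and sums; the
  **generalizability rule** keeps combinations with mean error within a
  fraction (default 10%) of the lowest mean error.

## Synthetic data

The generator emulates the empirical study conditions: a ~94-tip
birth–death fossil tree (birth 0.06, death 0.04 /myr, starting 160 Ma,
extinct lineages becoming fossil tips), FAD/LAD ranges drawn uniformly
within 5 myr of the true tip age (so time-scaling, zero-length branches
included, is exercised), and a 6-state ordered character evolved forward at
0.02 events/myr from the "scales" root state, which makes developmentally
complex states phylogenetically clustered. Ambiguity (`a&b` neighbour
sets, 5% of tips) and unknown codes are injected at configurable
fractions; the basal-most tips play the outgroup. All randomness flows from
one recorded seed; generators never touch global random state. What the
generator does **not** emulate: correlated characters, state-dependent
diversification, non-uniform fossil sampling, and topological error — so
passing recovery tests says nothing about robustness to those.

Recoding collapses the 6-state coding to 3 states (filamentous morphotypes
merged; pennaceous morphotypes merged) or to binary presence/absence,
memberwise over ambiguity sets.

## Problem sizes used by the shipped checks

The acceptance script and test suite size their simulations to run on one
CPU in minutes: rate recovery uses 200-tip trees over 20 seeds (the
1-parameter ER fit is cheap); the 21-model AICc ranking check uses 80-tip
trees over 10 seeds with a single optimizer start and 35 iterations (model
ranks, not converged rate values, are consumed); the LOOCV
model-comparison check uses 40-tip trees over 20 seeds; the orchestration
check runs the full 21-model grid with restricted cross-validation scope on
the 12-tip fixture. The full empirical-scale LOOCV grid (63 combinations ×
~90 folds) is a few thousand refits and runs in hours, not days; the
pipeline's `loocv_scope`/`loocv_max_folds` options exist precisely to
subsample it.

## Known limitations

* One character at a time; no polymorphic-state models (a tip preserving
  several morphotypes is coded by its most complex one).
* No joint (max-posterior) reconstruction, stochastic mapping, or Bayesian
  rate inference; no cal3/tip-dating time-scaling.
* ED amalgamation covers chain hierarchies only.
* The ED and SMM-switch rate-sharing conventions, the HRM switch topology
  and the root prior are documented package choices where the literature
  is silent; alternative conventions will move third-decimal results.
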