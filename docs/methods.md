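# Methods

## Model and state space

A basic sequence state is an ordered array of pairwise-distinct ancestry
tokens.  Tokens are opaque labels: any bijective relabelling yields the
same homology structure, and all alignment equality in the package goes
through a canonical form (tokens renumbered by first appearance, with a
fixed canonical column order — deletions before insertions within a zone
for pairwise alignments, a deterministic topological merge of the rows for
MSAs).  Fresh tokens for insertions are drawn from a global monotone
integer counter; the token values never enter any probability.

Indel events are operators: `Ins(x, l)` inserts `l` sites after position
`x` (1-based; `x = 0` is the left end), `Del(xB, xE)` deletes positions
`max(1, xB)..min(L, xE)`.  Raw deletion ranges may stick out of the
sequence (the sequence is viewed as embedded in an effectively infinite
chromosome); inside histories they are normalized to the clipped effective
operator whose rate aggregates all raw channels with the same action.
This aggregation is exact: operators with identical action induce
identical downstream evolution, so summing their rates changes no
probability.

A rate model supplies r_I(x, l; s, t) and raw r_D(xB, xE; s, t) with hard
cut-off lengths L_I^CO and L_D^CO; the exit rate R_X(s, t) is the sum over
all channels with nonempty action.  Raw ranges entirely outside the
sequence are no-ops and are excluded from both the channel list and the
exit rate, which preserves the conservation Σ channel rates = R_X exactly.
One consequence worth noting: for the space-homogeneous family the exit
rate is the affine A(t)·L + B(t) for every L ≥ 1, while the empty sequence
(L = 0) keeps only its left-end/whole-sequence insertion channel and sits
below the affine line.

### Time dependence

Built-in models expose a single global time profile c(t) (constant,
piecewise-constant, or callable) multiplying every rate.  Because the
modulation is shared, the substitution u = ∫ c(τ) dτ maps every
probability to the constant-rate case, so closed forms remain exact for
all profile kinds (callable profiles integrate c by quadrature).  Rates
with genuinely independent per-channel time dependence are out of scope;
they would require the quadrature/Monte-Carlo routes throughout.

## History probabilities

The probability of an ordered N-event history is the product of the event
rates (each evaluated on the state immediately before the event) times the
simplex integral of the exponentials of the interval exit rates.  With
constant rates the integral is the hypoexponential form, evaluated as
(−1)^N times the divided difference of f(r) = e^{−r·u} over the exit-rate
tuple {R_0, …, R_N}.  Numerical policy:

- the divided-difference table is built in mpmath extended precision
  (working precision 25 + 5N digits, at least 40), which absorbs the
  catastrophic cancellation between close-but-distinct nodes;
- nodes closer than 1e-9·max(1, |R|) are treated as coincident and use the
  exact confluent (Hermite) values f^(m)(R)/m! = (−u)^m e^{−R·u}/m!;
- two independent routes exist for cross-checking: nested adaptive
  quadrature (N ≤ 4) and a uniform-order-statistics Monte-Carlo estimator
  with reported standard error.  The closed form and quadrature agree to
  better than 1e-8 relative over randomized tuples including spacings of
  1e-6 (tested).

## Local history sets and class enumeration

Given a global history, its events are sorted into the zones between the
preserved ancestral sites (PASs) of the history's *own* resulting
alignment; the per-zone event subsequences, re-expressed in isolated
coordinates on the initial state, form the local history set (LHS).  The
equivalence class of a LHS contains all order-preserving interleavings of
its local histories — the multinomial N!/Π_k N_k! of them.  (Enumeration
of the interleavings confirms the factorial in the denominator.)

Interleavings are rebuilt by identity-tracked replay rather than chained
coordinate-shift algebra: each local event's footprint is recorded as site
tokens (deleted tokens, or the insertion anchor token plus the pre-assigned
inserted tokens), and positions are re-resolved against the current state
at each step.  This avoids compounded shift arithmetic entirely; the
binary swap relations are retained as an independent oracle and verified
by replay on a thousand randomized admissible pairs.

## Alignment probabilities

The pairwise alignment probability is the truncated sum of history
probabilities over all alignment-consistent histories, grouped by LHS
class (the two summation orders are computed and compared).  Local
histories per zone are enumerated by depth-first search over effective
operators confined strictly between the zone's delimiters, with an
admissible lower bound on the events still needed (remaining originals and
the insertion deficit divided by the cutoffs) pruning the search;
non-parsimonious histories, including invisible insert-then-delete round
trips in gapless zones, appear whenever the budget allows.  Budgets are
per-zone: the zone's parsimony minimum plus an `extra_events` allowance
(default 2 for standalone factorized calls, matched explicitly in all
identity tests).  Matched per-zone budgets on both routes make
direct = factorized an exact identity for condition-satisfying models —
this is the package's central internal check, verified to 1e-8 relative on
fixed and simulated alignments.

The truncation diagnostic bounds the residual mass by a Poisson tail with
intensity u times the largest exit rate seen among enumerated states
(inflated by one further maximum-length insertion).  It is a heuristic —
the state space is unbounded — and is reported, never used in a
probability.

## Factorability conditions

Condition (i): an event's rate is unchanged by any perturbation of the
state outside the event's zone.  Condition (ii): the event's exit-rate
increment is likewise local; equivalently the cross-increment δδR_X
vanishes for every PAS-separated event pair.  `check_conditions` probes
both by randomized falsification: sampled states, sampled separated event
pairs, tolerance 1e-9 on rate differences.  Sampling can refute but never
prove the universally quantified conditions; a pass is reported as "no
witness found in n probes".  The space-homogeneous family (and its Dawg
and long-indel specializations) passes by the affineness of its exit rate;
the flanked family fails condition (ii) precisely for lengths below the
deletion cutoff (the exit rate bends away from affine for L ≤ L_D^CO − 2;
the L = L_D^CO − 1 point still lies on the line because the missing term
carries a zero weight).

The region-heterogeneous family adds per-region rate increments confined
to tracked descendant regions.  A region's descendant span is maintained
as the positional range of the surviving anchor-interval tokens; sites
inserted strictly inside the span fall inside it positionally.  If every
anchor token dies the region is considered extinct — the lineage of
still-living inserted descendants is not tracked further, a deliberate
simplification documented here because it only matters after total
anchor-interval loss.  The family's region-merging hook removes alignment
delimiters interior to a (deletion-extended, bridged-and-merged) region
span, so all events coupled through one region form a single local
history; with that merging the family passes both condition probes.

## Tree-level probabilities

A rooted tree with branch lengths assigns node times (root at 0); each
branch's window is the ancestor-to-descendant time interval, with
per-branch model parameters supported through a branch→model map.  The
direct MSA probability sums, over phylogenetically correct assignments of
per-column presence sets (each column's carriers plus a connected set of
internal nodes), the root prior times per-branch pairwise probabilities.
By default no tokens absent from every leaf are introduced; the
`limits` parameter admits up to that many such unobservable sites,
carried by connected internal-only node sets at any slot in a region —
they are higher-order terms of the expansion, consistent with the finite
event budget.

The factorized form multiplies the probability of the Dollo reference root
state surviving intact across the whole tree by one factor per
gapless-column-delimited region.  Each region factor sums, over
region-restricted assignments, the root-prior ratio, the per-branch
exponentials of the branch-integrated exit-rate difference between a
hybrid state (reference outside the region, assignment inside) and the
reference, and the product of the local factors of the branch-alignment
zones inside the region.  Its validity is established operationally:
equality with the direct expansion at matched truncation under conditions
(i)–(iii), exercised on three- and four-leaf fixtures, and a nonzero gap
under flanked per-branch models with two coupled regions.

Root priors are length-based: geometric P(L) = (1−q)q^L (multiplicative
ratio q^{δL} per region), uniform on 0..L_max (ratio 1 in support), and
arbitrary custom priors for negative controls.  The condition-(iii) probe
checks P(s₁₂)/P(s₀) = [P(s₁)/P(s₀)]·[P(s₂)/P(s₀)] over joint length
perturbations of two regions.

## Simulator

The Gillespie simulator draws exponential waiting times at the current
exit rate and a channel proportional to the aggregated effective rates;
piecewise-constant profiles are simulated exactly through the u = ∫ c dτ
time change, callable profiles by Ogata-style thinning against a supplied
bound (off unless the bound is given).  Tree simulations derive a
deterministic RNG substream per branch from (seed, branch id), so results
are reproducible regardless of traversal order.  Ancestry tracking makes
every simulated alignment true by construction; `empirical_distribution`
bins canonical homologies with binomial standard errors.

One distributional property deserves a note: with matched insertion and
deletion rates (λ_I = λ_D, identical length distributions) the length
process is *not* exactly drift-free — insertions act at L+1 anchor
positions while the net deletion length rate is proportional to L, so the
mean drift is +λ·E[l] per unit time regardless of L.  The simulator test
asserts this exact first-order value rather than zero; over the tested
window the drift is below 2% of the sequence length.

## Problem sizes and what the tests show

All analytic computations are desk-scale by design: alignments of tens of
columns, event budgets of the parsimony minimum plus one or two, trees of
up to six leaves.  The test suite runs the equivalence algebra on 1000
randomized swaps, the path-integral engine on 200 random rate tuples
against quadrature, the factorization identities on the worked example
plus 20 simulated alignments, and the Monte-Carlo comparisons at 10^5
branch replicates and 4×10^4 tree replicates (agreement asserted within
three binomial standard errors plus the truncation allowance).  The
simulator emulates exactly the process the analytic machinery integrates
— the same rate models, the same clipping and aggregation — so these
checks validate internal consistency and the combinatorics of the
expansion.  They do not validate the biological adequacy of any rate
family for real sequences, and alignment *inference* (reconstructing the
alignment or tree) is entirely out of scope: input alignments are taken
as correct homology structures.

## Known limitations

- Probabilities are truncated sums; no closed-form summation of the
  infinite series is attempted, and the Poisson-tail truncation bound is
  heuristic.
- Per-channel time dependence beyond a shared global profile is not
  implemented in the built-in families.
- The direct MSA expansion is exponential in columns × internal nodes and
  guarded accordingly (≤ 6 leaves, explicit overflow errors).
- The region-heterogeneous span tracking does not follow inserted-site
  lineages after the whole anchor interval has been deleted.
- Substitutions and residue states are deliberately absent: the package
  computes the indel skeleton probability only.
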