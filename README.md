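# indelhist

Ab initio alignment probabilities under a general continuous-time Markov
model of sequence evolution via insertions and deletions.

## The problem

Most indel probabilistic models (pair HMMs, transducers) compute the indel
component of an alignment's probability *horizontally*, column by column.
A genuine evolutionary model instead accumulates transition probabilities
of the *entire* sequence *vertically* along the time axis, which is the only
formulation that handles overlapping indels, arbitrary (e.g. power-law)
indel length distributions, and rate variation across regions without
unnatural restrictions.  `indelhist` implements such a model and answers,
constructively and numerically, when the two pictures coincide: under which
rate models the vertical (ab initio) alignment probability factorizes into
a product of per-region contributions, i.e. a generalized HMM.

It is a research tool for people working on statistical alignment and indel
evolutionary models: every quantity is computed exactly (to a stated event
budget) at desk scale, with a Gillespie simulator of the same model as an
independent Monte-Carlo check.

## The model

Each site carries an *ancestry token*; shared tokens mean homology.  An
insertion `Ins(x, l)` adds `l` fresh sites after position `x`, a deletion
`Del(xB, xE)` removes positions `xB..xE` (clipped at the sequence ends).
A rate model supplies r_I(x, l; s, t) and r_D(xB, xE; s, t) with finite
cut-off lengths; the exit rate R_X(s, t) is the total rate of leaving
state s, and the probability of an ordered N-event history on [t_I, t_F] is
the hypoexponential simplex integral

    P[history] = (Π_ν r_ν) ∫_{t_I<τ_1<…<τ_N<t_F} exp(−Σ_ν ∫ R_X(s_ν)) dτ,

evaluated by confluent divided differences of e^{−R·T} in extended
precision.  The probability of a pairwise alignment given its ancestor is
the sum of history probabilities over all alignment-consistent histories,
organized as a direct sum over *local-history-set (LHS) equivalence
classes*: sorting a history's events into the zones between preserved
ancestral sites (PASs), all order-preserving interleavings of the per-zone
local histories replay to the same final state and form one class of
N!/Π_k N_k! members.

When (i) every event's rate and (ii) every event's exit-rate increment
depend only on the event's own zone, each class probability factorizes and
the whole alignment probability becomes

    P[α | s^A] = P[no event] × Π_κ μ̃_P(γ_κ),

one multiplication factor per inter-PAS zone.  On a rooted tree, with the
additional condition (iii) that the root-state prior is multiplicative
across regions (geometric or uniform length priors), the MSA probability
factorizes the same way across gapless-column-delimited regions, with the
Dollo parsimony state as the reference root.  Built-in rate families cover
the space-homogeneous case (including the Dawg simulator's model and the
detailed-balance "long indel" model — both factorable), a model flanked by
essential sites (non-factorable below the deletion cutoff; the degree of
non-factorability is the exit-rate cross-increment δδR_X), and a
region-heterogeneous family that stays factorable in a merged-region sense.

## Worked example

The seven-site ancestor `[1 2 3 4 5 6 7]` evolving into
`[1 5 6 8 9 10 7]` determines the alignment

```
1 2 3 4 5 6 - - - 7
1 - - - 5 6 8 9 10 7
```

```python
from indelhist import *
from indelhist.ratemodel import make_builtin_model
from indelhist.pwaprob import _region_min

anc = AncestrySeq([1, 2, 3, 4, 5, 6, 7])
dec = AncestrySeq([1, 5, 6, 8, 9, 10, 7])
pwa = build_pwa(anc, dec)
model = make_builtin_model("dawg", {"lambda_I": 0.1, "f_I": [0.5, 0.3, 0.2],
                                    "lambda_D": 0.1, "f_D": [0.5, 0.3, 0.2]})

print("minimum events:", min_events(pwa, model))
for h in enumerate_global_histories(model, pwa, N_max=2).histories:
    print("history:", list(h.ops))

regions = decompose_regions(pwa, model)
budgets = [_region_min(pwa, model, r) + 1 for r in regions.regions]
direct = pwa_prob_direct(model, pwa, 0.0, 1.0, per_region=budgets)
fact = pwa_prob_factorized(model, pwa, 0.0, 1.0, n_max_per_region=budgets)
print(f"direct     P = {direct.total.value:.12e}")
print(f"factorized P = {fact.total.value:.12e}")
```

prints

```
minimum events: 2
history: [Del(2,4), Ins(3,3)]
history: [Ins(6,3), Del(2,4)]
direct     P = 1.204096440205e-04
factorized P = 1.204096440205e-04
```

Two events suffice: delete sites 2–4 then insert three sites (whose
coordinates shift to `Ins(3,3)` once the deletion has happened first), or
insert first and delete after.  Summing all histories up to one extra event
per zone gives the alignment probability 1.204×10⁻⁴ over a unit time
window; the factorized route — the no-event factor 0.208 times the deletion
zone's factor 0.0325 and the insertion zone's 0.0178 (empty zones
contribute 1) — reproduces it to machine precision, as it must for a
space-homogeneous model.

The same API runs on trees (`msa_prob_direct` / `msa_prob_factorized`), and
the `indelhist` command exposes `simulate`, `pwa-prob`, `msa-prob`,
`lhs-decompose` and `check-conditions` subcommands over the ANC alignment
format (one row per sequence, whitespace-separated tokens, `-` for gaps),
JSON model configs, and Newick trees.

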