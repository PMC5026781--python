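"""MSA probabilities on a rooted tree: direct expansion and factorization.

The probability of a multiple alignment is the sum over phylogenetically
correct assignments of ancestral (internal-node) states of the root-state
prior times a product of branch-wise pairwise-alignment probabilities.  A
column's token may occupy a set of tree nodes only if that set forms a
connected subtree containing the leaves that carry it; the Dollo parsimony
state (token at the root iff its carriers span more than one child subtree
of the root) is the reference root state.

Under the per-branch factorability conditions plus a multiplicative root
prior — the prior's state-probability ratio factors across the regions
delimited by gapless columns, as a geometric or uniform length prior does —
the MSA probability factorizes into the probability of the reference root
state surviving intact across the whole tree times one factor per region.
All computations are desk-scale (small trees, short regions) by design.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .seqstate import (GAP, AncestrySeq, MsaAlignment, Region,
                       decompose_regions, build_pwa)
from .indelops import TokenSource
from .histprob import ProbResult, null_history_prob
from .pwaprob import (PwaProbReport, _region_min, pwa_prob_direct,
                      region_mult_factor)
from .ratemodel import RateModel

__all__ = [
    "PhyloTree",
    "RootPrior",
    "GeometricPrior",
    "UniformPrior",
    "CustomPrior",
    "InternalStateSet",
    "dollo_root_state",
    "phylogenetically_correct",
    "enumerate_internal_state_sets",
    "msa_prob_direct",
    "check_root_prior_factorization",
    "msa_prob_factorized",
]


class PhyloTree:
    """Rooted tree with branch lengths; node times measured from the root."""

    def __init__(self, parent: dict, lengths: dict, labels: dict, root):
        self.parent = dict(parent)  # node -> parent (root absent)
        self.lengths = dict(lengths)  # node -> length of branch above it
        self.labels = dict(labels)  # leaf node -> label
        self.root = root
        self.children: dict = {n: [] for n in self.nodes}
        for n, p in self.parent.items():
            self.children[p].append(n)
        self._times = {root: 0.0}
        for n in self._preorder():
            if n != root:
                self._times[n] = self._times[self.parent[n]] + self.lengths[n]

    # -- construction -------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        import dendropy

        tree = dendropy.Tree.get(data=text, schema="newick")
        parent, lengths, labels = {}, {}, {}
        ids = {}
        for i, nd in enumerate(tree.preorder_node_iter()):
            ids[nd] = i
            if nd.parent_node is not None:
                parent[i] = ids[nd.parent_node]
                lengths[i] = float(nd.edge.length or 0.0)
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon else f"leaf{i}"
        return cls(parent, lengths, labels, ids[tree.seed_node])

    # -- structure -----------------------------------------------------------
    @property
    def nodes(self) -> list:
        seen = {self.root}
        for n, p in self.parent.items():
            seen.add(n)
            seen.add(p)
        return sorted(seen)

    @property
    def leaves(self) -> list:
        return sorted(self.labels)

    @property
    def internal_nodes(self) -> list:
        return [n for n in self.nodes if n not in self.labels]

    def label(self, n) -> str:
        return self.labels[n]

    def leaf_by_label(self, label: str):
        for n, l in self.labels.items():
            if l == label:
                return n
        raise KeyError(label)

    def _preorder(self):
        order, stack = [], [self.root]
        kids = {n: [] for n in self.nodes}
        for n, p in self.parent.items():
            kids[p].append(n)
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(sorted(kids[n], reverse=True))
        return order

    def branches_preorder(self):
        return [(self.parent[n], n) for n in self._preorder() if n != self.root]

    def time(self, n) -> float:
        return self._times[n]

    def is_connected(self, nodes: frozenset) -> bool:
        """Do the given nodes induce a connected subtree?"""
        nodes = set(nodes)
        if not nodes:
            return True
        start = next(iter(nodes))
        seen = {start}
        frontier = [start]
        while frontier:
            n = frontier.pop()
            nbrs = list(self.children.get(n, []))
            if n in self.parent:
                nbrs.append(self.parent[n])
            for m in nbrs:
                if m in nodes and m not in seen:
                    seen.add(m)
                    frontier.append(m)
        return seen == nodes


# ---------------------------------------------------------------------------
# Root priors (condition (iii))
# ---------------------------------------------------------------------------

class RootPrior:
    """Prior over root states; built-ins depend on the length only."""

    multiplicative = False

    def prob_length(self, L: int) -> float:
        raise NotImplementedError

    def prob(self, s: AncestrySeq) -> float:
        return self.prob_length(len(s))

    def ratio(self, s: AncestrySeq, s0: AncestrySeq) -> float:
        return self.prob(s) / self.prob(s0)

    def sample(self, rng, token_source: Optional[TokenSource] = None) -> AncestrySeq:
        raise NotImplementedError


class GeometricPrior(RootPrior):
    """P(L) = (1 - q) q^L; ratios factor across regions as q^{δL}."""

    multiplicative = True

    def __init__(self, q: float):
        if not 0 < q < 1:
            raise ValueError("need 0 < q < 1")
        self.q = float(q)

    def prob_length(self, L: int) -> float:
        return (1.0 - self.q) * self.q ** L

    def sample(self, rng, token_source=None):
        L = int(rng.geometric(1.0 - self.q) - 1)
        toks = token_source.take(L) if token_source else range(1, L + 1)
        return AncestrySeq(toks)


class UniformPrior(RootPrior):
    """Uniform over lengths 0..L_max; ratios are 1 within the support."""

    multiplicative = True

    def __init__(self, L_max: int):
        self.L_max = int(L_max)

    def prob_length(self, L: int) -> float:
        return 1.0 / (self.L_max + 1) if 0 <= L <= self.L_max else 0.0

    def sample(self, rng, token_source=None):
        L = int(rng.integers(0, self.L_max + 1))
        toks = token_source.take(L) if token_source else range(1, L + 1)
        return AncestrySeq(toks)


class CustomPrior(RootPrior):
    """Arbitrary length-based prior, e.g. a deliberately non-multiplicative one."""

    def __init__(self, prob_length_func, multiplicative: bool = False):
        self._f = prob_length_func
        self.multiplicative = multiplicative

    def prob_length(self, L: int) -> float:
        return float(self._f(L))


# ---------------------------------------------------------------------------
# Ancestral-state enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InternalStateSet:
    """One assignment of per-column presence sets over all tree nodes.

    ``columns`` is an ordered tuple of (token, frozenset of node ids); the
    sequence state at node n is the subsequence of tokens whose presence
    set contains n.
    """

    columns: tuple

    def state_at(self, n) -> AncestrySeq:
        return AncestrySeq(tok for tok, pres in self.columns if n in pres)

    def presence(self, tok) -> frozenset:
        for t, pres in self.columns:
            if t == tok:
                return pres
        raise KeyError(tok)


def phylogenetically_correct(assignment: InternalStateSet, tree: PhyloTree) -> bool:
    """Every column's presence set must induce a connected subtree."""
    return all(tree.is_connected(pres) for _, pres in assignment.columns)


def dollo_root_state(msa: MsaAlignment, tree: PhyloTree) -> AncestrySeq:
    """Reference root state by Dollo parsimony (each token gained once).

    A token sits at the root iff the leaves carrying it are not confined to
    a single child subtree of the root.
    """
    leaf_of = {tree.label(n): n for n in tree.leaves}
    out = []
    for ci, col in enumerate(msa.columns):
        carriers = {leaf_of[msa.labels[i]] for i, t in enumerate(col) if t is not GAP}
        tok = next(t for t in col if t is not GAP)
        if _spans_root(carriers, tree):
            out.append(tok)
    return AncestrySeq(out)


def _spans_root(carriers: set, tree: PhyloTree) -> bool:
    if not carriers:
        return False
    subtree_of = {}
    for child in tree.children[tree.root]:
        stack = [child]
        while stack:
            n = stack.pop()
            subtree_of[n] = child
            stack.extend(tree.children.get(n, []))
    tops = {subtree_of[c] for c in carriers if c != tree.root}
    return len(tops) > 1 or tree.root in carriers


def _dollo_presence(carriers: set, tree: PhyloTree) -> frozenset:
    """Minimal connected set containing the carriers (Steiner tree)."""
    if not carriers:
        return frozenset()
    # union of paths from each carrier to their MRCA
    paths = []
    for c in carriers:
        path = [c]
        while path[-1] != tree.root:
            path.append(tree.parent[path[-1]])
        paths.append(path)
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    mrca = max(common, key=tree.time)  # deepest common ancestor
    out = {mrca}
    for p in paths:
        for n in p:
            out.add(n)
            if n == mrca:
                break
    return frozenset(out)


def _connected_supersets(carriers: set, tree: PhyloTree, allow_empty: bool):
    """All connected node sets containing the carriers (plus ∅ if allowed)."""
    internal = tree.internal_nodes
    base = _dollo_presence(carriers, tree)
    out = []
    optional = [n for n in internal if n not in base]
    for extra in itertools.chain.from_iterable(
            itertools.combinations(optional, k) for k in range(len(optional) + 1)):
        cand = frozenset(base | set(extra))
        if tree.is_connected(cand):
            out.append(cand)
    if allow_empty and not carriers:
        out = [frozenset()] + [c for c in out if c]
    # dedupe while keeping order
    seen, uniq = set(), []
    for c in out:
        if c not in seen:
            seen.add(c)
            uniq.append(c)
    return uniq


def enumerate_internal_state_sets(msa: MsaAlignment, tree: PhyloTree,
                                  region: Optional[Region] = None,
                                  limits: int = 0,
                                  max_assignments: int = 200_000,
                                  ) -> list[InternalStateSet]:
    """All phylogenetically correct ancestral assignments (region-restricted).

    Columns outside ``region`` are pinned to their Dollo presence sets.
    ``limits`` extra unobservable sites (tokens absent from every leaf) may
    be introduced at any slot inside the region, carried by connected sets
    of internal nodes; with limits=0 none are.  Raises OverflowError when
    the combinatorial budget is exceeded.
    """
    leaf_of = {tree.label(n): n for n in tree.leaves}
    in_region = set(region.columns) if region is not None else set(range(len(msa.columns)))
    per_col_options = []
    for ci, col in enumerate(msa.columns):
        carriers = {leaf_of[msa.labels[i]] for i, t in enumerate(col) if t is not GAP}
        tok = next(t for t in col if t is not GAP)
        if ci in in_region and len(carriers) < len(tree.leaves):
            opts = _connected_supersets(carriers, tree, allow_empty=False)
        else:
            opts = [_dollo_presence(carriers, tree)]
            if len(carriers) == len(tree.leaves):
                opts = [frozenset(tree.nodes)]
        per_col_options.append((ci, tok, [frozenset(set(o) | carriers) for o in opts]))

    n_combos = math.prod(len(o) for _, _, o in per_col_options)
    if n_combos > max_assignments:
        raise OverflowError(f"{n_combos} ancestral assignments exceed the budget")

    # phantom-site options: slot (column index to insert before, within the
    # region) x connected internal-only presence set
    phantom_opts = [()]
    if limits > 0:
        slots = sorted(in_region) + ([max(in_region) + 1] if in_region else [0])
        internal_sets = [frozenset(c)
                         for k in range(1, len(tree.internal_nodes) + 1)
                         for c in itertools.combinations(tree.internal_nodes, k)
                         if tree.is_connected(frozenset(c))]
        singles = [(slot, pres) for slot in slots for pres in internal_sets]
        for k in range(1, limits + 1):
            phantom_opts += list(itertools.combinations(singles, k))

    out = []
    for choice in itertools.product(*(opts for _, _, opts in per_col_options)):
        for phantoms in phantom_opts:
            cols = []
            by_slot: dict = {}
            for pi, (slot, pres) in enumerate(phantoms):
                by_slot.setdefault(slot, []).append((("u", pi), pres))
            for (ci, tok, _), pres in zip(per_col_options, choice):
                for ph in by_slot.get(ci, []):
                    cols.append(ph)
                cols.append((tok, pres))
            for slot in by_slot:
                if slot >= len(msa.columns):
                    cols.extend(by_slot[slot])
            out.append(InternalStateSet(tuple(cols)))
    return out


def is_phantom(tok) -> bool:
    """True for an unobservable-site token introduced by the enumeration."""
    return isinstance(tok, tuple) and len(tok) == 2 and tok[0] == "u"


# ---------------------------------------------------------------------------
# Direct and factorized MSA probabilities
# ---------------------------------------------------------------------------

def _branch_model(models_per_branch, branch) -> RateModel:
    if isinstance(models_per_branch, dict):
        return models_per_branch[branch]
    return models_per_branch


def msa_prob_direct(models_per_branch, msa: MsaAlignment, tree: PhyloTree,
                    root_prior: RootPrior, limits: int = 0,
                    extra_events: int = 0, method: str = "auto",
                    **kw) -> ProbResult:
    """Ab initio MSA probability: sum over ancestral states of the prior
    times per-branch pairwise-alignment probabilities.

    Per-branch alignment probabilities are truncated with per-zone budgets
    of (zone minimum + ``extra_events``), the same rule as the factorized
    route, so the two agree exactly under the factorability conditions.
    """
    if len(tree.leaves) > 6:
        raise OverflowError("direct MSA expansion is desk-scale (<= 6 leaves)")
    assignments = enumerate_internal_state_sets(msa, tree, None, limits)
    total, err2 = 0.0, 0.0
    for asg in assignments:
        term = root_prior.prob(asg.state_at(tree.root))
        if term == 0.0:
            continue
        e2 = 0.0
        for b in tree.branches_preorder():
            model = _branch_model(models_per_branch, b)
            pwa = build_pwa(asg.state_at(b[0]), asg.state_at(b[1]))
            decomp = decompose_regions(pwa, model)
            budgets = [_region_min(pwa, model, r) + extra_events
                       for r in decomp.regions]
            rep = pwa_prob_direct(model, pwa, tree.time(b[0]), tree.time(b[1]),
                                  per_region=budgets, method=method, **kw)
            term *= rep.total.value
            if rep.total.value > 0:
                e2 += (rep.total.error / rep.total.value) ** 2
        total += term
        err2 += (term * math.sqrt(e2)) ** 2 if e2 else 0.0
    return ProbResult(total, method if method != "auto" else "closed_form",
                      math.sqrt(err2))


def check_root_prior_factorization(root_prior: RootPrior, msa: MsaAlignment,
                                   tree: PhyloTree, regions=None,
                                   deltas=(-1, 0, 1, 2)) -> dict:
    """Probe condition (iii): multiplicativity of the prior ratio across regions.

    Perturbs the reference root state's length independently inside two
    regions and checks P(s12)/P(s0) = [P(s1)/P(s0)]·[P(s2)/P(s0)] for all
    sampled perturbation pairs; reports witnesses on failure.
    """
    s0 = dollo_root_state(msa, tree)
    L0 = len(s0)
    witnesses = []
    for d1 in deltas:
        for d2 in deltas:
            if L0 + d1 < 0 or L0 + d2 < 0 or L0 + d1 + d2 < 0:
                continue
            p0 = root_prior.prob_length(L0)
            if p0 == 0.0:
                continue
            lhs = root_prior.prob_length(L0 + d1 + d2) / p0
            rhs = (root_prior.prob_length(L0 + d1) / p0) * \
                  (root_prior.prob_length(L0 + d2) / p0)
            if not math.isclose(lhs, rhs, rel_tol=1e-12, abs_tol=1e-300):
                witnesses.append({"delta": (d1, d2), "joint": lhs, "product": rhs})
    return {"condition": "iii", "passed": not witnesses, "witnesses": witnesses}


def _hybrid_state(asg: InternalStateSet, node, region_cols: set,
                  s0_tokens: frozenset) -> AncestrySeq:
    """Node state with the region's content from ``asg`` and the reference
    root sequence outside it.

    Outside the region every node carries exactly the reference root
    content (the "intact all across the tree" baseline of the overall
    factor); inside, the assignment's presence sets decide.  Phantom
    columns only occur inside the region.
    """
    toks = []
    ci = 0  # MSA column index of the next non-phantom assignment column
    for tok, pres in asg.columns:
        if is_phantom(tok):
            if node in pres:
                toks.append(tok)
            continue
        if ci in region_cols:
            if node in pres:
                toks.append(tok)
        elif tok in s0_tokens:
            toks.append(tok)
        ci += 1
    return AncestrySeq(toks)


def msa_prob_factorized(models_per_branch, msa: MsaAlignment, tree: PhyloTree,
                        root_prior: RootPrior, limits: int = 0,
                        extra_events: int = 0, method: str = "auto",
                        check: bool = False, **kw) -> PwaProbReport:
    """Factorized MSA probability: intact-reference factor times one factor
    per gapless-column-delimited region.

    The overall factor is the prior probability of the Dollo reference root
    state times the probability it survives untouched along every branch.
    Each region factor sums, over the region-restricted ancestral
    assignments, the root-prior ratio times per-branch contributions: the
    exponential of the branch-integrated exit-rate difference between the
    branch's ancestral state and the reference (restricted to the region)
    times the product of the local alignment factors of the zones inside
    the region.
    """
    decomp = decompose_regions(msa)
    s0 = dollo_root_state(msa, tree)
    s0_tokens = frozenset(s0.ids)
    conditions = None
    if check:
        conditions = []
        for b in tree.branches_preorder():
            conditions.extend(_branch_model(models_per_branch, b).check_conditions(
                n_states=10, seed=0))
        conditions.append(check_root_prior_factorization(root_prior, msa, tree))

    overall = root_prior.prob(s0)
    for b in tree.branches_preorder():
        model = _branch_model(models_per_branch, b)
        overall *= null_history_prob(model, s0, tree.time(b[0]),
                                     tree.time(b[1])).value

    factors = []
    for region in decomp.regions:
        region_cols = set(region.columns)
        assignments = enumerate_internal_state_sets(msa, tree, region, limits)
        fsum = 0.0
        for asg in assignments:
            h_root = _hybrid_state(asg, tree.root, region_cols, s0_tokens)
            term = root_prior.ratio(h_root, s0)
            if term == 0.0:
                continue
            for b in tree.branches_preorder():
                model = _branch_model(models_per_branch, b)
                u_b = model.profile.integral(tree.time(b[0]), tree.time(b[1]))
                hA = _hybrid_state(asg, b[0], region_cols, s0_tokens)
                hD = _hybrid_state(asg, b[1], region_cols, s0_tokens)
                term *= math.exp(-(model.exit_rate_base(hA)
                                   - model.exit_rate_base(s0)) * u_b)
                pwa = build_pwa(hA, hD)
                sub = decompose_regions(pwa, model)
                inside = _zones_inside(pwa, sub, region, msa, hA)
                for z in inside:
                    b_ = _region_min(pwa, model, z) + extra_events
                    term *= region_mult_factor(model, pwa, z, tree.time(b[0]),
                                               tree.time(b[1]), b_, method,
                                               **kw).value
            fsum += term
        factors.append(fsum)
    total = overall * math.prod(factors)
    return PwaProbReport(
        total=ProbResult(total, method if method != "auto" else "closed_form"),
        overall=overall,
        region_factors=factors,
        by_history=None, by_class=None,
        n_min=-1, budget=("per-zone-min", extra_events), n_histories=-1,
        truncation_bound=float("nan"), conditions=conditions,
    )


def _zones_inside(pwa, sub_decomp, region: Region, msa: MsaAlignment, hA):
    """Zones of a branch PWA lying inside one MSA region.

    The region is bounded by the tokens of its delimiting gapless columns
    (None at the MSA ends); a zone lies inside iff its span along the
    branch ancestor falls between those tokens.
    """
    def boundary_token(delim):
        if delim is None:
            return None
        col = msa.columns[delim]
        return next(t for t in col if t is not GAP)

    t_left = boundary_token(region.left)
    t_right = boundary_token(region.right)
    pos = {t: i for i, t in enumerate(hA.ids)}
    lo = pos[t_left] if t_left is not None else -1
    hi = pos[t_right] if t_right is not None else len(hA)
    out = []
    for z in sub_decomp.regions:
        zl = pos[z.left] if z.left is not None else -1
        zr = pos[z.right] if z.right is not None else len(hA)
        if zl >= lo and zr <= hi:
            out.append(z)
    return out
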