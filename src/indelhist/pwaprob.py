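"""Pairwise-alignment probabilities: truncated expansion and factorization.

The probability of a pairwise alignment given its ancestor is the sum of
history probabilities over every alignment-consistent indel history.  The
sum is organized as a direct sum over LHS equivalence classes, truncated at
a finite event budget; local histories per inter-PAS zone are enumerated by
depth-first search with admissible pruning, and global histories are all
order-preserving interleavings of one local history per zone.

When the model's event rates and exit-rate increments are local (conditions
(i)/(ii)), the same truncated sum factorizes exactly into an overall
no-event factor times one multiplication factor per zone; both routes are
provided and their matched-truncation agreement is the package's principal
internal consistency check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .seqstate import (GAP, AncestrySeq, PairAlignment, Region,
                       RegionDecomposition, decompose_regions)
from .indelops import (LHS, Del, IndelHistory, IndelOp, Ins, LocalHistory,
                       lhs_from_locals)
from .histprob import (ProbResult, history_prob, lhs_class_prob,
                       local_mult_factor, null_history_prob)
from .ratemodel import RateModel

__all__ = [
    "HistoryEnumeration",
    "PwaProbReport",
    "min_events",
    "enumerate_local_histories",
    "enumerate_global_histories",
    "pwa_prob_direct",
    "region_mult_factor",
    "pwa_prob_factorized",
]


def _region_profile(pwa: PairAlignment, region: Region):
    """(deleted ancestor tokens, interior match tokens, per-slot insert counts).

    The region's sub-alignment is summarized as: which ancestor tokens must
    go, which interior gapless columns must be preserved (these occur only
    in merged meta-regions), and how many inserted sites must survive in
    each slot between consecutive preserved columns.
    """
    cols = [pwa.columns[i] for i in region.columns]
    deleted, matches = [], []
    slot_counts = [0]
    for a, d in cols:
        if a is not GAP and d is not GAP:
            matches.append(a)
            slot_counts.append(0)
        elif a is not GAP:
            deleted.append(a)
        else:
            slot_counts[-1] += 1
    return deleted, matches, slot_counts


def min_events(pwa: PairAlignment, model: RateModel,
               decomposition: Optional[RegionDecomposition] = None) -> int:
    """Minimum number of indel events able to create the alignment.

    Each zone needs ceil(deleted run / L_D^CO) deletions plus
    ceil(inserted run / L_I^CO) insertions; interior preserved columns of a
    merged meta-region split the runs.  Matches exhaustive search on small
    instances.
    """
    if decomposition is None:
        decomposition = decompose_regions(pwa, model)
    total = 0
    for region in decomposition.regions:
        deleted, matches, slots = _region_profile(pwa, region)
        # deletions: runs of deleted tokens are split by interior matches
        runs, cur = [], 0
        for i in region.columns:
            a, d = pwa.columns[i]
            if a is not GAP and d is GAP:
                cur += 1
            else:
                if cur:
                    runs.append(cur)
                cur = 0
        if cur:
            runs.append(cur)
        for run in runs:
            if model.L_D_CO == 0:
                raise ValueError("alignment has deletions but L_D_CO = 0")
            total += -(-run // model.L_D_CO)
        for cnt in slots:
            if cnt:
                if model.L_I_CO == 0:
                    raise ValueError("alignment has insertions but L_I_CO = 0")
                total += -(-cnt // model.L_I_CO)
    return total


def _region_min(pwa, model, region) -> int:
    deleted, matches, slots = _region_profile(pwa, region)
    runs, cur = [], 0
    for i in region.columns:
        a, d = pwa.columns[i]
        if a is not GAP and d is GAP:
            cur += 1
        else:
            if cur:
                runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    n = sum(-(-run // model.L_D_CO) for run in runs) if runs else 0
    n += sum(-(-c // model.L_I_CO) for c in slots if c)
    return n


def enumerate_local_histories(model: RateModel, pwa: PairAlignment,
                              region: Region, n_max: int) -> list[IndelHistory]:
    """All local histories of <= n_max events reproducing the zone's sub-PWA.

    Histories act in isolation on the full ancestor state; every event is
    confined strictly between the zone's delimiters (and, inside a merged
    meta-region, never deletes an interior preserved column).  The search is
    depth-first over effective operators with an admissible lower bound on
    the events still required, so non-parsimonious histories (including
    invisible insert-then-delete round trips) appear whenever the budget
    allows.
    """
    s_a = pwa.ancestor
    deleted, matches, target_slots = _region_profile(pwa, region)
    protected = set(matches)
    orig_region = set(deleted) | protected
    target_matches = list(matches)
    out: list[IndelHistory] = []

    def boundaries(state: AncestrySeq):
        p_l = state.index(region.left) + 1 if region.left is not None else 0
        p_r = state.index(region.right) + 1 if region.right is not None else len(state) + 1
        return p_l, p_r  # 1-based delimiter positions (0 / L+1 at the ends)

    def signature_ok(state: AncestrySeq) -> bool:
        p_l, p_r = boundaries(state)
        content = state.ids[p_l:p_r - 1]
        surv = [t for t in content if t in orig_region]
        if surv != target_matches:
            return False
        slots, cur = [0], 0
        for t in content:
            if t in protected:
                slots.append(0)
            elif t in orig_region:
                return False  # unreachable given surv check, kept for clarity
            else:
                slots[-1] += 1
        return slots == target_slots

    def lower_bound(state: AncestrySeq) -> int:
        p_l, p_r = boundaries(state)
        content = state.ids[p_l:p_r - 1]
        d_rem = sum(1 for t in content if t in orig_region and t not in protected)
        new_cnt = sum(1 for t in content if t not in orig_region)
        target_new = sum(target_slots)
        deficit = max(0, target_new - new_cnt)
        excess = max(0, new_cnt - target_new)
        need = 0
        if d_rem + excess:
            need += -(-(d_rem + excess) // max(1, model.L_D_CO))
        if deficit:
            need += -(-deficit // max(1, model.L_I_CO))
        return need

    def step_ops(state: AncestrySeq):
        p_l, p_r = boundaries(state)
        ops = []
        lo_anchor = p_l if region.left is not None else 0
        hi_anchor = p_r - 1 if region.right is not None else len(state)
        for x in range(lo_anchor, hi_anchor + 1):
            for l in range(1, model.L_I_CO + 1):
                ops.append(Ins(x, l))
        prot_pos = {state.index(t) + 1 for t in protected if t in set(state.ids)}
        for a in range(p_l + 1, p_r):
            if a in prot_pos or a > len(state):
                continue
            for b in range(a, min(a + model.L_D_CO - 1, p_r - 1, len(state)) + 1):
                if b in prot_pos:
                    break
                ops.append(Del(a, b))
        return ops

    from .indelops import TokenSource, apply_op

    def dfs(state: AncestrySeq, ops_so_far: tuple, src_next: int):
        if signature_ok(state):
            out.append(IndelHistory(s_a, ops_so_far))
        if len(ops_so_far) >= n_max:
            return
        if len(ops_so_far) + lower_bound(state) > n_max:
            return
        for op in step_ops(state):
            if model.op_rate(state, op) <= 0.0:
                continue
            if op.is_ins:
                toks = tuple(range(src_next, src_next + op.b))
                nxt, _ = apply_op(state, op, new_tokens=toks)
                dfs(nxt, ops_so_far + (op,), src_next + op.b)
            else:
                nxt, _ = apply_op(state, op)
                dfs(nxt, ops_so_far + (op,), src_next)

    start = TokenSource.after(s_a).next_token
    dfs(s_a, (), start)
    out.sort(key=lambda h: (len(h.ops), h.ops))
    return out


@dataclass
class HistoryEnumeration:
    """All PWA-consistent histories within budget, grouped by LHS class."""

    pwa: PairAlignment
    decomposition: RegionDecomposition
    n_min: int
    budget: object
    groups: list  # (LHS, [IndelHistory, ...])
    diagnostics: dict = field(default_factory=dict)

    @property
    def histories(self) -> list:
        return [h for _, hs in self.groups for h in hs]

    def __len__(self) -> int:
        return len(self.histories)


def enumerate_global_histories(model: RateModel, pwa: PairAlignment,
                               N_max: Optional[int] = None,
                               per_region: Optional[Sequence[int]] = None,
                               ) -> HistoryEnumeration:
    """Interleave per-zone local histories into all consistent global ones.

    Budgets: either a global ``N_max`` (each zone may then use up to
    N_max minus the other zones' minima) or explicit ``per_region`` caps
    (one per zone of the decomposition); combinations exceeding the global
    cap (when given) are dropped.
    """
    decomp = decompose_regions(pwa, model)
    s_a = pwa.ancestor
    mins = [_region_min(pwa, model, r) for r in decomp.regions]
    n_min = sum(mins)
    if per_region is not None:
        budgets = list(per_region)
        if len(budgets) != len(decomp.regions):
            raise ValueError("need one budget per zone")
    else:
        if N_max is None:
            raise ValueError("need N_max or per_region budgets")
        budgets = [N_max - (n_min - m) for m in mins]
    diag = {"n_min": n_min, "region_minima": mins}
    if N_max is not None and N_max < n_min:
        diag["note"] = f"budget {N_max} below minimum {n_min}"
        return HistoryEnumeration(pwa, decomp, n_min, N_max, [], diag)

    locals_per_region = [
        enumerate_local_histories(model, pwa, r, max(0, b))
        for r, b in zip(decomp.regions, budgets)
    ]
    groups = []
    import itertools

    for combo in itertools.product(*locals_per_region):
        n_tot = sum(len(h.ops) for h in combo)
        if N_max is not None and n_tot > N_max:
            continue
        chosen = [(decomp.regions[k], h) for k, h in enumerate(combo) if h.ops]
        lhs = lhs_from_locals(
            s_a, [h.ops for _, h in chosen],
            regions=[(r.left, r.right) for r, _ in chosen],
        )
        from .indelops import enumerate_class

        groups.append((lhs, enumerate_class(s_a, lhs)))
    return HistoryEnumeration(pwa, decomp, n_min,
                              N_max if per_region is None else tuple(budgets),
                              groups, diag)


@dataclass
class PwaProbReport:
    """Alignment probability with its factorization bookkeeping."""

    total: ProbResult
    overall: float  # no-event factor exp(-∫R(s^A))
    region_factors: Optional[list]  # per-zone multiplication factors (factorized route)
    by_history: Optional[float]  # direct route, summed history by history
    by_class: Optional[float]  # direct route, summed class by class
    n_min: int
    budget: object
    n_histories: int
    truncation_bound: float
    conditions: Optional[list] = None

    def to_json(self) -> dict:
        return {
            "total": self.total.to_json(),
            "overall_factor": self.overall,
            "region_factors": self.region_factors,
            "by_history": self.by_history,
            "by_class": self.by_class,
            "n_min": self.n_min,
            "budget": list(self.budget) if isinstance(self.budget, tuple) else self.budget,
            "n_histories": self.n_histories,
            "truncation_bound": self.truncation_bound,
        }


def _truncation_bound(model: RateModel, enum: HistoryEnumeration,
                      u: float, n_cap: int) -> float:
    """Heuristic residual mass: Poisson tail beyond the event budget.

    Intensity u times the largest exit rate seen among enumerated states,
    inflated by one further maximum-length insertion.  Heuristic only — the
    state space is unbounded.
    """
    from scipy.stats import poisson

    states = [enum.pwa.ancestor]
    for h in enum.histories:
        states.extend(h.replay().states)
    r_max = max(model.exit_rate_base(s) for s in states)
    longest = max(states, key=len)
    if model.L_I_CO > 0:
        from .indelops import apply_op

        grown, _ = apply_op(longest, Ins(len(longest), model.L_I_CO))
        r_max = max(r_max, model.exit_rate_base(grown))
    return float(poisson.sf(n_cap, u * r_max))


def pwa_prob_direct(model: RateModel, pwa: PairAlignment, t_I: float, t_F: float,
                    N_max: Optional[int] = None,
                    per_region: Optional[Sequence[int]] = None,
                    method: str = "auto", **kw) -> PwaProbReport:
    """Truncated ab initio alignment probability, summed history by history.

    The same sum is also accumulated class by class (the direct-sum
    organization); the two routes must agree to rounding.
    """
    enum = enumerate_global_histories(model, pwa, N_max, per_region)
    s_a = pwa.ancestor
    by_hist = 0.0
    err2 = 0.0
    for _, hists in enum.groups:
        for h in hists:
            p = history_prob(model, s_a, h.ops, t_I, t_F, method, **kw)
            by_hist += p.value
            err2 += p.error ** 2
    by_class = 0.0
    for lhs, _ in enum.groups:
        by_class += lhs_class_prob(model, s_a, lhs, t_I, t_F, method, **kw).value
    u = model.profile.integral(t_I, t_F)
    n_cap = max((len(h.ops) for h in enum.histories), default=0)
    bound = _truncation_bound(model, enum, u, n_cap) if enum.groups else 1.0
    return PwaProbReport(
        total=ProbResult(by_hist, method if method != "auto" else "closed_form",
                         math.sqrt(err2)),
        overall=null_history_prob(model, s_a, t_I, t_F).value,
        region_factors=None,
        by_history=by_hist,
        by_class=by_class,
        n_min=enum.n_min,
        budget=enum.budget,
        n_histories=len(enum),
        truncation_bound=bound,
    )


def region_mult_factor(model: RateModel, pwa: PairAlignment, region: Region,
                       t_I: float, t_F: float, n_max: int,
                       method: str = "auto", **kw) -> ProbResult:
    """Zone multiplication factor: sum of local-history factors up to n_max."""
    s_a = pwa.ancestor
    total, err2, m = 0.0, 0.0, "closed_form"
    for h in enumerate_local_histories(model, pwa, region, n_max):
        p = local_mult_factor(model, s_a, h.ops, t_I, t_F, method, **kw)
        total += p.value
        err2 += p.error ** 2
        m = p.method
    return ProbResult(total, m, math.sqrt(err2))


def pwa_prob_factorized(model: RateModel, pwa: PairAlignment, t_I: float,
                        t_F: float,
                        n_max_per_region: Union[int, Sequence[int], None] = None,
                        extra_events: int = 2, method: str = "auto",
                        check: bool = False, **kw) -> PwaProbReport:
    """Factorized alignment probability: overall factor times zone factors.

    Valid when the model's rates and exit-rate increments are local; with
    ``check=True`` a randomized condition probe is run first and a failing
    model still gets a report (the caller sees the probe in ``conditions``).
    Default per-zone budget is the zone's own minimum plus ``extra_events``.
    """
    decomp = decompose_regions(pwa, model)
    s_a = pwa.ancestor
    mins = [_region_min(pwa, model, r) for r in decomp.regions]
    if n_max_per_region is None:
        budgets = [m + extra_events for m in mins]
    elif isinstance(n_max_per_region, int):
        budgets = [n_max_per_region] * len(decomp.regions)
    else:
        budgets = list(n_max_per_region)
    conditions = None
    if check:
        conditions = model.check_conditions(n_states=20, seed=0)
    overall = null_history_prob(model, s_a, t_I, t_F).value
    factors = []
    err2 = 0.0
    for region, b in zip(decomp.regions, budgets):
        f = region_mult_factor(model, pwa, region, t_I, t_F, b, method, **kw)
        factors.append(f.value)
        err2 += (f.error / max(f.value, 1e-300)) ** 2
    total = overall * math.prod(factors)
    return PwaProbReport(
        total=ProbResult(total, method if method != "auto" else "closed_form",
                         abs(total) * math.sqrt(err2)),
        overall=overall,
        region_factors=factors,
        by_history=None,
        by_class=None,
        n_min=sum(mins),
        budget=tuple(budgets),
        n_histories=-1,
        truncation_bound=float("nan"),
        conditions=conditions,
    )
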