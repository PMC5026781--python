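"""Gillespie simulation of the indel model along a time axis or a tree.

The finite-time transition operator of the model is exactly the collection
of all indel histories weighted by their probabilities, which is what the
stochastic simulation algorithm samples: exponential waiting times at the
state's total exit rate, then a channel drawn proportionally to the
aggregated effective-operator rates.  Ancestry tracking makes every
simulated alignment *true* by construction, so the simulator doubles as a
fixture generator and as the Monte-Carlo oracle for the analytic
probabilities.

Time profiles: a piecewise-constant (or constant) global modulation c(t) is
simulated exactly by the time change u = ∫ c dτ; general callable profiles
use Ogata-style thinning against a caller-supplied bound on c(t) and are
off unless that bound is given.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqstate import (AncestrySeq, MsaAlignment, PairAlignment, build_pwa,
                       canonical_homology, merge_rows)
from .indelops import IndelHistory, IndelOp, TokenSource, apply_op
from .ratemodel import RateModel

__all__ = [
    "SimResult",
    "TreeSimResult",
    "gillespie_branch",
    "simulate_tree",
    "empirical_distribution",
]


@dataclass
class SimResult:
    """One simulated branch: event log, states, and the true alignment."""

    initial: AncestrySeq
    final: AncestrySeq
    ops: tuple
    times: tuple
    states: tuple  # s_0 .. s_N
    seed_info: object = None

    @property
    def history(self) -> IndelHistory:
        return IndelHistory(self.initial, self.ops)

    @property
    def pwa(self) -> PairAlignment:
        return build_pwa(self.initial, self.final)

    def __len__(self) -> int:
        return len(self.ops)


def _u_to_t(model: RateModel, t_I: float, u: float) -> float:
    """Invert the profile time change: find t with ∫_{t_I}^{t} c = u."""
    prof = model.profile
    if prof.kind == "constant":
        return t_I + u / prof.value
    if prof.kind == "piecewise":
        t = t_I
        remaining = u
        pts = [b for b in prof.breakpoints if b > t_I]
        for b in pts + [math.inf]:
            c = prof.factor(t)
            if c > 0:
                span = (b - t) * c
                if remaining <= span:
                    return t + remaining / c
                remaining -= span
            elif b is math.inf:
                return math.inf
            t = b
        return math.inf  # pragma: no cover
    raise ValueError("callable profiles need thinning (pass profile_bound)")


def gillespie_branch(model: RateModel, s_0: AncestrySeq, t_I: float, t_F: float,
                     rng, token_source: Optional[TokenSource] = None,
                     profile_bound: Optional[float] = None) -> SimResult:
    """Simulate the model from s_0 over [t_I, t_F].

    Waiting times are exponential at the current exit rate (piecewise
    profiles handled exactly by time rescaling, callables by thinning with
    ``profile_bound`` >= sup c(t)); channels are drawn proportionally to the
    aggregated effective rates.  A zero exit rate simply yields no events.
    """
    if token_source is None:
        token_source = TokenSource.after(s_0)
    prof = model.profile
    state = s_0
    t = t_I
    ops, times, states = [], [], [state]
    while True:
        R_base = model.exit_rate_base(state)
        if R_base <= 0.0:
            break
        if prof.kind == "callable":
            if profile_bound is None:
                raise ValueError("callable profile: supply profile_bound for thinning")
            # thinning against the constant bound
            while True:
                t = t + rng.exponential(1.0 / (R_base * profile_bound))
                if t >= t_F:
                    break
                if rng.uniform() * profile_bound <= prof.factor(t):
                    break
            if t >= t_F:
                break
        else:
            u_wait = rng.exponential(1.0 / R_base)
            u_done = prof.integral(t_I, t)
            t = _u_to_t(model, t_I, u_done + u_wait)
            if t >= t_F:
                break
        # channel weights are time-independent: the global profile scales
        # every rate equally, so draw proportionally to the base rates
        agg: dict = {}
        for _, eff, r in model._raw_channels(state):
            agg[eff] = agg.get(eff, 0.0) + r
        chans = sorted(agg.items())
        rates = np.array([r for _, r in chans])
        idx = rng.choice(len(chans), p=rates / rates.sum())
        op = chans[idx][0]
        state, _ = apply_op(state, op, token_source)
        ops.append(op)
        times.append(t)
        states.append(state)
    return SimResult(s_0, state, tuple(ops), tuple(times), tuple(states))


@dataclass
class TreeSimResult:
    """Simulation along a rooted tree: per-branch results and the true MSA."""

    root_state: AncestrySeq
    node_states: dict  # node id -> AncestrySeq
    branch_results: dict  # (parent id, child id) -> SimResult
    msa: MsaAlignment


def _assemble_msa(leaf_states: dict) -> MsaAlignment:
    """Merge leaf ancestry arrays into the true MSA via shared tokens."""
    labels = list(leaf_states)
    return merge_rows(labels, [leaf_states[l] for l in labels])


def simulate_tree(models_per_branch, tree, root, rng,
                  token_source: Optional[TokenSource] = None) -> TreeSimResult:
    """Recursive branch simulation down a rooted tree.

    ``models_per_branch`` is a RateModel or a dict keyed by (parent, child)
    node ids; ``root`` is an AncestrySeq or a sampleable root prior (object
    with ``sample(rng, token_source)``).  Each branch gets its own RNG
    substream derived from (seed, branch id), so results do not depend on
    traversal order.
    """
    from .msaprob import PhyloTree  # local import to avoid a cycle

    if not isinstance(tree, PhyloTree):
        raise TypeError("tree must be a PhyloTree")
    if hasattr(root, "sample"):
        root_state = root.sample(rng, token_source)
    else:
        root_state = root
    if token_source is None:
        token_source = TokenSource.after(root_state)

    def branch_model(b):
        if isinstance(models_per_branch, dict):
            return models_per_branch[b]
        return models_per_branch

    base_seed = int(rng.integers(0, 2 ** 31 - 1))
    node_states = {tree.root: root_state}
    branch_results = {}
    for parent, child in tree.branches_preorder():
        sub = np.random.default_rng((base_seed, hash((parent, child)) & 0x7FFFFFFF))
        res = gillespie_branch(branch_model((parent, child)), node_states[parent],
                               tree.time(parent), tree.time(child), sub,
                               token_source=token_source)
        node_states[child] = res.final
        branch_results[(parent, child)] = res
    leaf_states = {tree.label(n): node_states[n] for n in tree.leaves}
    return TreeSimResult(root_state, node_states, branch_results,
                         _assemble_msa(leaf_states))


def empirical_distribution(model: RateModel, s_0: AncestrySeq, T: float,
                           n_reps: int, rng) -> dict:
    """Frequencies of canonical PWA homologies over n_reps simulations.

    Returns {canonical PairAlignment: (frequency, standard error)} with
    SE = sqrt(p (1-p) / n).
    """
    counts: dict = {}
    for _ in range(n_reps):
        res = gillespie_branch(model, s_0, 0.0, T, rng)
        key = canonical_homology(res.pwa)
        counts[key] = counts.get(key, 0) + 1
    out = {}
    for key, c in counts.items():
        p = c / n_reps
        out[key] = (p, math.sqrt(p * (1 - p) / n_reps))
    return out
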