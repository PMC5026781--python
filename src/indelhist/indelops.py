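"""Indel operators, their algebra, and local-history-set equivalence classes.

An insertion ``Ins(x, l)`` puts ``l`` fresh sites immediately after the
``x``-th site (``x = 0`` means the left end).  A deletion ``Del(xB, xE)``
removes positions ``max(1, xB) .. min(L, xE)``; ranges sticking out of the
sequence are clipped, mirroring a sequence embedded in an effectively
infinite chromosome.  All coordinates are 1-based.

Two events whose footprints are separated by at least one site that both
leave intact can be swapped in time without changing the final state, after
a deterministic coordinate shift (``swap_pair``).  Sorting a global
history's events into the inter-PAS zones of its own resulting alignment
yields its *local history set* (LHS); all order-preserving interleavings of
the local histories form one equivalence class with identical final state.
Interleavings are rebuilt by identity-tracked replay: each local event's
footprint is remembered as site tokens (including to-be-inserted ones), and
positions are re-resolved against the current state, which avoids
compounding coordinate-shift arithmetic.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .seqstate import GAP, AncestrySeq, build_pwa, pas_set

__all__ = [
    "IndelOp",
    "Ins",
    "Del",
    "IndelHistory",
    "ReplayRecord",
    "LocalHistory",
    "LHS",
    "TokenSource",
    "NotSeparableError",
    "apply_op",
    "apply_history",
    "swap_pair",
    "normalize_to_lhs",
    "lhs_from_locals",
    "class_size",
    "enumerate_class",
    "history_to_json",
    "history_from_json",
]


class NotSeparableError(ValueError):
    """The two events overlap or are adjacent: no binary equivalence applies."""


@dataclass(frozen=True, order=True)
class IndelOp:
    """An insertion ('I': after site x, length l) or deletion ('D': xB..xE)."""

    kind: str
    a: int  # Ins: x;  Del: xB
    b: int  # Ins: l;  Del: xE

    def __post_init__(self):
        if self.kind == "I":
            if self.b < 1:
                raise ValueError("insertion length must be >= 1")
        elif self.kind == "D":
            if self.a > self.b:
                raise ValueError("deletion needs xB <= xE")
        else:
            raise ValueError(f"unknown op kind {self.kind!r}")

    @property
    def is_ins(self) -> bool:
        return self.kind == "I"

    def delta_L(self, L: int) -> int:
        """Length change when applied to a sequence of length L."""
        if self.is_ins:
            return self.b
        return -(min(L, self.b) - max(1, self.a) + 1)

    def __repr__(self) -> str:
        return f"{'Ins' if self.is_ins else 'Del'}({self.a},{self.b})"


def Ins(x: int, l: int) -> IndelOp:
    return IndelOp("I", x, l)


def Del(xB: int, xE: int) -> IndelOp:
    return IndelOp("D", xB, xE)


class TokenSource:
    """Monotone counter handing out fresh ancestry tokens."""

    def __init__(self, start: int = 1):
        self.next_token = start

    @classmethod
    def after(cls, *states) -> "TokenSource":
        top = 0
        for s in states:
            for t in s:
                if isinstance(t, int):
                    top = max(top, t)
        return cls(top + 1)

    def take(self, n: int) -> tuple:
        out = tuple(range(self.next_token, self.next_token + n))
        self.next_token += n
        return out


def apply_op(state: AncestrySeq, op: IndelOp, token_source: Optional[TokenSource] = None,
             new_tokens: Optional[Sequence] = None):
    """Apply one operator; returns (new state, footprint).

    Footprint is ``('I', anchor_token_or_None, inserted_tokens)`` or
    ``('D', deleted_tokens)`` — the identity-level record used for replay.
    Explicit ``new_tokens`` override the token source (used when replaying
    a recorded history).
    """
    ids = list(state.ids)
    L = len(ids)
    if op.is_ins:
        x, l = op.a, op.b
        if not 0 <= x <= L:
            raise ValueError(f"insertion anchor {x} out of range 0..{L}")
        if new_tokens is None:
            if token_source is None:
                token_source = TokenSource.after(state)
            new_tokens = token_source.take(l)
        new_tokens = tuple(new_tokens)
        if len(new_tokens) != l:
            raise ValueError("wrong number of inserted tokens")
        anchor = ids[x - 1] if x >= 1 else None
        out = AncestrySeq(ids[:x] + list(new_tokens) + ids[x:])
        return out, ("I", anchor, new_tokens)
    a, b = max(1, op.a), min(L, op.b)
    if a > b:
        raise ValueError(f"deletion {op} has empty clipped range on length {L}")
    deleted = tuple(ids[a - 1:b])
    out = AncestrySeq(ids[:a - 1] + ids[b:])
    return out, ("D", deleted)


@dataclass
class ReplayRecord:
    """Full replay of a history: all intermediate states and footprints."""

    initial: AncestrySeq
    ops: tuple  # effective (clipped) operators actually applied
    states: tuple  # s_0 .. s_N
    footprints: tuple

    @property
    def final(self) -> AncestrySeq:
        return self.states[-1]


def apply_history(state: AncestrySeq, ops: Iterable[IndelOp],
                  token_source: Optional[TokenSource] = None) -> ReplayRecord:
    """Sequentially apply ``ops``, keeping every intermediate state.

    Raw deletions are normalized to their clipped effective form in the
    returned record.  Errors carry the failing step index.
    """
    ops = list(ops)
    if token_source is None:
        token_source = TokenSource.after(state)
    states = [state]
    fps = []
    eff_ops = []
    for step, op in enumerate(ops):
        try:
            nxt, fp = apply_op(states[-1], op, token_source)
        except ValueError as exc:
            raise ValueError(f"step {step}: {exc}") from exc
        if op.is_ins:
            eff_ops.append(op)
        else:
            L = len(states[-1])
            eff_ops.append(Del(max(1, op.a), min(L, op.b)))
        states.append(nxt)
        fps.append(fp)
    return ReplayRecord(state, tuple(eff_ops), tuple(states), tuple(fps))


@dataclass(frozen=True)
class IndelHistory:
    """Temporally ordered indel events (earliest first) on an initial state."""

    initial: AncestrySeq
    ops: tuple

    def __init__(self, initial: AncestrySeq, ops: Iterable[IndelOp]):
        object.__setattr__(self, "initial", initial)
        object.__setattr__(self, "ops", tuple(ops))

    def replay(self) -> ReplayRecord:
        return apply_history(self.initial, self.ops)

    def __len__(self) -> int:
        return len(self.ops)


# ---------------------------------------------------------------------------
# Binary equivalence relations between PAS-separated events.
# ---------------------------------------------------------------------------

def _clip_len(op: IndelOp) -> int:
    # effective deleted length of a possibly left-sticking-out deletion
    return min(op.b - op.a + 1, op.b)


def swap_pair(first: IndelOp, second: IndelOp):
    """Exchange the temporal order of two PAS-separable events.

    Returns ``(new_first, new_second)`` such that applying them in the
    swapped order yields the identical final state on any admissible
    sequence.  Each of the four insertion/deletion pairings supports both
    readings (whichever event lies left along the sequence may come first
    or second); if neither precondition holds the events overlap or are
    adjacent and :class:`NotSeparableError` is raised.
    """
    f, s = first, second
    if f.is_ins and s.is_ins:
        if f.a > s.a:  # first event lies right of second
            return s, Ins(f.a + s.b, f.b)
        if s.a > f.a + f.b:  # second event lies right of first's inserted block
            return Ins(s.a - f.b, s.b), f
    elif f.is_ins and not s.is_ins:
        lp = _clip_len(s)
        if f.a > s.b:  # insertion right of deletion
            return s, Ins(f.a - lp, f.b)
        if s.a - f.b > f.a + 1:  # deletion right of inserted block
            return Del(s.a - f.b, s.b - f.b), f
    elif not f.is_ins and s.is_ins:
        if f.a > s.a + 1:  # deletion right of insertion point
            return s, Del(f.a + s.b, f.b + s.b)
        lp = _clip_len(f)
        if s.a + lp > f.b:  # insertion right of deleted block
            return Ins(s.a + lp, s.b), f
    else:
        l2p = _clip_len(s)
        if f.a > s.b + 1:  # first deletion right of second
            return s, Del(f.a - l2p, f.b - l2p)
        l1p = _clip_len(f)
        if s.a + l1p > f.b + 1:  # second deletion right of first
            return Del(s.a + l1p, s.b + l1p), f
    raise NotSeparableError(f"{f} and {s} are not PAS-separable")


# ---------------------------------------------------------------------------
# LHS normalization and equivalence-class enumeration.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalHistory:
    """One local indel history, isolated on the initial state.

    ``region`` is the (left PAS token, right PAS token) pair of the final
    alignment that confines the events (None marks a sequence end).
    ``ops`` are in isolated coordinates; ``footprints`` carry the
    token-identity records used to re-derive coordinates in interleavings.
    """

    region: tuple
    ops: tuple
    footprints: tuple

    def __len__(self) -> int:
        return len(self.ops)


@dataclass(frozen=True)
class LHS:
    """A local history set: canonical representative of an equivalence class."""

    initial: AncestrySeq
    locals_: tuple  # LocalHistory, ordered left-to-right along the ancestor
    final: AncestrySeq  # final state of identity-tracked replay

    @property
    def counts(self) -> tuple:
        return tuple(len(lh) for lh in self.locals_)

    @property
    def K(self) -> int:
        return len(self.locals_)

    @property
    def N(self) -> int:
        return sum(self.counts)


def _flanking_pas(state: AncestrySeq, lo: int, hi: int, pas: set):
    """Nearest PAS tokens left of index ``lo`` and right of index ``hi``."""
    ids = state.ids
    left = next((ids[i] for i in range(lo - 1, -1, -1) if ids[i] in pas), None)
    right = next((ids[i] for i in range(hi, len(ids)) if ids[i] in pas), None)
    return (left, right)


def _footprint_span(state_before: AncestrySeq, state_after: AncestrySeq, fp) -> tuple:
    """(lo, hi) index range (in state_before, half-open) touched by the event."""
    if fp[0] == "I":
        anchor = fp[1]
        x = state_before.index(anchor) + 1 if anchor is not None else 0
        return x, x
    toks = fp[1]
    idx = [state_before.index(t) for t in toks]
    return min(idx), max(idx) + 1


def normalize_to_lhs(initial: AncestrySeq, ops: Iterable[IndelOp]) -> LHS:
    """Sort a global history's events into the inter-PAS zones of its own PWA.

    Every event lands in exactly one zone of the alignment between the
    history's initial and final states; the per-zone subsequences of events
    (temporal order preserved) are then re-expressed in isolated coordinates
    on the initial state.
    """
    rec = apply_history(initial, ops)
    pas = set(initial.ids) & set(rec.final.ids)
    order = {t: i for i, t in enumerate(initial.ids) if t in pas}

    assignment: dict = {}
    for step, fp in enumerate(rec.footprints):
        before = rec.states[step]
        lo, hi = _footprint_span(before, rec.states[step + 1], fp)
        key = _flanking_pas(before, lo, hi, pas)
        assignment.setdefault(key, []).append((step, fp))

    def region_rank(key):
        left, _ = key
        return -1 if left is None else order[left]

    locals_ = []
    for key in sorted(assignment, key=region_rank):
        steps = assignment[key]
        # isolated replay of just this zone's events, reusing recorded tokens
        state = initial
        iso_ops, iso_fps = [], []
        for _, fp in steps:
            if fp[0] == "I":
                anchor, toks = fp[1], fp[2]
                x = state.index(anchor) + 1 if anchor is not None else 0
                op = Ins(x, len(toks))
                state, fp2 = apply_op(state, op, new_tokens=toks)
            else:
                toks = fp[1]
                idx = sorted(state.index(t) for t in toks)
                if idx != list(range(idx[0], idx[0] + len(idx))):  # pragma: no cover
                    raise AssertionError("non-contiguous deletion footprint")
                op = Del(idx[0] + 1, idx[-1] + 1)
                state, fp2 = apply_op(state, op)
            iso_ops.append(op)
            iso_fps.append(fp2)
        locals_.append(LocalHistory(key, tuple(iso_ops), tuple(iso_fps)))
    return LHS(initial, tuple(locals_), rec.final)


def lhs_from_locals(initial: AncestrySeq, locals_ops: Sequence[Sequence[IndelOp]],
                    regions: Optional[Sequence[tuple]] = None) -> LHS:
    """Build an LHS from per-zone local histories given in isolated coordinates.

    ``locals_ops[k]`` acts on ``initial`` in isolation; zones must be ordered
    left-to-right.  Fresh tokens are drawn from one shared counter so the
    locals' footprints stay disjoint.
    """
    src = TokenSource.after(initial)
    locals_ = []
    for k, ops in enumerate(locals_ops):
        rec = apply_history(initial, ops, token_source=src)
        key = regions[k] if regions is not None else (None, None)
        locals_.append(LocalHistory(key, rec.ops, rec.footprints))
    # identity replay right-to-left to obtain the joint final state
    final = _replay_interleaving(initial, locals_,
                                 _rightmost_first_order([len(l) for l in locals_]))[1]
    return LHS(initial, tuple(locals_), final)


def _rightmost_first_order(counts):
    order = []
    for k in reversed(range(len(counts))):
        order.extend([k] * counts[k])
    return order


def _replay_interleaving(initial: AncestrySeq, locals_: Sequence[LocalHistory],
                         which: Sequence[int]):
    """Replay one interleaving (sequence of local indices) by token identity.

    Returns (IndelHistory with concrete coordinates, final state).
    """
    ptr = [0] * len(locals_)
    state = initial
    ops = []
    for k in which:
        fp = locals_[k].footprints[ptr[k]]
        ptr[k] += 1
        if fp[0] == "I":
            anchor, toks = fp[1], fp[2]
            x = state.index(anchor) + 1 if anchor is not None else 0
            op = Ins(x, len(toks))
            state, _ = apply_op(state, op, new_tokens=toks)
        else:
            toks = fp[1]
            idx = sorted(state.index(t) for t in toks)
            if idx != list(range(idx[0], idx[0] + len(idx))):  # pragma: no cover
                raise AssertionError("non-contiguous deletion footprint")
            op = Del(idx[0] + 1, idx[-1] + 1)
            state, _ = apply_op(state, op)
        ops.append(op)
    return IndelHistory(initial, ops), state


def class_size(lhs: LHS) -> int:
    """Number of LHS-equivalent global histories: N! / prod_k N_k!."""
    from math import factorial

    n = factorial(lhs.N)
    for c in lhs.counts:
        n //= factorial(c)
    return n


def enumerate_class(initial: AncestrySeq, lhs: LHS) -> list[IndelHistory]:
    """All order-preserving interleavings of the LHS's local histories.

    Every returned history replays to the identical final ancestry array;
    operator coordinates are resolved by identity-tracked replay.
    """
    counts = lhs.counts
    labels = []
    for k, c in enumerate(counts):
        labels.extend([k] * c)
    seen = set()
    out = []
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        hist, final = _replay_interleaving(initial, lhs.locals_, perm)
        if final.ids != lhs.final.ids:  # pragma: no cover
            raise AssertionError("interleaving replay diverged from LHS final state")
        out.append(hist)
    return out


# ---------------------------------------------------------------------------
# History serialization: JSON lines, one op per record.
# ---------------------------------------------------------------------------

def history_to_json(hist: IndelHistory) -> str:
    lines = [json.dumps({"initial": list(hist.initial.ids)})]
    for op in hist.ops:
        if op.is_ins:
            lines.append(json.dumps({"type": "I", "x": op.a, "l": op.b}))
        else:
            lines.append(json.dumps({"type": "D", "xB": op.a, "xE": op.b}))
    return "\n".join(lines) + "\n"


def history_from_json(text: str) -> IndelHistory:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    head = json.loads(lines[0])
    initial = AncestrySeq(head["initial"])
    ops = []
    for ln in lines[1:]:
        rec = json.loads(ln)
        if rec["type"] == "I":
            ops.append(Ins(rec["x"], rec["l"]))
        else:
            ops.append(Del(rec["xB"], rec["xE"]))
    return IndelHistory(initial, ops)
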