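"""Indel rate models: channel rates, exit rates, and factorability probes.

A rate model supplies the insertion rate r_I(x, l; s, t) and the *raw*
deletion rate r_D(xB, xE; s, t) (ranges sticking out of the sequence are
allowed and later clipped), with finite cut-off lengths L_I^CO / L_D^CO
beyond which all rates vanish.  The exit rate R_X(s, t) — the total rate of
leaving state s — is the sum of all channels; histories are expressed with
*effective* (clipped) deletion operators whose rate aggregates every raw
channel with the same action, which is exact because identical-action
operators induce identical downstream evolution.

Built-in families
-----------------
``homogeneous``    g_I(l), g_D(l) independent of position (ends may differ
                   via g_IL / g_IR); exit rate is affine in L: A·L + B.
``dawg``           homogeneous with g_I = lambda_I f_I(l), g_D = lambda_D
                   f_D(l) and end rates equal to interior rates.
``long_indel``     homogeneous with detailed-balance-tied rates:
                   lambda_l = (lambda_1/mu_1)^l mu_l, plus dedicated
                   end-insertion and whole-sequence (L = 0) terms.
``flanked``        deletion rate zero whenever the range sticks out
                   (biologically essential flanks); exit rate non-affine for
                   L < L_D^CO, which breaks factorability (condition (ii)).
``region_hetero``  homogeneous baseline plus per-region rate increments
                   confined to tracked descendant regions of anchored
                   intervals of an initial state.

Time dependence enters as one global profile c(t) multiplying every rate;
the shared modulation makes all history probabilities reducible to the
constant-rate case by the time change u = ∫ c(τ) dτ.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .seqstate import AncestrySeq, GAP, PairAlignment
from .indelops import Del, IndelOp, Ins, apply_op

__all__ = [
    "TimeProfile",
    "RateModel",
    "ConditionReport",
    "make_builtin_model",
    "model_from_config",
    "model_to_config",
]


class TimeProfile:
    """Global rate modulation c(t): constant, piecewise-constant, or callable."""

    def __init__(self, kind: str = "constant", value: float = 1.0,
                 breakpoints: Sequence[float] = (), values: Sequence[float] = (),
                 func: Optional[Callable[[float], float]] = None):
        self.kind = kind
        self.value = float(value)
        self.breakpoints = tuple(float(b) for b in breakpoints)
        self.values = tuple(float(v) for v in values)
        self.func = func
        if kind == "piecewise":
            if len(self.values) != len(self.breakpoints) + 1:
                raise ValueError("need len(values) == len(breakpoints) + 1")
            if any(v < 0 for v in self.values):
                raise ValueError("profile values must be >= 0")
        elif kind == "callable" and func is None:
            raise ValueError("callable profile needs func")

    def factor(self, t: float) -> float:
        if self.kind == "constant":
            return self.value
        if self.kind == "piecewise":
            return self.values[bisect_right(self.breakpoints, t)]
        return float(self.func(t))

    def integral(self, t0: float, t1: float) -> float:
        """∫_{t0}^{t1} c(τ) dτ — the effective duration for base rates."""
        if t1 < t0:
            raise ValueError("t1 < t0")
        if self.kind == "constant":
            return self.value * (t1 - t0)
        if self.kind == "piecewise":
            pts = [t0] + [b for b in self.breakpoints if t0 < b < t1] + [t1]
            return sum(self.factor(0.5 * (a + b)) * (b - a)
                       for a, b in zip(pts[:-1], pts[1:]))
        from scipy.integrate import quad

        val, _ = quad(self.func, t0, t1, limit=200)
        return val

    def to_config(self):
        if self.kind == "constant":
            return {"kind": "constant", "value": self.value}
        if self.kind == "piecewise":
            return {"kind": "piecewise", "breakpoints": list(self.breakpoints),
                    "values": list(self.values)}
        return {"kind": "callable"}


@dataclass
class ConditionReport:
    """Outcome of a randomized factorability-condition probe."""

    condition: str  # "i" or "ii"
    passed: bool
    witnesses: list
    tolerance: float
    n_probes: int

    def __bool__(self) -> bool:
        return self.passed


class RateModel:
    """Base class: families override the position-dependent base rates."""

    kind = "abstract"

    def __init__(self, L_I_CO: int, L_D_CO: int, profile: Optional[TimeProfile] = None):
        if L_I_CO < 0 or L_D_CO < 0:
            raise ValueError("cutoffs must be >= 0")
        self.L_I_CO = int(L_I_CO)
        self.L_D_CO = int(L_D_CO)
        self.profile = profile or TimeProfile()
        self.region_merge_hook = None

    # -- family-specific base rates (time factored out) ---------------------
    def r_I_base(self, x: int, l: int, s: AncestrySeq) -> float:
        raise NotImplementedError

    def r_D_base(self, xB: int, xE: int, s: AncestrySeq) -> float:
        raise NotImplementedError

    # -- public, time-dependent rates ---------------------------------------
    def r_I(self, x: int, l: int, s: AncestrySeq, t: float = 0.0) -> float:
        if l < 1 or l > self.L_I_CO or not 0 <= x <= len(s):
            return 0.0
        return self.profile.factor(t) * self.r_I_base(x, l, s)

    def r_D(self, xB: int, xE: int, s: AncestrySeq, t: float = 0.0) -> float:
        if xE - xB + 1 > self.L_D_CO or xE < xB:
            return 0.0
        return self.profile.factor(t) * self.r_D_base(xB, xE, s)

    # -- channel enumeration ------------------------------------------------
    def _raw_channels(self, s: AncestrySeq):
        """Yield (op_raw, effective_op, base_rate) over all nonzero channels.

        Only deletions with a nonempty clipped action are channels: a raw
        range entirely outside the sequence would be a no-op and would break
        the conservation between channels and exit rate.
        """
        L = len(s)
        for x in range(0, L + 1):
            for l in range(1, self.L_I_CO + 1):
                r = self.r_I_base(x, l, s)
                if r > 0.0:
                    op = Ins(x, l)
                    yield op, op, r
        if L >= 1:
            for xB in range(2 - self.L_D_CO, L + 1):
                for xE in range(max(xB, 1), min(xB + self.L_D_CO - 1, L + self.L_D_CO - 1) + 1):
                    if xE - xB + 1 > self.L_D_CO:
                        continue
                    a, b = max(1, xB), min(L, xE)
                    if a > b:
                        continue
                    r = self.r_D_base(xB, xE, s)
                    if r > 0.0:
                        yield Del(xB, xE), Del(a, b), r

    def exit_rate(self, s: AncestrySeq, t: float = 0.0) -> float:
        """Total rate R_X(s, t) of leaving state s (all channels summed)."""
        return self.profile.factor(t) * self.exit_rate_base(s)

    def exit_rate_base(self, s: AncestrySeq) -> float:
        return sum(r for _, _, r in self._raw_channels(s))

    def enumerate_channels(self, s: AncestrySeq, t: float = 0.0):
        """Distinct effective operators with aggregated rates.

        The rates sum exactly to ``exit_rate(s, t)``.
        """
        c = self.profile.factor(t)
        agg: dict = {}
        for _, eff, r in self._raw_channels(s):
            agg[eff] = agg.get(eff, 0.0) + r
        return [(op, c * r) for op, r in sorted(agg.items())]

    def op_rate(self, s: AncestrySeq, op: IndelOp, t: float = 0.0) -> float:
        """Aggregated rate of one effective operator at state s."""
        c = self.profile.factor(t)
        if op.is_ins:
            return c * self.r_I_base(op.a, op.b, s) if op.b <= self.L_I_CO else 0.0
        L = len(s)
        a, b = max(1, op.a), min(L, op.b)
        if (a, b) != (op.a, op.b):
            raise ValueError(f"{op} is not in effective (clipped) form for L={L}")
        total = 0.0
        lo_B = a if a > 1 else 2 - self.L_D_CO
        hi_E = b if b < L else L + self.L_D_CO - 1
        for xB in range(lo_B, a + 1):
            for xE in range(b, hi_E + 1):
                if xE - xB + 1 <= self.L_D_CO:
                    total += self.r_D_base(xB, xE, s)
        return c * total

    # -- exit-rate increments -----------------------------------------------
    def delta_exit(self, s: AncestrySeq, op: IndelOp, t: float = 0.0) -> float:
        """δR_X = R_X(s·op, t) − R_X(s, t)."""
        s2, _ = apply_op(s, op)
        return self.exit_rate(s2, t) - self.exit_rate(s, t)

    def delta_delta_exit(self, s: AncestrySeq, op1: IndelOp, op2: IndelOp,
                         t: float = 0.0) -> float:
        """Degree of non-factorability δδR_X for a PAS-separated event pair.

        Compares the exit-rate increment of op1 before and after op2 has
        acted; op1's coordinates on s·op2 are resolved by token identity.
        Zero for every admissible pair iff the exit-rate increment is local
        (condition (ii)); identically zero for affine exit rates.
        """
        s2, _ = apply_op(s, op2)
        op1b = self._track_op(s, op1, s2)
        r_before = self.delta_exit(s, op1, t)
        s3, _ = apply_op(s2, op1b)
        r_after = self.exit_rate(s3, t) - self.exit_rate(s2, t)
        return r_after - r_before

    @staticmethod
    def _track_op(s: AncestrySeq, op: IndelOp, s2: AncestrySeq) -> IndelOp:
        """Re-express op (defined on s) in the coordinates of s2."""
        if op.is_ins:
            if op.a == 0:
                return op
            anchor = s[op.a - 1]
            return Ins(s2.index(anchor) + 1, op.b)
        a, b = max(1, op.a), min(len(s), op.b)
        toks = s.ids[a - 1:b]
        idx = sorted(s2.index(tk) for tk in toks)
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValueError("event footprint disrupted by the other event")
        return Del(idx[0] + 1, idx[-1] + 1)

    # -- probe helpers --------------------------------------------------------
    def _op_span(self, s: AncestrySeq, op: IndelOp):
        if op.is_ins:
            return (op.a, op.a)  # between sites op.a and op.a+1
        return (max(1, op.a) - 1, min(len(s), op.b))

    def probe_pair_separated(self, s: AncestrySeq, op1: IndelOp, op2: IndelOp) -> bool:
        """True if the two events would lie in different local regions.

        Requires at least one site left intact between the footprints (a
        would-be PAS).  The region-heterogeneous family additionally
        requires the events not to touch the same tracked region.
        """
        a1, b1 = self._op_span(s, op1)
        a2, b2 = self._op_span(s, op2)
        if a1 > a2:
            (a1, b1), (a2, b2) = (a2, b2), (a1, b1)
        return a2 - b1 >= 1

    def check_conditions(self, n_states: int = 30, lengths=(2, 10), seed: int = 0,
                         tol: float = 1e-9, t: float = 0.0) -> list[ConditionReport]:
        """Randomized falsification probe of factorability conditions (i)/(ii).

        Samples states and PAS-separated event pairs (M, P) and checks that
        the rate of M (condition i) and its exit-rate increment (condition
        ii) are unchanged when P perturbs the sequence outside M's region.
        Sampling can only falsify, not prove, the universally quantified
        conditions; a fail report carries explicit witnesses.
        """
        import numpy as np

        rng = np.random.default_rng(seed)
        wit_i, wit_ii = [], []
        n_done = 0
        attempts = 0
        while n_done < n_states and attempts < 50 * n_states:
            attempts += 1
            L = int(rng.integers(lengths[0], lengths[1] + 1))
            s = AncestrySeq(range(1, L + 1))
            chans = self.enumerate_channels(s, t)
            if len(chans) < 2:
                continue
            i1, i2 = rng.choice(len(chans), size=2, replace=False)
            op_m, rate_m = chans[i1]
            op_p, _ = chans[i2]
            if not self.probe_pair_separated(s, op_m, op_p):
                continue
            n_done += 1
            s_pert, _ = apply_op(s, op_p)
            try:
                op_m2 = self._track_op(s, op_m, s_pert)
            except ValueError:
                continue
            rate_after = self.op_rate(s_pert, op_m2, t)
            if abs(rate_after - rate_m) > tol:
                wit_i.append((s, op_m, op_p, rate_m, rate_after))
            ddr = self.delta_delta_exit(s, op_m, op_p, t)
            if abs(ddr) > tol:
                wit_ii.append((s, op_m, op_p, ddr))
        return [
            ConditionReport("i", not wit_i, wit_i, tol, n_done),
            ConditionReport("ii", not wit_ii, wit_ii, tol, n_done),
        ]


# ---------------------------------------------------------------------------
# Built-in families
# ---------------------------------------------------------------------------

class HomogeneousModel(RateModel):
    """Space-homogeneous rates g_I(l), g_D(l); affine exit rate A·L + B."""

    kind = "homogeneous"

    def __init__(self, g_I: Sequence[float], g_D: Sequence[float],
                 g_IL: Optional[Sequence[float]] = None,
                 g_IR: Optional[Sequence[float]] = None,
                 profile: Optional[TimeProfile] = None):
        super().__init__(len(g_I), len(g_D), profile)
        self.g_I = tuple(float(v) for v in g_I)
        self.g_D = tuple(float(v) for v in g_D)
        self.g_IL = tuple(float(v) for v in (g_IL if g_IL is not None else g_I))
        self.g_IR = tuple(float(v) for v in (g_IR if g_IR is not None else g_I))
        if len(self.g_IL) != self.L_I_CO or len(self.g_IR) != self.L_I_CO:
            raise ValueError("end-insertion vectors must match L_I_CO")
        for v in self.g_I + self.g_D + self.g_IL + self.g_IR:
            if v < 0:
                raise ValueError("negative rate")

    def r_I_base(self, x, l, s):
        if x == 0:
            return self.g_IL[l - 1]
        if x == len(s):
            return self.g_IR[l - 1]
        return self.g_I[l - 1]

    def r_D_base(self, xB, xE, s):
        return self.g_D[xE - xB]

    def affine_coeffs(self) -> tuple[float, float]:
        """(A, B) of the exit rate A·L + B (valid for L >= 1), at base time."""
        A = sum(self.g_I) + sum(self.g_D)
        B = (sum((l - 1) * g for l, g in enumerate(self.g_D, start=1))
             - sum(self.g_I) + sum(self.g_IL) + sum(self.g_IR))
        return A, B


class DawgModel(HomogeneousModel):
    """g_I = lambda_I f_I(l), g_D = lambda_D f_D(l); ends equal interior."""

    kind = "dawg"

    def __init__(self, lambda_I: float, f_I: Sequence[float], lambda_D: float,
                 f_D: Sequence[float], profile: Optional[TimeProfile] = None):
        g_I = [lambda_I * f for f in f_I]
        g_D = [lambda_D * f for f in f_D]
        super().__init__(g_I, g_D, g_IL=g_I, g_IR=g_I, profile=profile)
        self.lambda_I, self.lambda_D = float(lambda_I), float(lambda_D)
        self.f_I, self.f_D = tuple(map(float, f_I)), tuple(map(float, f_D))


class LongIndelModel(HomogeneousModel):
    """Detailed-balance rates: lambda_l = (lambda_1/mu_1)^l mu_l.

    End insertions use the tail sums lambda~_l = rho^l Σ_{l'>=l} mu_l', and
    the empty sequence admits only the whole-sequence insertion channel
    lambda~~_l = rho^l Σ_{l'>=l} l' mu_l' (rho = lambda_1/mu_1).
    """

    kind = "long_indel"

    def __init__(self, lambda_1: float, mu_1: float, mu: Sequence[float],
                 L_I_CO: Optional[int] = None, profile: Optional[TimeProfile] = None):
        mu = [float(v) for v in mu]
        if abs(mu[0] - mu_1) > 1e-12 * max(1.0, abs(mu_1)):
            raise ValueError("mu[0] must equal mu_1")
        rho = lambda_1 / mu_1
        L_D_CO = len(mu)
        L_I_CO = L_D_CO if L_I_CO is None else int(L_I_CO)
        if L_I_CO > L_D_CO:
            raise ValueError("long-indel ties need L_I_CO <= L_D_CO")
        lam = [rho ** l * mu[l - 1] for l in range(1, L_I_CO + 1)]
        lam_end = [rho ** l * sum(mu[l - 1:]) for l in range(1, L_I_CO + 1)]
        super().__init__(lam, mu, g_IL=lam_end, g_IR=lam_end, profile=profile)
        self.rho = rho
        self.lam_whole = tuple(
            rho ** l * sum(lp * mu[lp - 1] for lp in range(l, L_D_CO + 1))
            for l in range(1, L_I_CO + 1)
        )

    def r_I_base(self, x, l, s):
        if len(s) == 0:
            return self.lam_whole[l - 1]
        return super().r_I_base(x, l, s)


class FlankedModel(HomogeneousModel):
    """Homogeneous rates, but deletions may not stick out of the sequence.

    Models a neutral region flanked by biologically essential sites.  The
    exit rate is affine only for L >= L_D^CO; below the cutoff it bends,
    the exit-rate increment becomes non-local, and alignment probabilities
    are no longer factorable (condition (ii) fails while (i) holds).
    """

    kind = "flanked"

    def r_D_base(self, xB, xE, s):
        if xB < 1 or xE > len(s):
            return 0.0
        return self.g_D[xE - xB]


@dataclass
class _TrackedRegion:
    anchor_tokens: tuple  # tokens of the interval in the bound initial state
    dg_I: tuple
    dg_D: tuple

    def span(self, s: AncestrySeq):
        """Current [xB;y(s), xE;y(s)] (1-based) or None if extinct."""
        idx = [i for i, t in enumerate(s.ids) if t in self.anchor_set]
        if not idx:
            return None
        return (min(idx) + 1, max(idx) + 1)

    def __post_init__(self):
        self.anchor_set = frozenset(self.anchor_tokens)


class RegionHeteroModel(HomogeneousModel):
    """Homogeneous baseline plus rate increments confined to tracked regions.

    Each region is anchored on an interval of a bound initial state; its
    descendant span in any state s is the positional range of the surviving
    anchor tokens (sites inserted strictly inside the span fall inside it
    positionally).  Insertion increments apply strictly inside a span,
    deletion increments to ranges contained in a span, so every increment
    depends only on the in-region portion of the state and the model keeps
    factorable probabilities in the merged-region sense.
    """

    kind = "region_hetero"

    def __init__(self, g_I, g_D, regions: Sequence[dict],
                 initial_state: AncestrySeq, g_IL=None, g_IR=None,
                 profile: Optional[TimeProfile] = None):
        super().__init__(g_I, g_D, g_IL=g_IL, g_IR=g_IR, profile=profile)
        self.initial_state = initial_state
        self.regions: list[_TrackedRegion] = []
        prev_end = 0
        for spec in regions:
            xB0, xE0 = spec["anchor"]
            if not 1 <= xB0 <= xE0 <= len(initial_state):
                raise ValueError(f"anchor {spec['anchor']} out of range")
            if xB0 <= prev_end:
                raise ValueError("tracked regions overlap")
            prev_end = xE0
            dg_I = tuple(float(v) for v in spec.get("delta_g_I", [0.0] * self.L_I_CO))
            dg_D = tuple(float(v) for v in spec.get("delta_g_D", [0.0] * self.L_D_CO))
            if len(dg_I) != self.L_I_CO or len(dg_D) != self.L_D_CO:
                raise ValueError("increment vectors must match cutoffs")
            self.regions.append(
                _TrackedRegion(tuple(initial_state.ids[xB0 - 1:xE0]), dg_I, dg_D)
            )
        self.region_merge_hook = self._merge_hook

    def r_I_base(self, x, l, s):
        r = super().r_I_base(x, l, s)
        for reg in self.regions:
            sp = reg.span(s)
            if sp and sp[0] <= x <= sp[1] - 1:
                r += reg.dg_I[l - 1]
        if r < 0:
            raise ValueError("negative total insertion rate")
        return r

    def r_D_base(self, xB, xE, s):
        r = super().r_D_base(xB, xE, s)
        for reg in self.regions:
            sp = reg.span(s)
            if sp and sp[0] <= xB and xE <= sp[1]:
                r += reg.dg_D[xE - xB]
        if r < 0:
            raise ValueError("negative total deletion rate")
        return r

    def probe_pair_separated(self, s, op1, op2):
        if not super().probe_pair_separated(s, op1, op2):
            return False
        touched = [self._regions_touched(s, op) for op in (op1, op2)]
        return not (touched[0] & touched[1])

    def _regions_touched(self, s, op):
        a, b = self._op_span(s, op)
        out = set()
        for y, reg in enumerate(self.regions):
            sp = reg.span(s)
            if sp and not (b < sp[0] - 1 or a > sp[1]):
                out.add(y)
        return out

    def _merge_hook(self, pwa: PairAlignment, delims):
        """Drop PAS delimiters interior to a (deletion-extended) meta-region.

        Each tracked region's alignment-column span is extended by any
        deletion run overlapping it; overlapping extended spans merge into
        meta-regions, whose interior PASs cannot separate local histories.
        """
        cols = pwa.columns
        spans = []
        for reg in self.regions:
            idx = [i for i, (a, d) in enumerate(cols) if a in reg.anchor_set]
            if idx:
                spans.append([min(idx), max(idx)])
        # extend by overlapping maximal deletion runs
        runs, start = [], None
        for i, (a, d) in enumerate(cols):
            if a is not GAP and d is GAP:
                start = i if start is None else start
            else:
                if start is not None:
                    runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(cols) - 1))
        for sp in spans:
            for r0, r1 in runs:
                if not (r1 < sp[0] or r0 > sp[1]):
                    sp[0], sp[1] = min(sp[0], r0), max(sp[1], r1)
        # merge overlapping spans into meta-regions
        spans.sort()
        merged = []
        for sp in spans:
            if merged and sp[0] <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], sp[1])
            else:
                merged.append(sp)
        pos = {a: i for i, (a, d) in enumerate(cols) if a is not GAP and d == a}
        return [tok for tok in delims
                if not any(m0 < pos[tok] < m1 for m0, m1 in merged)]


# ---------------------------------------------------------------------------
# Construction and config round-trip
# ---------------------------------------------------------------------------

_FAMILIES = {
    "homogeneous": HomogeneousModel,
    "dawg": DawgModel,
    "long_indel": LongIndelModel,
    "flanked": FlankedModel,
    "region_hetero": RegionHeteroModel,
}


def _profile_from_config(cfg) -> TimeProfile:
    if cfg is None:
        return TimeProfile()
    if cfg.get("kind", "constant") == "constant":
        return TimeProfile("constant", value=cfg.get("value", 1.0))
    if cfg["kind"] == "piecewise":
        return TimeProfile("piecewise", breakpoints=cfg["breakpoints"],
                           values=cfg["values"])
    raise ValueError(f"unknown time profile {cfg!r}")


def make_builtin_model(kind: str, params: dict,
                       initial_state: Optional[AncestrySeq] = None,
                       profile: Optional[TimeProfile] = None) -> RateModel:
    """Construct one of the built-in families from a parameter mapping."""
    if kind not in _FAMILIES:
        raise ValueError(f"unknown model family {kind!r}; know {sorted(_FAMILIES)}")
    p = dict(params)
    if kind in ("homogeneous", "flanked"):
        return _FAMILIES[kind](p["g_I"], p["g_D"], p.get("g_IL"), p.get("g_IR"),
                               profile=profile)
    if kind == "dawg":
        return DawgModel(p["lambda_I"], p["f_I"], p["lambda_D"], p["f_D"],
                         profile=profile)
    if kind == "long_indel":
        return LongIndelModel(p["lambda_1"], p["mu_1"], p["mu"],
                              L_I_CO=p.get("L_I_CO"), profile=profile)
    if initial_state is None:
        raise ValueError("region_hetero needs the initial state to anchor regions")
    return RegionHeteroModel(p["g_I"], p["g_D"], p["regions"], initial_state,
                             p.get("g_IL"), p.get("g_IR"), profile=profile)


_CONFIG_KEYS = {"family", "params", "time_profile", "regions_initial_state"}


def model_from_config(cfg: dict) -> RateModel:
    """Build a model from a structured JSON-style config (schema-checked)."""
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    if "family" not in cfg or "params" not in cfg:
        raise ValueError("config needs 'family' and 'params'")
    profile = _profile_from_config(cfg.get("time_profile"))
    initial = None
    if cfg.get("regions_initial_state") is not None:
        initial = AncestrySeq(cfg["regions_initial_state"])
    return make_builtin_model(cfg["family"], cfg["params"], initial, profile)


def model_to_config(model: RateModel) -> dict:
    cfg: dict = {"family": model.kind, "time_profile": model.profile.to_config()}
    if isinstance(model, DawgModel):
        cfg["params"] = {"lambda_I": model.lambda_I, "f_I": list(model.f_I),
                         "lambda_D": model.lambda_D, "f_D": list(model.f_D)}
    elif isinstance(model, LongIndelModel):
        cfg["params"] = {"lambda_1": model.rho * model.g_D[0], "mu_1": model.g_D[0],
                         "mu": list(model.g_D), "L_I_CO": model.L_I_CO}
    elif isinstance(model, RegionHeteroModel):
        init = model.initial_state
        tok_pos = {t: i + 1 for i, t in enumerate(init.ids)}
        cfg["params"] = {
            "g_I": list(model.g_I), "g_D": list(model.g_D),
            "g_IL": list(model.g_IL), "g_IR": list(model.g_IR),
            "regions": [
                {"anchor": [tok_pos[r.anchor_tokens[0]], tok_pos[r.anchor_tokens[-1]]],
                 "delta_g_I": list(r.dg_I), "delta_g_D": list(r.dg_D)}
                for r in model.regions
            ],
        }
        cfg["regions_initial_state"] = list(init.ids)
    elif isinstance(model, (FlankedModel, HomogeneousModel)):
        cfg["params"] = {"g_I": list(model.g_I), "g_D": list(model.g_D),
                         "g_IL": list(model.g_IL), "g_IR": list(model.g_IR)}
    else:  # pragma: no cover
        raise TypeError(f"cannot serialize {model!r}")
    return cfg
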