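"""Ancestry-indexed sequence states and alignment homology structures.

A *basic sequence state* is an ordered array of pairwise-distinct ancestry
tokens.  Two sites in different sequences are homologous exactly when they
carry the same token; token *values* are otherwise meaningless, so all
equality of alignments is up to bijective relabelling (``canonical_homology``).

A pairwise alignment (PWA) or multiple alignment (MSA) here is a *homology
structure* only: an ordered list of columns of tokens-or-gaps, with no
residue content.  Sites present in both rows of a PWA are *preserved
ancestral sites* (PASs); they delimit the regions inside which local indel
histories are confined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

GAP = None  # gap slot in alignment columns

__all__ = [
    "GAP",
    "AncestrySeq",
    "PairAlignment",
    "MsaAlignment",
    "Region",
    "RegionDecomposition",
    "RearrangementError",
    "build_pwa",
    "pas_set",
    "decompose_regions",
    "canonical_homology",
    "merge_rows",
    "canonical_msa",
    "read_anc",
    "write_anc",
    "export_gapped_fasta",
]


class RearrangementError(ValueError):
    """Shared tokens appear in different relative orders in two sequences.

    The model covers insertions and deletions only; any out-of-order shared
    tokens would require a genome rearrangement.
    """


@dataclass(frozen=True)
class AncestrySeq:
    """Ordered array of distinct ancestry tokens (the basic sequence state)."""

    ids: tuple = ()

    def __init__(self, ids: Iterable = ()):
        ids = tuple(ids)
        if len(set(ids)) != len(ids):
            raise ValueError("ancestry tokens must be pairwise distinct")
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __getitem__(self, i):
        return self.ids[i]

    def index(self, token) -> int:
        return self.ids.index(token)

    def __repr__(self) -> str:
        return f"AncestrySeq({list(self.ids)!r})"


def _check_row(row: Sequence) -> None:
    toks = [t for t in row if t is not GAP]
    if len(set(toks)) != len(toks):
        raise ValueError("duplicate token within one alignment row")


@dataclass(frozen=True)
class PairAlignment:
    """Columns of (ancestor slot, descendant slot); never (GAP, GAP)."""

    columns: tuple

    def __init__(self, columns: Iterable):
        columns = tuple((a, d) for a, d in columns)
        if any(a is GAP and d is GAP for a, d in columns):
            raise ValueError("all-gap column")
        _check_row([a for a, _ in columns])
        _check_row([d for _, d in columns])
        object.__setattr__(self, "columns", columns)

    @property
    def ancestor(self) -> AncestrySeq:
        return AncestrySeq(a for a, _ in self.columns if a is not GAP)

    @property
    def descendant(self) -> AncestrySeq:
        return AncestrySeq(d for _, d in self.columns if d is not GAP)

    @property
    def rows(self) -> tuple:
        return (
            tuple(a for a, _ in self.columns),
            tuple(d for _, d in self.columns),
        )

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class MsaAlignment:
    """Columns of per-leaf slots (token or GAP), with leaf labels."""

    labels: tuple
    columns: tuple

    def __init__(self, labels: Iterable[str], columns: Iterable):
        labels = tuple(labels)
        columns = tuple(tuple(c) for c in columns)
        for c in columns:
            if len(c) != len(labels):
                raise ValueError("column width does not match label count")
            if all(t is GAP for t in c):
                raise ValueError("all-gap column")
        for i in range(len(labels)):
            _check_row([c[i] for c in columns])
        # shared-token order preservation between every pair of rows
        for i, j in itertools.combinations(range(len(labels)), 2):
            ri = [c[i] for c in columns if c[i] is not GAP]
            rj = [c[j] for c in columns if c[j] is not GAP]
            shared = set(ri) & set(rj)
            if [t for t in ri if t in shared] != [t for t in rj if t in shared]:
                raise RearrangementError(
                    f"rows {labels[i]!r} and {labels[j]!r} share tokens out of order"
                )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "columns", columns)

    def row(self, label: str) -> AncestrySeq:
        i = self.labels.index(label)
        return AncestrySeq(c[i] for c in self.columns if c[i] is not GAP)

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class Region:
    """One inter-delimiter zone: columns strictly between two delimiters.

    ``left``/``right`` are the delimiting PAS tokens (or gapless-column
    indices for MSAs); ``None`` marks a sequence end.  ``columns`` are the
    alignment column indices inside the zone (possibly empty).
    """

    left: object
    right: object
    columns: tuple


@dataclass(frozen=True)
class RegionDecomposition:
    delimiters: tuple  # ordered PAS tokens / gapless column indices
    regions: tuple  # ordered Region, len = len(delimiters) + 1

    def __len__(self) -> int:
        return len(self.regions)


def build_pwa(ancestor: AncestrySeq, descendant: AncestrySeq) -> PairAlignment:
    """Align two ancestry arrays into the unique PWA they determine.

    Matched columns are exactly the shared tokens; within one inter-PAS zone
    deletion columns are emitted before insertion columns (a fixed canonical
    order; any order is homology-equivalent).

    Raises :class:`RearrangementError` if shared tokens occur in different
    relative orders.
    """
    a, d = list(ancestor), list(descendant)
    shared = set(a) & set(d)
    sa = [t for t in a if t in shared]
    sd = [t for t in d if t in shared]
    if sa != sd:
        raise RearrangementError("shared tokens out of order between sequences")
    cols = []
    ia = id_ = 0
    for pas in sa + [None]:
        while ia < len(a) and a[ia] != pas:
            cols.append((a[ia], GAP))
            ia += 1
        while id_ < len(d) and d[id_] != pas:
            cols.append((GAP, d[id_]))
            id_ += 1
        if pas is not None:
            cols.append((pas, pas))
            ia += 1
            id_ += 1
    return PairAlignment(cols)


def pas_set(pwa: PairAlignment) -> list:
    """Tokens present in both rows, in order (the preserved ancestral sites)."""
    return [a for a, d in pwa.columns if a is not GAP and d is not GAP]


def _gapless_columns(msa: MsaAlignment) -> list[int]:
    return [i for i, c in enumerate(msa.columns) if all(t is not GAP for t in c)]


def decompose_regions(aln, model=None) -> RegionDecomposition:
    """Split an alignment into inter-delimiter zones.

    By default every PAS (every gapless column for an MSA) is a delimiter.
    A model carrying a region-merging hook (the region-heterogeneous family)
    may drop delimiters interior to one of its meta-regions, so that all
    events inside the meta-region form a single local history.
    """
    if isinstance(aln, PairAlignment):
        delims = pas_set(aln)
        if model is not None and getattr(model, "region_merge_hook", None):
            delims = model.region_merge_hook(aln, delims)
        delim_set = set(delims)
        positions = {a: i for i, (a, d) in enumerate(aln.columns) if a in delim_set and d == a}
    elif isinstance(aln, MsaAlignment):
        delims = _gapless_columns(aln)
        if model is not None and getattr(model, "region_merge_hook", None):
            delims = model.region_merge_hook(aln, delims)
        positions = {i: i for i in delims}
    else:  # pragma: no cover - defensive
        raise TypeError(f"not an alignment: {aln!r}")

    regions = []
    bounds = [None] + list(delims) + [None]
    col_idx = {d: positions[d] for d in delims}
    n = len(aln.columns)
    for left, right in zip(bounds[:-1], bounds[1:]):
        lo = col_idx[left] + 1 if left is not None else 0
        hi = col_idx[right] if right is not None else n
        regions.append(Region(left, right, tuple(range(lo, hi))))
    return RegionDecomposition(tuple(delims), tuple(regions))


def canonical_homology(aln):
    """Relabel tokens by first appearance (row-major within each column).

    Two alignments describe the same homology structure iff their canonical
    forms are identical objects under ``==``.  Also accepts an AncestrySeq.
    """
    mapping: dict = {}

    def relabel(tok):
        if tok is GAP:
            return GAP
        if tok not in mapping:
            mapping[tok] = len(mapping) + 1
        return mapping[tok]

    if isinstance(aln, AncestrySeq):
        return AncestrySeq(relabel(t) for t in aln)
    if isinstance(aln, PairAlignment):
        return PairAlignment((relabel(a), relabel(d)) for a, d in aln.columns)
    if isinstance(aln, MsaAlignment):
        return MsaAlignment(aln.labels, (tuple(relabel(t) for t in c) for c in aln.columns))
    raise TypeError(f"cannot canonicalize {aln!r}")


def merge_rows(labels: Sequence[str], seqs: Sequence[AncestrySeq]) -> MsaAlignment:
    """Merge ancestry arrays into the MSA their shared tokens determine.

    A deterministic linear extension of the token precedence order: at each
    step the first row front token that is at the front of *every* row
    containing it is emitted.  Raises :class:`RearrangementError` if the
    precedence relation is cyclic.  Serves as the canonical column order for
    MSA homology comparison (see :func:`canonical_homology`).
    """
    rows = [list(s) for s in seqs]
    ptr = [0] * len(rows)
    remaining = [set(r) for r in rows]
    columns = []
    while any(p < len(r) for p, r in zip(ptr, rows)):
        emitted = False
        for i, r in enumerate(rows):
            if ptr[i] >= len(r):
                continue
            tok = r[ptr[i]]
            if all(tok not in remaining[j]
                   or (ptr[j] < len(rows[j]) and rows[j][ptr[j]] == tok)
                   for j in range(len(rows))):
                col = []
                for j, rj in enumerate(rows):
                    if ptr[j] < len(rj) and rj[ptr[j]] == tok:
                        col.append(tok)
                        ptr[j] += 1
                        remaining[j].discard(tok)
                    else:
                        col.append(GAP)
                columns.append(tuple(col))
                emitted = True
                break
        if not emitted:
            raise RearrangementError("rows share tokens out of order")
    return MsaAlignment(labels, columns)


def canonical_msa(msa: MsaAlignment) -> MsaAlignment:
    """Canonical form of an MSA homology: re-merged column order + relabel."""
    return canonical_homology(
        merge_rows(msa.labels, [msa.row(l) for l in msa.labels])
    )


# ---------------------------------------------------------------------------
# "ANC" text format: one row per sequence, whitespace-separated tokens,
# "-" for gaps, "#" comments, optional "label:" row prefixes.
# ---------------------------------------------------------------------------

def _parse_token(tok: str):
    if tok == "-":
        return GAP
    try:
        return int(tok)
    except ValueError:
        return tok


def read_anc(path_or_text, kind: str = "auto"):
    """Read an ANC file into a PairAlignment, MsaAlignment, or AncestrySeq.

    ``kind`` is one of ``auto`` (2 rows -> PWA, else MSA), ``pwa``, ``msa``,
    ``seq`` (single ungapped row).
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        text = str(path_or_text)
        if "\n" not in text and not text.strip().startswith(("#",)) and len(text) < 4096:
            try:
                with open(text) as fh:
                    text = fh.read()
            except OSError:
                pass
    rows, labels = [], []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" in line:
            label, line = line.split(":", 1)
            labels.append(label.strip())
        else:
            labels.append(None)
        try:
            rows.append([_parse_token(t) for t in line.split()])
        except ValueError as exc:  # pragma: no cover
            raise ValueError(f"line {ln}: {exc}") from exc
    if any(l is None for l in labels):
        labels = [l if l is not None else f"seq{i + 1}" for i, l in enumerate(labels)]
    if kind == "seq" or (kind == "auto" and len(rows) == 1):
        (row,) = rows
        if GAP in row:
            raise ValueError("gaps not allowed in a bare sequence row")
        return AncestrySeq(row)
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValueError(f"ragged alignment rows (widths {sorted(widths)})")
    columns = list(zip(*rows)) if rows else []
    if kind == "pwa" or (kind == "auto" and len(rows) == 2):
        return PairAlignment(columns)
    return MsaAlignment(labels, columns)


def _fmt(tok) -> str:
    return "-" if tok is GAP else str(tok)


def write_anc(aln, path=None) -> str:
    """Serialize an alignment (or AncestrySeq) to ANC text; round-trips."""
    if isinstance(aln, AncestrySeq):
        lines = [" ".join(_fmt(t) for t in aln)]
    elif isinstance(aln, PairAlignment):
        lines = [" ".join(_fmt(c[i]) for c in aln.columns) for i in range(2)]
    elif isinstance(aln, MsaAlignment):
        lines = [
            f"{label}: " + " ".join(_fmt(c[i]) for c in aln.columns)
            for i, label in enumerate(aln.labels)
        ]
    else:
        raise TypeError(f"cannot serialize {aln!r}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


_FASTA_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


def export_gapped_fasta(aln, fasta_path, legend_path):
    """Export an alignment as gapped FASTA plus a token legend sidecar.

    Export-only and lossy: tokens are rendered as cycling single letters,
    and the legend maps each token to its letter.
    """
    if isinstance(aln, PairAlignment):
        labels = ("ancestor", "descendant")
        rows = [[c[i] for c in aln.columns] for i in range(2)]
    elif isinstance(aln, MsaAlignment):
        labels = aln.labels
        rows = [[c[i] for c in aln.columns] for i in range(len(labels))]
    else:
        raise TypeError(f"cannot export {aln!r}")
    tokens: dict = {}
    for row in rows:
        for t in row:
            if t is not GAP and t not in tokens:
                tokens[t] = _FASTA_ALPHABET[len(tokens) % len(_FASTA_ALPHABET)]
    with open(fasta_path, "w") as fh:
        for label, row in zip(labels, rows):
            fh.write(f">{label}\n")
            fh.write("".join("-" if t is GAP else tokens[t] for t in row) + "\n")
    with open(legend_path, "w") as fh:
        fh.write("# token\tsymbol\n")
        for t, sym in tokens.items():
            fh.write(f"{t}\t{sym}\n")
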