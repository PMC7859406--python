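"""Constrained alignment of a cryptogene region to its mature edited mRNA.

Kinetoplastid U-indel editing inserts and deletes only uridines, with rare
deaminative base conversions (C→U, A→I, the latter read as A→G in cDNA).
The aligner here is a three-state affine dynamic program (match / insertion
run / deletion run) whose operation set is restricted accordingly:

* insertion columns are admissible only where the mRNA character is T,
* deletion columns only where the gene character is T,
* a C(gene)↔T(mRNA) column scores as a C→U edit, A(gene)↔G(mRNA) as A→I,
* any other mismatch is a generic mismatch (tolerating sequencing error),
  scored punitively and optionally disallowed.

The mRNA is always consumed end to end; with ``end_free_gene`` the gene
region may be entered/left anywhere without cost, so a transcript can cover
a sub-interval of a padded gene region.  Tracebacks are canonicalized by
left-shifting every indel run to its 5'-most score-equal placement
(VCF-style normalization), which makes event lists deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .core_io import Interval, SeqRecord

__all__ = [
    "EditEvent",
    "EditingAlignment",
    "EditAlignParams",
    "align_editing",
    "oracle_align",
    "canonicalize",
    "apply_events",
]

U_INS = "U_INS"
U_DEL = "U_DEL"
C_TO_U = "C_TO_U"
A_TO_I = "A_TO_I"

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_NEG = -1.0e30


@dataclass(frozen=True)
class EditEvent:
    """One editing event on the gene/mRNA pair.

    ``gene_pos`` is 0-based on the gene region; for ``U_INS`` it is the gene
    position *before* which the U's are inserted.  ``run_len`` is the number
    of consecutive inserted/deleted U's (always 1 for substitutions).
    """

    kind: str
    gene_pos: int
    mrna_pos: int
    run_len: int = 1

    def __post_init__(self) -> None:
        if self.kind not in (U_INS, U_DEL, C_TO_U, A_TO_I):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.run_len < 1:
            raise ValueError("run_len must be >= 1")
        if self.kind in (C_TO_U, A_TO_I) and self.run_len != 1:
            raise ValueError("substitution events have run_len == 1")


@dataclass(frozen=True)
class EditingAlignment:
    """A canonical gene-region/mRNA alignment restricted to editing events."""

    gene_id: str
    mrna_id: str
    gene_ival: Interval
    events: tuple[EditEvent, ...]
    score: float
    n_ins: int
    n_del: int
    other_mismatches: tuple[tuple[int, int], ...] = ()
    gene_seq: str = field(repr=False, default="")  # full gene-region sequence
    mrna_seq: str = field(repr=False, default="")

    def __post_init__(self) -> None:
        assert self.n_ins == sum(e.run_len for e in self.events if e.kind == U_INS)
        assert self.n_del == sum(e.run_len for e in self.events if e.kind == U_DEL)
        # length conservation over the aligned gene span
        assert len(self.mrna_seq) == len(self.gene_ival) + self.n_ins - self.n_del

    @property
    def n_c_to_u(self) -> int:
        return sum(1 for e in self.events if e.kind == C_TO_U)

    @property
    def n_a_to_i(self) -> int:
        return sum(1 for e in self.events if e.kind == A_TO_I)


@dataclass(frozen=True)
class EditAlignParams:
    """Scores for the constrained editing aligner (penalties negative).

    Run costs are affine: a run of length L costs ``open + (L-1)*ext``.
    Cheap extension reflects the long U-insertion runs of pan-editing.
    """

    match: float = 2.0
    deam_sub: float = -4.0
    other_mismatch: float = -9.0
    ins_open: float = -3.0
    ins_ext: float = -1.0
    del_open: float = -3.0
    del_ext: float = -1.0
    allow_other_mismatch: bool = True
    end_free_gene: bool = True

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match must be positive")
        for name in ("deam_sub", "other_mismatch", "ins_open", "ins_ext", "del_open", "del_ext"):
            if getattr(self, name) >= 0:
                raise ValueError(f"{name} must be negative")


def _sub_score(gc: int, rc: int, p: EditAlignParams) -> float:
    if gc == rc and gc != 4:
        return p.match
    if (gc == 1 and rc == 3) or (gc == 0 and rc == 2):  # C->U, A->I(G)
        return p.deam_sub
    return p.other_mismatch if p.allow_other_mismatch else _NEG


@njit(cache=True)
def _fill(g, r, match, deam, other, ins_open, ins_ext, del_open, del_ext, end_free):  # pragma: no cover
    """Five-state fill: M (aligned column), I/D runs split by whether an
    aligned column has occurred yet (``1`` seen / ``0`` not).  An admissible
    alignment must align at least one gene position, so the optimum is read
    from the *seen* states only."""
    n, m = g.shape[0], r.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    I1 = np.full((n + 1, m + 1), _NEG)
    D1 = np.full((n + 1, m + 1), _NEG)
    I0 = np.full((n + 1, m + 1), _NEG)
    D0 = np.full((n + 1, m + 1), _NEG)
    for i in range(n + 1):
        for j in range(m + 1):
            if i >= 1 and j >= 1:
                gc, rc = g[i - 1], r[j - 1]
                if gc == rc and gc != 4:
                    s = match
                elif (gc == 1 and rc == 3) or (gc == 0 and rc == 2):
                    s = deam
                else:
                    s = other
                svd = 0.0 if (j - 1 == 0 and (end_free or i - 1 == 0)) else _NEG
                prev = max(M[i - 1, j - 1], I1[i - 1, j - 1], D1[i - 1, j - 1],
                           I0[i - 1, j - 1], D0[i - 1, j - 1], svd)
                if prev > _NEG / 2 and s > _NEG / 2:
                    M[i, j] = prev + s
            if j >= 1 and r[j - 1] == 3:
                base = max(M[i, j - 1], D1[i, j - 1])
                best = _NEG
                if base > _NEG / 2:
                    best = base + ins_open
                if I1[i, j - 1] > _NEG / 2 and I1[i, j - 1] + ins_ext > best:
                    best = I1[i, j - 1] + ins_ext
                I1[i, j] = best
                svl = 0.0 if (j - 1 == 0 and (end_free or i == 0)) else _NEG
                base0 = max(D0[i, j - 1], svl)
                best0 = _NEG
                if base0 > _NEG / 2:
                    best0 = base0 + ins_open
                if I0[i, j - 1] > _NEG / 2 and I0[i, j - 1] + ins_ext > best0:
                    best0 = I0[i, j - 1] + ins_ext
                I0[i, j] = best0
            if i >= 1 and g[i - 1] == 3:
                base = max(M[i - 1, j], I1[i - 1, j])
                best = _NEG
                if base > _NEG / 2:
                    best = base + del_open
                if D1[i - 1, j] > _NEG / 2 and D1[i - 1, j] + del_ext > best:
                    best = D1[i - 1, j] + del_ext
                D1[i, j] = best
                svu = 0.0 if (j == 0 and (end_free or i - 1 == 0)) else _NEG
                base0 = max(I0[i - 1, j], svu)
                best0 = _NEG
                if base0 > _NEG / 2:
                    best0 = base0 + del_open
                if D0[i - 1, j] > _NEG / 2 and D0[i - 1, j] + del_ext > best0:
                    best0 = D0[i - 1, j] + del_ext
                D0[i, j] = best0
    return M, I1, D1, I0, D0


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC[c] for c in seq], dtype=np.int8)


def align_editing(
    gene_region: SeqRecord, mrna: SeqRecord, params: EditAlignParams | None = None
) -> Optional[EditingAlignment]:
    """Optimal constrained alignment of a gene region to a mature mRNA.

    Returns ``None`` when no admissible alignment exists (only possible with
    ``allow_other_mismatch=False``).  The returned alignment is canonical:
    every indel run sits at its leftmost score-equal placement.
    """
    p = params or EditAlignParams()
    g = _encode(gene_region.seq)
    r = _encode(mrna.seq)
    other = p.other_mismatch if p.allow_other_mismatch else _NEG
    M, I1, D1, I0, D0 = _fill(
        g, r, p.match, p.deam_sub, other,
        p.ins_open, p.ins_ext, p.del_open, p.del_ext, p.end_free_gene,
    )
    n, m = len(g), len(r)
    if p.end_free_gene:
        ends = [(max(M[i, m], I1[i, m], D1[i, m]), i) for i in range(n + 1)]
        score = max(e[0] for e in ends)
        end_i = min(i for s, i in ends if s == score)
    else:
        score = max(M[n, m], I1[n, m], D1[n, m])
        end_i = n
    if score <= _NEG / 2:
        return None
    ops, start_i = _traceback(M, I1, D1, I0, D0, g, r, end_i, p)
    ops, start_i = _left_shift(ops, start_i, gene_region.seq, mrna.seq)
    return _build_alignment(gene_region, mrna, ops, start_i, float(score))


def _traceback(M, I1, D1, I0, D0, g, r, end_i, p: EditAlignParams):
    m = len(r)
    i, j = end_i, m

    def sv(i, j):
        return 0.0 if (j == 0 and (p.end_free_gene or i == 0)) else _NEG

    vals = {"M": M[i, j], "D1": D1[i, j], "I1": I1[i, j]}
    state = max(vals, key=lambda s: (vals[s], s))  # deterministic tie-break
    ops: list[str] = []
    while True:
        if state == "M":
            ops.append("M")
            i, j = i - 1, j - 1
            cand = [
                ("stop", sv(i, j)),
                ("M", M[i, j]),
                ("D1", D1[i, j]),
                ("I1", I1[i, j]),
                ("D0", D0[i, j]),
                ("I0", I0[i, j]),
            ]
        elif state in ("I1", "I0"):
            ops.append("I")
            here = (I1 if state == "I1" else I0)[i, j]
            j -= 1
            if state == "I1":
                if I1[i, j] > _NEG / 2 and here == I1[i, j] + p.ins_ext:
                    continue
                cand = [("M", M[i, j]), ("D1", D1[i, j])]
            else:
                if I0[i, j] > _NEG / 2 and here == I0[i, j] + p.ins_ext:
                    continue
                cand = [("stop", sv(i, j)), ("D0", D0[i, j])]
        else:  # D1 / D0
            ops.append("D")
            here = (D1 if state == "D1" else D0)[i, j]
            i -= 1
            if state == "D1":
                if D1[i, j] > _NEG / 2 and here == D1[i, j] + p.del_ext:
                    continue
                cand = [("M", M[i, j]), ("I1", I1[i, j])]
            else:
                if D0[i, j] > _NEG / 2 and here == D0[i, j] + p.del_ext:
                    continue
                cand = [("stop", sv(i, j)), ("I0", I0[i, j])]
        best = max(v for _, v in cand)
        state = next(s for s, v in cand if v == best)
        if state == "stop":
            break
    ops.reverse()
    return "".join(ops), i


def _left_shift(ops: str, start_i: int, gene: str, mrna: str) -> tuple[str, int]:
    """Shift every indel run to its 5'-most score-equal admissible placement.

    An I run can move left across an M column when the mRNA character it
    would newly absorb is T (the displaced aligned character is then also T,
    so the column score is unchanged); a D run symmetrically when the gene
    character is T.  At an I/D junction the insertion is placed first.
    """
    cols = list(ops)
    changed = True
    while changed:
        changed = False
        # recompute (i, j) offsets per column
        pos = _column_positions(cols, start_i)
        for t in range(1, len(cols)):
            op, prev = cols[t], cols[t - 1]
            if op == "I" and prev == "M":
                # run start at t: require previous col M and mrna char before run is T
                if t == 0 or (t >= 1 and cols[t - 1] == "M"):
                    i_t, j_t = pos[t]
                    if mrna[j_t - 1] == "T" if j_t >= 1 else False:
                        # j of the M column is j_t - 1... the M col consumes mrna[j_t-1]
                        cols[t - 1], cols[t] = "I", "M"
                        # move the M column past the whole run
                        u = t
                        while u + 1 < len(cols) and cols[u + 1] == "I":
                            cols[u], cols[u + 1] = cols[u + 1], cols[u]
                            u += 1
                        changed = True
                        break
            elif op == "D" and prev == "M":
                i_t, j_t = pos[t]
                if i_t >= 1 and gene[i_t - 1] == "T":
                    cols[t - 1], cols[t] = "D", "M"
                    u = t
                    while u + 1 < len(cols) and cols[u + 1] == "D":
                        cols[u], cols[u + 1] = cols[u + 1], cols[u]
                        u += 1
                    changed = True
                    break
            elif op == "I" and prev == "D":
                # canonical order: insertion before deletion at a junction
                a = t - 1
                while a >= 1 and cols[a - 1] == "D":
                    a -= 1
                b = t
                while b + 1 < len(cols) and cols[b + 1] == "I":
                    b += 1
                cols[a : b + 1] = cols[t : b + 1] + cols[a:t]
                changed = True
                break
    return "".join(cols), start_i


def _column_positions(cols: Sequence[str], start_i: int) -> list[tuple[int, int]]:
    """(gene index, mrna index) consumed-so-far before each column."""
    out = []
    i, j = start_i, 0
    for op in cols:
        out.append((i, j))
        if op == "M":
            i, j = i + 1, j + 1
        elif op == "I":
            j += 1
        else:
            i += 1
    return out


def _build_alignment(
    gene_region: SeqRecord, mrna: SeqRecord, ops: str, start_i: int, score: float
) -> EditingAlignment:
    gene, r = gene_region.seq, mrna.seq
    events: list[EditEvent] = []
    other: list[tuple[int, int]] = []
    i, j = start_i, 0
    t = 0
    n_ins = n_del = 0
    while t < len(ops):
        op = ops[t]
        if op == "M":
            gc, rc = gene[i], r[j]
            if gc != rc:
                if gc == "C" and rc == "T":
                    events.append(EditEvent(C_TO_U, i, j))
                elif gc == "A" and rc == "G":
                    events.append(EditEvent(A_TO_I, i, j))
                else:
                    other.append((i, j))
            i, j, t = i + 1, j + 1, t + 1
        elif op == "I":
            L = 0
            j0 = j
            while t < len(ops) and ops[t] == "I":
                L, j, t = L + 1, j + 1, t + 1
            events.append(EditEvent(U_INS, i, j0, L))
            n_ins += L
        else:
            L = 0
            i0 = i
            while t < len(ops) and ops[t] == "D":
                L, i, t = L + 1, i + 1, t + 1
            events.append(EditEvent(U_DEL, i0, j, L))
            n_del += L
    events.sort(key=lambda e: (e.gene_pos, e.mrna_pos))
    end_i = i
    if end_i == start_i:
        # degenerate all-insertion alignment (possible only for an all-T
        # mRNA); treated as unalignable
        return None
    return EditingAlignment(
        gene_region.id,
        mrna.id,
        Interval(gene_region.id, start_i, end_i),
        tuple(events),
        score,
        n_ins,
        n_del,
        tuple(other),
        gene,
        r,
    )


def canonicalize(aln: EditingAlignment) -> EditingAlignment:
    """Left-shift indel runs to their 5'-most score-equal placement (idempotent)."""
    gene = aln.gene_seq
    start_i = aln.gene_ival.start
    ops = _events_to_ops(aln)
    shifted, _ = _left_shift(ops, start_i, gene, aln.mrna_seq)
    rebuilt = _build_alignment(
        SeqRecord(aln.gene_id, gene),
        SeqRecord(aln.mrna_id, aln.mrna_seq),
        shifted,
        start_i,
        aln.score,
    )
    assert rebuilt is not None
    return rebuilt


def _events_to_ops(aln: EditingAlignment) -> str:
    """Rebuild the column path of an alignment from its event list.

    Event gene positions are absolute on the gene region; the path spans
    ``gene_ival`` only.
    """
    ins_at: dict[int, int] = {}
    deleted: set[int] = set()
    for e in aln.events:
        if e.kind == U_INS:
            ins_at[e.gene_pos] = ins_at.get(e.gene_pos, 0) + e.run_len
        elif e.kind == U_DEL:
            deleted.update(range(e.gene_pos, e.gene_pos + e.run_len))
    ops: list[str] = []
    for i in range(aln.gene_ival.start, aln.gene_ival.end + 1):
        ops.extend("I" * ins_at.get(i, 0))  # insertions attach before i
        if i < aln.gene_ival.end:
            ops.append("D" if i in deleted else "M")
    return "".join(ops)


def apply_events(gene_region: str, events: Sequence[EditEvent]) -> str:
    """Apply an event list to a gene region, reproducing the mature mRNA.

    Exact inverse of alignment when no generic mismatches are present.
    """
    ins_at: dict[int, int] = {}
    sub_at: dict[int, str] = {}
    deleted: set[int] = set()
    for e in events:
        if e.kind == U_INS:
            ins_at[e.gene_pos] = ins_at.get(e.gene_pos, 0) + e.run_len
        elif e.kind == U_DEL:
            deleted.update(range(e.gene_pos, e.gene_pos + e.run_len))
        elif e.kind == C_TO_U:
            sub_at[e.gene_pos] = "T"
        else:
            sub_at[e.gene_pos] = "G"
    out: list[str] = []
    for i in range(len(gene_region) + 1):
        out.append("T" * ins_at.get(i, 0))
        if i < len(gene_region) and i not in deleted:
            out.append(sub_at.get(i, gene_region[i]))
    return "".join(out)


# ---------------------------------------------------------------------------
# Exhaustive oracle (independent of the DP)

_ORACLE_MAX_GENE = 10
_ORACLE_MAX_MRNA = 12


def oracle_align(
    gene_region: SeqRecord, mrna: SeqRecord, params: EditAlignParams | None = None
) -> Optional[float]:
    """Best score over *all* admissible alignments, by explicit enumeration.

    Only for tiny inputs (gene <= 10 nt, mRNA <= 12 nt); returns ``None``
    when no admissible alignment exists.
    """
    p = params or EditAlignParams()
    gene, r = gene_region.seq, mrna.seq
    if len(gene) > _ORACLE_MAX_GENE or len(r) > _ORACLE_MAX_MRNA:
        raise ValueError("oracle_align size limit exceeded")
    n, m = len(gene), len(r)

    def sub(gc: str, rc: str) -> float:
        if gc == rc and gc != "N":
            return p.match
        if (gc == "C" and rc == "T") or (gc == "A" and rc == "G"):
            return p.deam_sub
        return p.other_mismatch if p.allow_other_mismatch else _NEG

    def rec(i: int, j: int, state: str, seen: bool) -> float:
        """Best completion score; an alignment must use >= 1 aligned column."""
        best = _NEG
        if j == m and seen:
            if i == n or p.end_free_gene:
                best = 0.0
        if i < n and j < m:
            s = sub(gene[i], r[j])
            if s > _NEG / 2:
                tail = rec(i + 1, j + 1, "M", True)
                if tail > _NEG / 2:
                    best = max(best, s + tail)
        if j < m and r[j] == "T":
            cost = p.ins_ext if state == "I" else p.ins_open
            tail = rec(i, j + 1, "I", seen)
            if tail > _NEG / 2:
                best = max(best, cost + tail)
        if i < n and gene[i] == "T":
            cost = p.del_ext if state == "D" else p.del_open
            tail = rec(i + 1, j, "D", seen)
            if tail > _NEG / 2:
                best = max(best, cost + tail)
        return best

    starts = range(n + 1) if p.end_free_gene else (0,)
    best = max(rec(i0, 0, "start", False) for i0 in starts)
    return None if best <= _NEG / 2 else best
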