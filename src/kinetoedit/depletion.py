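"""Thymidine-depletion homology search and a standard-space local search.

Pan-edited mitochondrial mRNAs gain so many uridines that the underlying
cryptogene is invisible to a conventional nucleotide search.  Because U-indel
editing only inserts/deletes U (T in cDNA space), a gene and its edited
transcript project onto the *same* string once every T is removed.  The
T-depleted search therefore removes all T's from query and database (keeping
a position map back to original coordinates), runs a seed-and-extend local
search over the remaining 3-letter alphabet, and reports hits in original
coordinates.

The standard-space ``local_search`` is the same seed-and-extend engine over
the 4-letter alphabet; it backs prey decontamination, transcript-to-genome
mapping and minicircle backbone detection.  No low-complexity masking is
applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core_io import Interval, SeqRecord, revcomp

__all__ = [
    "DepletedSeq",
    "HomologyHit",
    "SearchParams",
    "deplete_t",
    "restore_interval",
    "tdepleted_search",
    "local_search",
]


# ---------------------------------------------------------------------------
# T-depletion


@dataclass(frozen=True)
class DepletedSeq:
    """A T-free projection of a DNA sequence with a map back to source coords.

    ``index_map[i]`` is the original position of ``depleted[i]``; it is
    strictly increasing, and re-inserting the removed T's at the gaps of the
    map reconstructs the source sequence exactly.
    """

    source_id: str
    depleted: str
    index_map: tuple[int, ...]

    def __post_init__(self) -> None:
        if "T" in self.depleted:
            raise ValueError("DepletedSeq contains T")
        if len(self.index_map) != len(self.depleted):
            raise ValueError("index_map length mismatch")


def deplete_t(record: SeqRecord) -> DepletedSeq:
    """Project a sequence into T-free space (empty result allowed)."""
    depleted = []
    index_map = []
    for i, c in enumerate(record.seq):
        if c != "T":
            depleted.append(c)
            index_map.append(i)
    return DepletedSeq(record.id, "".join(depleted), tuple(index_map))


def restore_interval(d: DepletedSeq, start: int, end: int) -> Interval:
    """Map a half-open interval in depleted space back to original coordinates."""
    if not (0 <= start < end <= len(d.depleted)):
        raise ValueError(
            f"depleted interval [{start}, {end}) out of range for {d.source_id} "
            f"(depleted length {len(d.depleted)})"
        )
    return Interval(d.source_id, d.index_map[start], d.index_map[end - 1] + 1)


# ---------------------------------------------------------------------------
# Seed-and-extend local search engine


@dataclass(frozen=True)
class SearchParams:
    """Knobs for the seed-and-extend local search.

    ``seed_len=None`` picks the default for the space it runs in: 10 for the
    3-letter depleted alphabet, 12 for standard DNA.  Word sizes down to 4
    are accepted (at a sensitivity/speed cost).
    """

    seed_len: int | None = None
    min_hit_len: int = 40
    min_identity: float = 0.7
    xdrop: float = 20.0
    max_hits: int = 50
    band: int = 15
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_ext: int = -2

    def __post_init__(self) -> None:
        if self.seed_len is not None and self.seed_len < 4:
            raise ValueError("seed_len must be >= 4")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class HomologyHit:
    """A local alignment between query and subject, in original coordinates.

    ``identity`` is matches / alignment columns (gap columns count), measured
    in the space the search ran in.  ``ops`` is the per-column alignment path
    ('=' match, 'X' mismatch, 'I' subject-only column, 'D' query-only column),
    also in search space.
    """

    query_id: str
    subject_id: str
    q_ival: Interval
    s_ival: Interval
    strand: str
    identity: float
    score: float
    n_match: int
    n_cols: int
    ops: str = field(repr=False, default="")


_DEFAULT_SEED = {"depleted": 10, "standard": 12}


def _seed_clusters(q: str, s: str, k: int, band: int, max_gap: int = 200):
    """Exact k-mer seed matches grouped into diagonal clusters."""
    index: dict[str, list[int]] = {}
    for j in range(len(s) - k + 1):
        index.setdefault(s[j : j + k], []).append(j)
    seeds = []  # (diag, qpos)
    for i in range(len(q) - k + 1):
        for j in index.get(q[i : i + k], ()):
            seeds.append((i - j, i))
    if not seeds:
        return []
    seeds.sort()
    clusters = []
    group: list[tuple[int, int]] = [seeds[0]]
    for d, i in seeds[1:]:
        if d - group[-1][0] <= band:
            group.append((d, i))
        else:
            clusters.extend(_split_by_qpos(group, k, max_gap))
            group = [(d, i)]
    clusters.extend(_split_by_qpos(group, k, max_gap))
    return clusters


def _split_by_qpos(group, k, max_gap):
    """Split one diagonal band of seeds where the query jumps too far."""
    group = sorted(group, key=lambda t: t[1])
    out = []
    cur = [group[0]]
    for d, i in group[1:]:
        if i - cur[-1][1] <= max_gap:
            cur.append((d, i))
        else:
            out.append(_bounds(cur, k))
            cur = [(d, i)]
    out.append(_bounds(cur, k))
    return out


def _bounds(seeds, k):
    diags = [d for d, _ in seeds]
    qpos = [i for _, i in seeds]
    return (min(diags), max(diags), min(qpos), max(qpos) + k)


def _banded_sw(a: str, b: str, dlo: int, dhi: int, p: SearchParams):
    """Banded Smith-Waterman with affine gaps; returns (score, ops, qspan, sspan).

    The band restricts diagonals i-j to [dlo, dhi].  N never matches.
    Returns None when no cell scores positive.
    """
    n, m = len(a), len(b)
    width = dhi - dlo + 1
    NEG = float("-inf")
    # score and pointer matrices indexed [i][j - (i - dhi)] ; j = i - d
    H = [[NEG] * width for _ in range(n + 1)]
    E = [[NEG] * width for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * width for _ in range(n + 1)]  # gap in b (consumes a)
    ptr = [[0] * width for _ in range(n + 1)]  # bitfields for traceback
    best = (0.0, 0, 0)
    for i in range(0, n + 1):
        jlo = max(0, i - dhi)
        jhi = min(m, i - dlo)
        if jlo > jhi:
            continue
        for j in range(jlo, jhi + 1):
            c = j - (i - dhi)
            if i == 0 or j == 0:
                H[i][c] = 0.0
                continue
            ai, bj = a[i - 1], b[j - 1]
            sub = p.match if (ai == bj and ai != "N") else p.mismatch
            cd = (j - 1) - (i - 1 - dhi)
            diag = H[i - 1][cd] if 0 <= cd < width else NEG
            h = max(0.0, (diag + sub) if diag != NEG else NEG)
            # E: gap in a, from (i, j-1)
            cl = (j - 1) - (i - dhi)
            e = NEG
            if 0 <= cl < width:
                hh, ee = H[i][cl], E[i][cl]
                e = max(
                    hh + p.gap_open if hh != NEG else NEG,
                    ee + p.gap_ext if ee != NEG else NEG,
                )
            # F: gap in b, from (i-1, j)
            cu = j - (i - 1 - dhi)
            f = NEG
            if 0 <= cu < width:
                hh, ff = H[i - 1][cu], F[i - 1][cu]
                f = max(
                    hh + p.gap_open if hh != NEG else NEG,
                    ff + p.gap_ext if ff != NEG else NEG,
                )
            E[i][c], F[i][c] = e, f
            hbest = max(h, e, f)
            H[i][c] = hbest
            # pointers: 1 diag, 2 from E, 3 from F; plus gap-continuation bits
            if hbest <= 0:
                ptr[i][c] = 0
            elif hbest == h:
                ptr[i][c] = 1
            elif hbest == e:
                ptr[i][c] = 2
            else:
                ptr[i][c] = 3
            if hbest > best[0]:
                best = (hbest, i, j)
    if best[0] <= 0:
        return None
    score, i, j = best
    ops = []
    state = "H"
    while i > 0 and j > 0:
        c = j - (i - dhi)
        if state == "H":
            move = ptr[i][c]
            if move == 0:
                break
            if move == 1:
                ops.append("=" if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else "X")
                i, j = i - 1, j - 1
            elif move == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            # decide whether this gap column came from H or an extended E
            cl = (j - 1) - (i - dhi)
            ops.append("I")
            prev_e = E[i][cl] if 0 <= cl < width else NEG
            here = E[i][j - (i - dhi)]
            j -= 1
            if prev_e != NEG and here == prev_e + p.gap_ext:
                state = "E"
            else:
                state = "H"
        else:  # F
            cu = j - (i - 1 - dhi)
            ops.append("D")
            prev_f = F[i - 1][cu] if 0 <= cu < width else NEG
            here = F[i][j - (i - dhi)]
            i -= 1
            if prev_f != NEG and here == prev_f + p.gap_ext:
                state = "F"
            else:
                state = "H"
    ops.reverse()
    return score, "".join(ops), (i, best[1]), (j, best[2])


def _search_one_strand(qseq: str, sseq: str, params: SearchParams, seed_len: int):
    """Raw hits of qseq against one strand of sseq: (score, ops, qspan, sspan)."""
    if len(qseq) < seed_len or len(sseq) < seed_len:
        return []
    # how far past the outermost seeds an alignment may extend before the
    # score must have dropped below the x-drop cutoff
    margin = int(params.xdrop) + params.band
    raw = []
    for dlo, dhi, qlo, qhi in _seed_clusters(qseq, sseq, seed_len, params.band):
        qa = max(0, qlo - margin)
        qb = min(len(qseq), qhi + margin)
        sa = max(0, (qlo - dhi) - margin)
        sb = min(len(sseq), (qhi - dlo) + margin)
        a = qseq[qa:qb]
        b = sseq[sa:sb]
        # diagonal bounds of the cluster relative to the window slices
        rdlo = (dlo - params.band) - (qa - sa)
        rdhi = (dhi + params.band) - (qa - sa)
        rdlo = max(rdlo, -(len(b) - 1)) if len(b) else rdlo
        rdhi = min(rdhi, len(a) - 1) if len(a) else rdhi
        res = _banded_sw(a, b, rdlo, rdhi, params)
        if res is None:
            continue
        score, ops, (qi0, qi1), (sj0, sj1) = res
        raw.append((score, ops, (qa + qi0, qa + qi1), (sa + sj0, sa + sj1)))
    return raw


def _dedup(hits: list[HomologyHit]) -> list[HomologyHit]:
    kept: list[HomologyHit] = []
    for h in hits:
        dup = False
        for k in kept:
            if (
                k.subject_id == h.subject_id
                and k.strand == h.strand
                and h.s_ival.overlap(k.s_ival) > 0.5 * min(len(h.s_ival), len(k.s_ival))
                and h.q_ival.overlap(k.q_ival) > 0.5 * min(len(h.q_ival), len(k.q_ival))
            ):
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def _finalize(hits: list[HomologyHit], params: SearchParams) -> list[HomologyHit]:
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.s_ival.start))
    hits = _dedup(hits)
    return hits[: params.max_hits]


def local_search(
    query: SeqRecord, db: Sequence[SeqRecord], params: SearchParams | None = None
) -> list[HomologyHit]:
    """Seed-and-extend local search in standard DNA space, both strands.

    Hits are sorted by descending score (ties: subject id, then subject
    start); identity counts gap columns; minus-strand subject intervals are
    reported on the forward strand.
    """
    params = params or SearchParams()
    seed_len = params.seed_len or _DEFAULT_SEED["standard"]
    hits: list[HomologyHit] = []
    for subj in db:
        for strand in "+-":
            sseq = subj.seq if strand == "+" else revcomp(subj.seq)
            for score, ops, (q0, q1), (s0, s1) in _search_one_strand(
                query.seq, sseq, params, seed_len
            ):
                n_cols = len(ops)
                n_match = ops.count("=")
                if n_cols < params.min_hit_len:
                    continue
                identity = n_match / n_cols
                if identity < params.min_identity:
                    continue
                if strand == "-":
                    s0, s1 = len(subj.seq) - s1, len(subj.seq) - s0
                hits.append(
                    HomologyHit(
                        query.id,
                        subj.id,
                        Interval(query.id, q0, q1),
                        Interval(subj.id, s0, s1, strand),
                        strand,
                        identity,
                        score,
                        n_match,
                        n_cols,
                        ops,
                    )
                )
    return _finalize(hits, params)


def tdepleted_search(
    query: SeqRecord, db: Sequence[SeqRecord], params: SearchParams | None = None
) -> list[HomologyHit]:
    """Local search in T-depleted space; hits reported in original coordinates.

    Both query and every subject strand are projected T-free before seeding,
    so a cryptogene and its U-indel-edited transcript align at 100% identity
    regardless of the editing pattern.  ``identity``/``score`` are measured in
    depleted space; intervals are mapped back through the position maps.
    """
    params = params or SearchParams()
    seed_len = params.seed_len or _DEFAULT_SEED["depleted"]
    dq = deplete_t(query)
    if not dq.depleted:
        return []
    hits: list[HomologyHit] = []
    for subj in db:
        for strand in "+-":
            sseq = subj.seq if strand == "+" else revcomp(subj.seq)
            ds = deplete_t(SeqRecord(subj.id, sseq))
            if not ds.depleted:
                continue
            for score, ops, (q0, q1), (s0, s1) in _search_one_strand(
                dq.depleted, ds.depleted, params, seed_len
            ):
                n_cols = len(ops)
                n_match = ops.count("=")
                if n_cols < params.min_hit_len:
                    continue
                identity = n_match / n_cols
                if identity < params.min_identity:
                    continue
                q_ival = restore_interval(dq, q0, q1)
                s_iv = restore_interval(ds, s0, s1)
                a, b = s_iv.start, s_iv.end
                if strand == "-":
                    a, b = len(subj.seq) - b, len(subj.seq) - a
                hits.append(
                    HomologyHit(
                        query.id,
                        subj.id,
                        q_ival,
                        Interval(subj.id, a, b, strand),
                        strand,
                        identity,
                        score,
                        n_match,
                        n_cols,
                        ops,
                    )
                )
    return _finalize(hits, params)
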