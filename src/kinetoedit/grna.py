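"""Minicircle/maxicircle architecture and guide-RNA duplex detection.

Kinetoplastid mitochondrial DNA splits into maxicircles (protein/rRNA genes,
possibly cryptogenes) and minicircles (a conserved backbone plus short
variable cassettes encoding guide RNAs).  A guide RNA is antisense to a
block of *edited* mRNA, pairing by Watson-Crick rules plus G:U wobble.

This module classifies contigs using homology evidence against mature
transcripts, segments conserved backbones shared between contigs, finds
gRNA cassettes as wobble-aware antisense duplexes against edited mRNAs, and
tests whether a contig is circular-mapping (terminal self-overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core_io import Interval, SeqRecord, revcomp
from .depletion import HomologyHit, SearchParams, local_search, tdepleted_search

__all__ = [
    "MtContigClass",
    "GRnaHit",
    "GRnaParams",
    "MtClassifyParams",
    "classify_contigs",
    "find_backbone",
    "find_grnas",
    "detect_circularity",
]

MAXICIRCLE_LIKE = "MAXICIRCLE_LIKE"
MINICIRCLE_LIKE = "MINICIRCLE_LIKE"
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class MtContigClass:
    contig_id: str
    label: str
    evidence: tuple[str, ...]
    circular: bool
    backbone_ivals: tuple[Interval, ...]


@dataclass(frozen=True)
class GRnaHit:
    """An ungapped antisense duplex between a minicircle cassette and an mRNA.

    ``cassette_ival.strand`` is the strand the gRNA would be transcribed
    from; tallies satisfy duplex length == n_wc + n_wobble + n_mismatch ==
    len(cassette_ival) == len(mrna_ival).  ``anchor_len`` is the longest run
    of consecutive Watson-Crick pairs.
    """

    minicircle_id: str
    cassette_ival: Interval
    mrna_id: str
    mrna_ival: Interval
    n_wc: int
    n_wobble: int
    n_mismatch: int
    anchor_len: int
    score: float = 0.0

    def __post_init__(self) -> None:
        total = self.n_wc + self.n_wobble + self.n_mismatch
        assert total == len(self.cassette_ival) == len(self.mrna_ival)


@dataclass(frozen=True)
class GRnaParams:
    """Wobble-aware duplex scoring; ``allow_wobble=False`` scores G:U pairs
    as mismatches, mimicking a plain nucleotide-identity search."""

    # pan-edited mRNAs are U-rich, so short chance duplexes against them are
    # far more common than base-composition-naive estimates suggest; 30/8
    # keeps specificity with no sensitivity cost for ~85 nt cassettes
    min_duplex: int = 30
    min_anchor: int = 8
    wc_score: float = 1.0
    wobble_score: float = 0.5
    # random pairs are WC/wobble ~37% of the time, so a -1 mismatch keeps
    # chance extension barely negative and lets duplexes wander past the
    # cassette; -2 makes off-cassette extension decay fast
    mismatch_pen: float = -2.0
    max_mismatch_frac: float = 0.1
    seed_len: int = 10
    xdrop: float = 4.0
    allow_wobble: bool = True

    def __post_init__(self) -> None:
        if not (self.min_duplex >= self.min_anchor >= 1):
            raise ValueError("need min_duplex >= min_anchor >= 1")


@dataclass(frozen=True)
class MtClassifyParams:
    minicircle_len_range: tuple[int, int] = (300, 2500)
    backbone_min_identity: float = 0.90
    backbone_min_len: int = 100
    backbone_min_share: int = 2
    maxi_min_hit: int = 150  # nt of subject covered for mRNA/rRNA gene evidence
    circ_min_overlap: int = 50
    circ_max_mismatch: int = 2
    search: SearchParams = field(default_factory=SearchParams)


# ---------------------------------------------------------------------------
# Contig classification


def classify_contigs(
    contigs: Sequence[SeqRecord],
    mrna_set: Sequence[SeqRecord],
    rrna_set: Sequence[SeqRecord] = (),
    params: MtClassifyParams | None = None,
) -> list[MtContigClass]:
    """Label contigs MAXICIRCLE_LIKE / MINICIRCLE_LIKE / UNCLASSIFIED.

    Maxicircle evidence is a T-depleted (mRNA) or standard (rRNA) homology
    hit covering >= ``maxi_min_hit`` nt of the contig — long enough to be a
    gene region rather than an ~85 nt gRNA cassette.  Minicircle calls
    require a shared backbone interval and a length within the configured
    range.
    """
    if not contigs:
        raise ValueError("classify_contigs: empty contig set")
    p = params or MtClassifyParams()
    backbones: dict[str, list[Interval]] = {}
    if len(contigs) >= 2:
        backbones = find_backbone(
            contigs, p.backbone_min_identity, p.backbone_min_len,
            p.backbone_min_share, p.search,
        )
    out: list[MtContigClass] = []
    for contig in contigs:
        evidence: list[str] = []
        for mrna in mrna_set:
            for h in tdepleted_search(mrna, [contig], p.search):
                if len(h.s_ival) >= p.maxi_min_hit:
                    evidence.append(f"{mrna.id}:{h.s_ival.start}-{h.s_ival.end}{h.strand}")
        for rrna in rrna_set:
            for h in local_search(rrna, [contig], p.search):
                if len(h.s_ival) >= p.maxi_min_hit:
                    evidence.append(f"{rrna.id}:{h.s_ival.start}-{h.s_ival.end}{h.strand}")
        bb = tuple(backbones.get(contig.id, ()))
        circ, _ = (
            detect_circularity(contig, p.circ_min_overlap, p.circ_max_mismatch)
            if len(contig) > 2 * p.circ_min_overlap
            else (False, 0)
        )
        lo, hi = p.minicircle_len_range
        if evidence:
            label = MAXICIRCLE_LIKE
        elif bb and lo <= len(contig) <= hi:
            label = MINICIRCLE_LIKE
        else:
            label = UNCLASSIFIED
        out.append(MtContigClass(contig.id, label, tuple(evidence), circ, bb))
    return out


def find_backbone(
    contigs: Sequence[SeqRecord],
    min_identity: float = 0.90,
    min_len: int = 100,
    min_share: int = 2,
    search: SearchParams | None = None,
) -> dict[str, list[Interval]]:
    """Per-contig intervals shared (at >= min_identity over >= min_len) with
    at least ``min_share`` other contigs; overlapping evidence is merged."""
    if len(contigs) < 2:
        raise ValueError("find_backbone needs >= 2 contigs")
    search = search or SearchParams()
    sp = SearchParams(
        seed_len=search.seed_len, min_hit_len=min_len, min_identity=min_identity,
        xdrop=search.xdrop, max_hits=search.max_hits, band=search.band,
    )
    # partners[cid] = {other_id: set of supported positions on cid}; a
    # position is supported when it lies in a min_len-wide alignment window
    # at >= min_identity, so chance extensions into unrelated flanks do not
    # inflate the backbone while isolated private mutations do not break it
    partners: dict[str, dict[str, set[int]]] = {c.id: {} for c in contigs}
    for q in contigs:
        others = [s for s in contigs if s.id != q.id]
        for h in local_search(q, others, sp):
            subj_len = next(len(c) for c in contigs if c.id == h.subject_id)
            q_pos, s_pos = _supported_positions(h, subj_len, min_identity, min_len)
            partners[h.subject_id].setdefault(h.query_id, set()).update(s_pos)
            partners[h.query_id].setdefault(h.subject_id, set()).update(q_pos)
    out: dict[str, list[Interval]] = {}
    for contig in contigs:
        cov = [0] * (len(contig) + 1)
        for shared in partners[contig.id].values():
            for x in shared:
                cov[x] += 1
        ivals: list[Interval] = []
        start = None
        for x in range(len(contig) + 1):
            if x < len(contig) and cov[x] >= min_share:
                if start is None:
                    start = x
            elif start is not None:
                if x - start >= min_len:
                    ivals.append(Interval(contig.id, start, x))
                start = None
        out[contig.id] = ivals
    return out


def _supported_positions(
    h: HomologyHit, subj_len: int, min_identity: float, min_len: int
) -> tuple[set[int], set[int]]:
    """Query/subject positions inside a qualifying alignment window.

    A column qualifies when some short window (20 columns, the boundary
    resolution) containing it reaches ``min_identity``; the ``min_len``
    requirement is enforced on the emitted coverage runs.  Subject positions
    are mapped to the forward strand.
    """
    ops = h.ops
    n = len(ops)
    w = min(20, min_len)
    good = [False] * n
    if n >= w:
        pref = [0] * (n + 1)
        for i, op in enumerate(ops):
            pref[i + 1] = pref[i] + (op == "=")
        for a in range(0, n - w + 1):
            if pref[a + w] - pref[a] >= min_identity * w:
                for c in range(a, a + w):
                    good[c] = True
    q_pos: set[int] = set()
    s_off: set[int] = set()  # offset from hit start on the searched strand
    qpos, spos = h.q_ival.start, 0
    for i, op in enumerate(ops):
        if op in "=X":
            if good[i]:
                q_pos.add(qpos)
                s_off.add(spos)
            qpos += 1
            spos += 1
        elif op == "I":
            if good[i]:
                s_off.add(spos)
            spos += 1
        else:
            if good[i]:
                q_pos.add(qpos)
            qpos += 1
    if h.strand == "+":
        return q_pos, {h.s_ival.start + x for x in s_off}
    # '-' ops walk the rc subject from rc position subj_len - s_ival.end
    rc_start = subj_len - h.s_ival.end
    return q_pos, {subj_len - 1 - (rc_start + x) for x in s_off}


# ---------------------------------------------------------------------------
# Guide-RNA duplex detection

_WOBBLE_RC = {("C", "T"), ("A", "G")}  # rc(gRNA) char vs mRNA char for G:U pairs


def _pair_class(c: str, m: str, allow_wobble: bool) -> str:
    if c == m and c != "N":
        return "wc"
    if allow_wobble and (c, m) in _WOBBLE_RC:
        return "wobble"
    return "mm"


def find_grnas(
    minicircle: SeqRecord,
    edited_mrnas: Sequence[SeqRecord],
    params: GRnaParams | None = None,
) -> list[GRnaHit]:
    """Best-scoring antisense duplexes between a minicircle and edited mRNAs.

    Both minicircle strands are tried; the duplex is ungapped, seeded on
    exact Watson-Crick word matches and extended with x-drop under the
    wobble-aware scores.  Hits need duplex >= min_duplex, anchor >=
    min_anchor, mismatch fraction <= max_mismatch_frac; overlaps resolve to
    the best score.
    """
    p = params or GRnaParams()
    L = len(minicircle)
    raw: list[GRnaHit] = []
    for grna_strand in "+-":
        # rc of the gRNA-bearing strand is colinear with the mRNA sense
        c = revcomp(minicircle.seq) if grna_strand == "+" else minicircle.seq
        for mrna in edited_mrnas:
            for i0, i1, j0 in _duplex_segments(c, mrna.seq, p):
                seg_c = c[i0:i1]
                seg_m = mrna.seq[j0 : j0 + (i1 - i0)]
                tallies = [_pair_class(a, b, p.allow_wobble) for a, b in zip(seg_c, seg_m)]
                n_wc = tallies.count("wc")
                n_wob = tallies.count("wobble")
                n_mm = tallies.count("mm")
                dlen = len(tallies)
                if dlen < p.min_duplex or n_mm > p.max_mismatch_frac * dlen:
                    continue
                anchor = _longest_run(tallies, "wc")
                if anchor < p.min_anchor:
                    continue
                score = n_wc * p.wc_score + n_wob * p.wobble_score + n_mm * p.mismatch_pen
                if grna_strand == "+":
                    cass = Interval(minicircle.id, L - i1, L - i0, "+")
                else:
                    cass = Interval(minicircle.id, i0, i1, "-")
                raw.append(
                    GRnaHit(
                        minicircle.id, cass, mrna.id,
                        Interval(mrna.id, j0, j0 + dlen),
                        n_wc, n_wob, n_mm, anchor, score,
                    )
                )
    raw.sort(key=lambda h: (-h.score, h.mrna_id, h.cassette_ival.start))
    kept: list[GRnaHit] = []
    for h in raw:
        if any(
            h.cassette_ival.overlap(k.cassette_ival) > 0
            for k in kept
        ):
            continue
        kept.append(h)
    return kept


def _duplex_segments(c: str, m: str, p: GRnaParams):
    """Seed-and-extend ungapped segments of c vs m (WC = character equality)."""
    k = p.seed_len
    if len(c) < k or len(m) < k:
        return
    index: dict[str, list[int]] = {}
    for j in range(len(m) - k + 1):
        index.setdefault(m[j : j + k], []).append(j)
    done: set[tuple[int, int]] = set()  # (diag, start) de-dup
    for i in range(len(c) - k + 1):
        for j in index.get(c[i : i + k], ()):
            diag = i - j
            # extend left
            score = 0.0
            best_l, li = 0.0, i
            x, y = i - 1, j - 1
            while x >= 0 and y >= 0:
                cls = _pair_class(c[x], m[y], p.allow_wobble)
                score += {"wc": p.wc_score, "wobble": p.wobble_score, "mm": p.mismatch_pen}[cls]
                if score > best_l:
                    best_l, li = score, x
                if score < best_l - p.xdrop:
                    break
                x, y = x - 1, y - 1
            # extend right from seed end
            score = 0.0
            best_r, ri = 0.0, i + k
            x, y = i + k, j + k
            while x < len(c) and y < len(m):
                cls = _pair_class(c[x], m[y], p.allow_wobble)
                score += {"wc": p.wc_score, "wobble": p.wobble_score, "mm": p.mismatch_pen}[cls]
                if score > best_r:
                    best_r, ri = score, x + 1
                if score < best_r - p.xdrop:
                    break
                x, y = x + 1, y + 1
            key = (diag, li)
            if key in done:
                continue
            done.add(key)
            yield li, ri, li - diag


def _longest_run(tallies: list[str], kind: str) -> int:
    best = cur = 0
    for t in tallies:
        cur = cur + 1 if t == kind else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# Circular mapping


def detect_circularity(
    contig: SeqRecord, min_overlap: int = 50, max_mismatch: int = 2
) -> tuple[bool, int]:
    """Terminal self-overlap test for circular-mapping contigs.

    True iff a prefix of length >= min_overlap equals a suffix with at most
    ``max_mismatch`` substitutions; reports the longest such overlap.  This
    reports evidence of circularization only — an overlap can also be an
    assembly artifact.
    """
    n = len(contig)
    if n <= 2 * min_overlap:
        raise ValueError("contig too short for circularity test")
    seq = contig.seq
    for L in range(n // 2, min_overlap - 1, -1):
        mism = 0
        ok = True
        suffix_off = n - L
        for x in range(L):
            if seq[x] != seq[suffix_off + x]:
                mism += 1
                if mism > max_mismatch:
                    ok = False
                    break
        if ok:
            return True, L
    return False, 0
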