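"""Spliced-leader (SL) detection and degenerate stem-loop motif search.

Kinetoplastid nuclear mRNAs carry a short spliced leader added by
trans-splicing; the SL sequence differs between the organism of interest
and its prey, so the best-matching SL reference attributes a transcript to
TARGET or PREY (ties are AMBIGUOUS, never silently assigned).

The motif language is a minimal pattern grammar for rRNA landmark searches:
IUPAC literals with a mismatch budget, length-variable gaps, and paired
stems (Watson-Crick, optionally G:U, with a mispair budget), enough to
describe conserved stem-loops such as the 9S 530-loop and 12S A-loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .core_io import Interval, SeqRecord, revcomp

__all__ = [
    "SLRef",
    "SLCall",
    "detect_sl",
    "trim_sl",
    "sl_fraction",
    "Literal",
    "StemOpen",
    "Gap",
    "StemClose",
    "MotifPattern",
    "MotifHit",
    "PairingReport",
    "scan_motif",
    "compare_to_reference",
    "parse_pattern",
]

TARGET = "TARGET"
PREY = "PREY"
AMBIGUOUS = "AMBIGUOUS"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "T"), ("T", "G")}


# ---------------------------------------------------------------------------
# Spliced leaders


@dataclass(frozen=True)
class SLRef:
    name: str
    seq: str
    source: str  # TARGET or PREY

    def __post_init__(self) -> None:
        if len(self.seq) < 10:
            raise ValueError(f"SL reference {self.name!r} shorter than 10 nt")
        if self.source not in (TARGET, PREY):
            raise ValueError(f"SL reference source must be TARGET or PREY")


@dataclass(frozen=True)
class SLCall:
    transcript_id: str
    ref_name: str
    offset: int
    matched_len: int
    mismatches: int
    source: str


def detect_sl(
    transcript: SeqRecord,
    refs: Sequence[SLRef],
    max_mismatch: int = 1,
    min_suffix: int = 10,
    search_window: int = 40,
) -> Optional[SLCall]:
    """Best SL-suffix match within the transcript's 5' search window.

    Because trans-splicing joins the 3' end of the SL to the mRNA, a
    truncated transcript may retain only an SL *suffix*; every reference
    suffix of length >= ``min_suffix`` is tried at every offset within the
    first ``search_window`` nt.  Best = longest match, then fewest
    mismatches, then TARGET over PREY; a TARGET/PREY tie is AMBIGUOUS.
    """
    if not refs:
        raise ValueError("detect_sl: empty reference set")
    t = transcript.seq
    max_len = max(len(r.seq) for r in refs)
    for L in range(max_len, min_suffix - 1, -1):
        # candidates at this matched length: (mismatches, offset, ref index)
        cands: list[tuple[int, int, int]] = []
        for ri, ref in enumerate(refs):
            if len(ref.seq) < L:
                continue
            suf = ref.seq[-L:]
            for off in range(0, min(search_window, len(t) - L) + 1):
                if off + L > len(t):
                    break
                mism = 0
                ok = True
                for a, b in zip(t[off : off + L], suf):
                    if a != b:
                        mism += 1
                        if mism > max_mismatch:
                            ok = False
                            break
                if ok:
                    cands.append((mism, off, ri))
        if not cands:
            continue
        best_mism = min(c[0] for c in cands)
        best = [c for c in cands if c[0] == best_mism]
        sources = {refs[ri].source for _, _, ri in best}
        if sources == {TARGET, PREY}:
            mism, off, ri = min(best, key=lambda c: (c[1], c[2]))
            return SLCall(transcript.id, refs[ri].name, off, L, mism, AMBIGUOUS)
        order = {TARGET: 0, PREY: 1}
        mism, off, ri = min(best, key=lambda c: (order[refs[c[2]].source], c[1], c[2]))
        return SLCall(transcript.id, refs[ri].name, off, L, mism, refs[ri].source)
    return None


def trim_sl(transcript: SeqRecord, call: Optional[SLCall]) -> SeqRecord:
    """Remove a detected spliced leader (and anything 5' of it).

    The SL is trans-spliced, not genome-encoded, so trimming it before
    genome mapping prevents spurious extension into intergenic sequence.
    Returns the transcript unchanged when ``call`` is None or trimming
    would leave nothing.
    """
    if call is None:
        return transcript
    cut = call.offset + call.matched_len
    if cut >= len(transcript.seq):
        return transcript
    return SeqRecord(transcript.id, transcript.seq[cut:], transcript.description)


def sl_fraction(
    transcripts: Sequence[SeqRecord],
    refs: Sequence[SLRef],
    max_mismatch: int = 1,
    min_suffix: int = 10,
    search_window: int = 40,
) -> tuple[dict[str, tuple[int, float]], list[SLCall]]:
    """Counts and fractions of SL-positive transcripts per attribution class.

    Returns a {TARGET, PREY, AMBIGUOUS, NONE} -> (count, fraction) table
    partitioning the transcript set, plus the individual calls.
    """
    if not transcripts:
        raise ValueError("sl_fraction: empty transcript set")
    calls: list[SLCall] = []
    counts = {TARGET: 0, PREY: 0, AMBIGUOUS: 0, "NONE": 0}
    for t in transcripts:
        call = detect_sl(t, refs, max_mismatch, min_suffix, search_window)
        if call is None:
            counts["NONE"] += 1
        else:
            counts[call.source] += 1
            calls.append(call)
    n = len(transcripts)
    table = {k: (v, v / n) for k, v in counts.items()}
    return table, calls


# ---------------------------------------------------------------------------
# Motif pattern language


@dataclass(frozen=True)
class Literal:
    iupac: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        bad = set(self.iupac.upper()) - set(_IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters {bad}")


@dataclass(frozen=True)
class StemOpen:
    id: str
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("invalid stem length range")


@dataclass(frozen=True)
class Gap:
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.min_len <= self.max_len):
            raise ValueError("invalid gap length range")


@dataclass(frozen=True)
class StemClose:
    id: str
    max_mispair: int = 0
    allow_gu: bool = True


Element = Union[Literal, StemOpen, Gap, StemClose]


@dataclass(frozen=True)
class MotifPattern:
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        open_ids: set[str] = set()
        closed: set[str] = set()
        for el in self.elements:
            if isinstance(el, StemOpen):
                if el.id in open_ids:
                    raise ValueError(f"duplicate stem id {el.id!r}")
                open_ids.add(el.id)
            elif isinstance(el, StemClose):
                if el.id not in open_ids:
                    raise ValueError(f"STEM_CLOSE {el.id!r} has no prior STEM_OPEN")
                if el.id in closed:
                    raise ValueError(f"stem {el.id!r} closed twice")
                closed.add(el.id)
        if open_ids - closed:
            raise ValueError(f"unclosed stems: {open_ids - closed}")


@dataclass(frozen=True)
class MotifHit:
    """One pattern occurrence.  Intervals are per element, in the coordinates
    of the scanned strand (for '-' hits, positions on the reverse
    complement).  ``stem_pairs`` lists, per stem in close order, the
    (opening, closing) nucleotides column by column from the stem base."""

    seq_id: str
    strand: str
    ivals: tuple[Interval, ...]
    stem_pairs: tuple[tuple[tuple[str, str], ...], ...]
    n_identical_pairs: int = 0
    n_compensatory: int = 0

    @property
    def start(self) -> int:
        return self.ivals[0].start

    @property
    def end(self) -> int:
        return self.ivals[-1].end


@dataclass(frozen=True)
class PairingReport:
    n_identical: int
    n_compensatory: int


def _pairs(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _WC or (allow_gu and (a, b) in _GU)


def _match_literal(seq: str, pos: int, el: Literal) -> bool:
    lit = el.iupac.upper()
    if pos + len(lit) > len(seq):
        return False
    mism = 0
    for c, code in zip(seq[pos : pos + len(lit)], lit):
        if c not in _IUPAC[code]:
            mism += 1
            if mism > el.max_mismatch:
                return False
    return True


def _match_from(seq: str, pos: int, elements: tuple[Element, ...], idx: int,
                ivals: list[tuple[int, int]], stems: dict[str, tuple[int, int]]):
    """Backtracking matcher; returns the first (leftmost-shortest) full match."""
    if idx == len(elements):
        return list(ivals)
    el = elements[idx]
    if isinstance(el, Literal):
        if _match_literal(seq, pos, el):
            ivals.append((pos, pos + len(el.iupac)))
            res = _match_from(seq, pos + len(el.iupac), elements, idx + 1, ivals, stems)
            if res:
                return res
            ivals.pop()
        return None
    if isinstance(el, Gap):
        for L in range(el.min_len, el.max_len + 1):
            if pos + L > len(seq):
                break
            ivals.append((pos, pos + L))
            res = _match_from(seq, pos + L, elements, idx + 1, ivals, stems)
            if res:
                return res
            ivals.pop()
        return None
    if isinstance(el, StemOpen):
        for L in range(el.min_len, el.max_len + 1):
            if pos + L > len(seq):
                break
            stems[el.id] = (pos, pos + L)
            ivals.append((pos, pos + L))
            res = _match_from(seq, pos + L, elements, idx + 1, ivals, stems)
            if res:
                return res
            ivals.pop()
            del stems[el.id]
        return None
    # StemClose: length fixed by the opener; columns pair reverse-wise
    o0, o1 = stems[el.id]
    L = o1 - o0
    if pos + L > len(seq):
        return None
    mispair = 0
    for t in range(L):
        if not _pairs(seq[o0 + t], seq[pos + L - 1 - t], el.allow_gu):
            mispair += 1
            if mispair > el.max_mispair:
                return None
    ivals.append((pos, pos + L))
    res = _match_from(seq, pos + L, elements, idx + 1, ivals, stems)
    if res:
        return res
    ivals.pop()
    return None


def scan_motif(seq: SeqRecord, pattern: MotifPattern) -> list[MotifHit]:
    """All non-overlapping pattern occurrences on both strands.

    Scans left to right per strand taking the leftmost (then shortest)
    match, then resumes past it.
    """
    hits: list[MotifHit] = []
    for strand in "+-":
        s = seq.seq if strand == "+" else revcomp(seq.seq)
        pos = 0
        while pos < len(s):
            found = None
            for start in range(pos, len(s)):
                stems: dict[str, tuple[int, int]] = {}
                res = _match_from(s, start, pattern.elements, 0, [], stems)
                if res:
                    found = (start, res, dict(stems))
                    break
            if not found:
                break
            start, ivals, stems = found
            hit_ivals = tuple(
                Interval(seq.id, a, b, strand) if b > a else Interval(seq.id, a, a + 1, strand)
                for (a, b) in ivals
                if b > a  # zero-length gaps carry no interval
            )
            stem_pairs = []
            for idx, el in enumerate(pattern.elements):
                if isinstance(el, StemClose):
                    o0, o1 = stems[el.id]
                    c0, c1 = ivals[idx]
                    L = o1 - o0
                    stem_pairs.append(
                        tuple((s[o0 + t], s[c1 - 1 - t]) for t in range(L))
                    )
            hits.append(MotifHit(seq.id, strand, hit_ivals, tuple(stem_pairs)))
            pos = ivals[-1][1] if ivals[-1][1] > start else start + 1
    return hits


def compare_to_reference(
    hit: MotifHit, reference_pairs: Sequence[tuple[str, str]],
    allow_gu: bool = True,
) -> PairingReport:
    """Count identical vs compensatory stem columns against a reference.

    A column is *compensatory* when both structures pair there but with
    different nucleotide pairs; *identical* when the pairs agree.  Tolerated
    mispairs count as neither.
    """
    hit_cols = [p for stem in hit.stem_pairs for p in stem]
    if len(hit_cols) != len(reference_pairs):
        raise ValueError(
            f"stem length mismatch: hit has {len(hit_cols)} paired columns, "
            f"reference {len(reference_pairs)}"
        )
    n_id = n_comp = 0
    for (ha, hb), (ra, rb) in zip(hit_cols, reference_pairs):
        hp = _pairs(ha, hb, allow_gu)
        rp = _pairs(ra.upper().replace("U", "T"), rb.upper().replace("U", "T"), allow_gu)
        if hp and rp:
            if (ha, hb) == (ra.upper().replace("U", "T"), rb.upper().replace("U", "T")):
                n_id += 1
            else:
                n_comp += 1
    return PairingReport(n_id, n_comp)


def parse_pattern(text: str) -> MotifPattern:
    """Parse the one-element-per-line plain-text pattern format.

    ::

        LITERAL ACGT 1
        STEM_OPEN s1 4 6
        GAP 3 8
        STEM_CLOSE s1 1 GU

    The trailing STEM_CLOSE token is ``GU`` (allow G:U, default) or ``NOGU``.
    Blank lines and ``#`` comments are ignored.
    """
    elements: list[Element] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        try:
            kind = tok[0].upper()
            if kind == "LITERAL":
                elements.append(Literal(tok[1], int(tok[2]) if len(tok) > 2 else 0))
            elif kind == "STEM_OPEN":
                elements.append(StemOpen(tok[1], int(tok[2]), int(tok[3])))
            elif kind == "GAP":
                elements.append(Gap(int(tok[1]), int(tok[2])))
            elif kind == "STEM_CLOSE":
                allow_gu = True
                if len(tok) > 3:
                    allow_gu = tok[3].upper() != "NOGU"
                elements.append(StemClose(tok[1], int(tok[2]) if len(tok) > 2 else 0, allow_gu))
            else:
                raise ValueError(f"unknown element {tok[0]!r}")
        except (IndexError, ValueError) as exc:
            raise ValueError(f"pattern line {lineno}: {raw!r}: {exc}") from exc
    return MotifPattern(tuple(elements))
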