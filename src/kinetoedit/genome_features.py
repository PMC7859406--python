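"""Prey decontamination, transcript-to-genome mapping and gene polarity.

Free-living prokinetoplastids are grown on eukaryotic prey whose sequences
contaminate the assemblies.  A genomic contig counts as contaminant when it
shares >= 93% identity with a prey transcript over >= 100 aligned bp (both
thresholds inclusive; identity = matches / alignment columns, gaps
included).  Mapped transcripts then give per-contig gene order, strand
bias (polycistron-like same-strand clusters) and intergenic distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .core_io import Interval, SeqRecord
from .depletion import HomologyHit, SearchParams, local_search

__all__ = [
    "DecontamParams",
    "PreyFlag",
    "TranscriptMapping",
    "ContigAnnotation",
    "flag_prey_contigs",
    "map_transcripts",
    "polarity_report",
]


@dataclass(frozen=True)
class DecontamParams:
    min_identity: float = 0.93
    min_len: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True)
class PreyFlag:
    contig_id: str
    flagged: bool
    evidence: Optional[HomologyHit] = None


@dataclass(frozen=True)
class TranscriptMapping:
    transcript_id: str
    contig_id: str
    t_ival: Interval
    c_ival: Interval
    strand: str
    identity: float
    coverage: float


@dataclass(frozen=True)
class ContigAnnotation:
    contig_id: str
    genes: tuple[tuple[str, Interval, str], ...]
    same_strand_fraction: float
    strand_runs: tuple[int, ...]
    intergenic: tuple[int, ...]
    mean_intergenic: float
    n_overlapping: int = 0  # gene pairs whose spacing was clipped to 0


def _has_qualifying_window(ops: str, min_identity: float, min_len: int) -> bool:
    """Does any contiguous run of alignment columns of length >= min_len have
    identity >= min_identity?  Thresholds inclusive."""
    n = len(ops)
    if n < min_len:
        return False
    pref = [0] * (n + 1)
    for i, op in enumerate(ops):
        pref[i + 1] = pref[i] + (1 if op == "=" else 0)
    for a in range(0, n - min_len + 1):
        for b in range(a + min_len, n + 1):
            if pref[b] - pref[a] >= min_identity * (b - a):
                return True
            # once a window starting at `a` fails, longer windows can still
            # pass, so no early break on b
    return False


def flag_prey_contigs(
    contigs: Sequence[SeqRecord],
    prey_refs: Sequence[SeqRecord],
    params: DecontamParams | None = None,
) -> list[PreyFlag]:
    """Flag contigs with prey similarity >= min_identity over >= min_len bp.

    A contig is flagged iff any local alignment against any prey reference
    contains a contiguous stretch of >= min_len columns at >= min_identity.
    """
    if not prey_refs:
        raise ValueError("flag_prey_contigs: empty prey reference set")
    p = params or DecontamParams()
    # decide on exact windows of the alignment; scoring mirrors megablast
    # ratios (+1/-2, gaps -4/-2) so that chance flank extensions below
    # ~2/3 identity score negative and never attach to a planted segment
    sp = SearchParams(
        min_hit_len=p.min_len,
        min_identity=max(0.5, p.min_identity - 0.15),
        match=1, mismatch=-2, gap_open=-4, gap_ext=-2,
    )
    out: list[PreyFlag] = []
    for contig in contigs:
        best: Optional[HomologyHit] = None
        for prey in prey_refs:
            for h in local_search(prey, [contig], sp):
                if _has_qualifying_window(h.ops, p.min_identity, p.min_len):
                    if best is None or h.score > best.score:
                        best = h
        out.append(PreyFlag(contig.id, best is not None, best))
    return out


def map_transcripts(
    transcripts: Sequence[SeqRecord],
    contigs: Sequence[SeqRecord],
    min_identity: float = 0.90,
    min_len: int = 50,
) -> tuple[list[TranscriptMapping], float]:
    """Map transcripts to genomic contigs, unspliced, best hit per locus.

    Returns the mappings plus the fraction of transcripts with at least one
    mapping.  Coverage is the aligned fraction of the transcript.
    """
    if not transcripts or not contigs:
        raise ValueError("map_transcripts: empty input")
    sp = SearchParams(min_hit_len=min_len, min_identity=min_identity)
    mappings: list[TranscriptMapping] = []
    n_mapped = 0
    for t in transcripts:
        hits = local_search(t, contigs, sp)
        if hits:
            n_mapped += 1
        for h in hits:
            mappings.append(
                TranscriptMapping(
                    t.id, h.subject_id, h.q_ival, h.s_ival, h.strand,
                    h.identity, len(h.q_ival) / len(t),
                )
            )
    return mappings, n_mapped / len(transcripts)


def polarity_report(mappings: Sequence[TranscriptMapping]) -> list[ContigAnnotation]:
    """Per-contig gene order, strand runs and intergenic spacing.

    Genes are mapped transcripts ordered by start; intergenic distance is
    next.start − prev.end, clipped to 0 (and counted) for overlapping
    mappings; same_strand_fraction is the majority strand share.
    """
    if not mappings:
        raise ValueError("polarity_report: no mappings")
    by_contig: dict[str, list[TranscriptMapping]] = {}
    for m in mappings:
        by_contig.setdefault(m.contig_id, []).append(m)
    out: list[ContigAnnotation] = []
    for contig_id in sorted(by_contig):
        ms = sorted(by_contig[contig_id], key=lambda m: (m.c_ival.start, m.c_ival.end))
        genes = tuple((m.transcript_id, m.c_ival, m.strand) for m in ms)
        strands = [m.strand for m in ms]
        n = len(ms)
        same = max(strands.count("+"), strands.count("-")) / n
        runs: list[int] = []
        for s in strands:
            if runs and s == last:
                runs[-1] += 1
            else:
                runs.append(1)
            last = s
        inter: list[int] = []
        n_overlap = 0
        for a, b in zip(ms, ms[1:]):
            d = b.c_ival.start - a.c_ival.end
            if d < 0:
                d = 0
                n_overlap += 1
            inter.append(d)
        mean_inter = sum(inter) / len(inter) if inter else 0.0
        out.append(
            ContigAnnotation(
                contig_id, genes, same, tuple(runs), tuple(inter), mean_inter, n_overlap
            )
        )
    return out
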