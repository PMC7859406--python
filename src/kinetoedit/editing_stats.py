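"""Quantitative summaries of reconstructed editing.

Turns edit-event lists into the per-transcript and species-level numbers of
interest: U-insertion/deletion counts, percent length expansion of the
mature mRNA over its cryptogene, an editing-pattern class (pan-edited vs
terminally edited), clustered deaminative (C→U / A→I) edits, and whether a
stop codon was created by editing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio.Data import CodonTable

from .core_io import Interval
from .editing import A_TO_I, C_TO_U, U_DEL, U_INS, EditEvent, EditingAlignment

logger = logging.getLogger("kinetoedit")

__all__ = [
    "EditingStats",
    "DeaminativeCluster",
    "SpeciesSummary",
    "summarize_editing",
    "classify_pattern",
    "detect_deaminative_clusters",
    "stop_created_by_editing",
    "aggregate",
]

UNEDITED = "UNEDITED"
FIVE_PRIME = "FIVE_PRIME"
FIVE_AND_THREE_PRIME = "FIVE_AND_THREE_PRIME"
PAN = "PAN"


@dataclass(frozen=True)
class EditingStats:
    gene_id: str
    gene_len: int
    n_ins: int
    n_del: int
    pct_expansion: float
    n_c_to_u: int
    n_a_to_i: int
    pattern: str
    stop_created_by_editing: bool


@dataclass(frozen=True)
class DeaminativeCluster:
    seq_id: str
    span: Interval
    n_edits: int
    n_c_to_u: int
    n_a_to_i: int

    def __post_init__(self) -> None:
        assert self.n_edits == self.n_c_to_u + self.n_a_to_i


@dataclass(frozen=True)
class SpeciesSummary:
    n_genes: int
    mean_ins: float
    min_ins: int
    max_ins: int
    mean_del: float
    min_del: int
    max_del: int
    mean_pct_expansion: float
    min_pct_expansion: float
    max_pct_expansion: float


def classify_pattern(
    events: Sequence[EditEvent],
    gene_len: int,
    window_frac: float = 0.25,
    density_min: float = 1.0,
    n_bins: int = 20,
    pan_frac: float = 0.70,
) -> str:
    """Classify the spatial editing pattern along a gene.

    The gene is split into ``n_bins`` equal bins; a bin is *edited* when it
    holds at least ``density_min`` edit sites.  Fewer than 3 sites in total
    is UNEDITED; edited bins confined to the first ``window_frac`` of the
    gene is FIVE_PRIME; confined to the first and last ``window_frac`` is
    FIVE_AND_THREE_PRIME; anything more dispersed is PAN (which always holds
    when edited bins cover >= ``pan_frac`` of bins).

    Event positions must be 0-based relative to the gene span of length
    ``gene_len``.
    """
    if gene_len <= 0:
        raise ValueError("gene_len must be positive")
    sites = [e.gene_pos for e in events]
    if len(sites) < 3:
        return UNEDITED
    counts = [0] * n_bins
    for pos in sites:
        b = min(n_bins - 1, pos * n_bins // gene_len)
        counts[b] += 1
    edited = [b for b, c in enumerate(counts) if c >= density_min]
    if not edited:
        return UNEDITED
    head = max(1, int(round(window_frac * n_bins)))
    in_head = [b for b in edited if b < head]
    in_tail = [b for b in edited if b >= n_bins - head]
    if len(in_head) == len(edited):
        return FIVE_PRIME
    if len(in_head) + len(in_tail) == len(edited):
        return FIVE_AND_THREE_PRIME
    return PAN


def _relative_events(aln: EditingAlignment) -> list[EditEvent]:
    off = aln.gene_ival.start
    return [
        EditEvent(e.kind, e.gene_pos - off, e.mrna_pos, e.run_len) for e in aln.events
    ]


def summarize_editing(
    aln: EditingAlignment, code: int = 4, frame_start: int = 0
) -> EditingStats:
    """Per-transcript editing statistics for one gene/mRNA alignment.

    ``pct_expansion`` is 100·(n_ins − n_del)/gene_len with the aligned
    gene-region length as denominator.
    """
    gene_len = len(aln.gene_ival)
    if gene_len == 0:
        raise ValueError("gene_len is zero")
    pct = 100.0 * (aln.n_ins - aln.n_del) / gene_len
    stop = False
    if len(aln.mrna_seq) >= frame_start + 3:
        stop = stop_created_by_editing(aln, code, frame_start)
    return EditingStats(
        gene_id=aln.gene_id,
        gene_len=gene_len,
        n_ins=aln.n_ins,
        n_del=aln.n_del,
        pct_expansion=pct,
        n_c_to_u=aln.n_c_to_u,
        n_a_to_i=aln.n_a_to_i,
        pattern=classify_pattern(_relative_events(aln), gene_len),
        stop_created_by_editing=stop,
    )


def detect_deaminative_clusters(
    events: Sequence[EditEvent],
    window: int = 30,
    min_edits: int = 3,
    seq_id: str = "",
) -> list[DeaminativeCluster]:
    """Maximal groups of deaminative edits with consecutive spacing <= window.

    Only substitution events (C→U, A→I) are considered; groups smaller than
    ``min_edits`` are dropped.  Spans are tight (first to last edit site,
    half-open).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    subs = sorted(
        (e for e in events if e.kind in (C_TO_U, A_TO_I)), key=lambda e: e.gene_pos
    )
    clusters: list[DeaminativeCluster] = []
    group: list[EditEvent] = []
    for e in subs:
        if group and e.gene_pos - group[-1].gene_pos > window:
            clusters.extend(_emit(group, min_edits, seq_id))
            group = []
        group.append(e)
    clusters.extend(_emit(group, min_edits, seq_id))
    return clusters


def _emit(group: list[EditEvent], min_edits: int, seq_id: str) -> list[DeaminativeCluster]:
    if len(group) < min_edits:
        return []
    n_c = sum(1 for e in group if e.kind == C_TO_U)
    n_a = sum(1 for e in group if e.kind == A_TO_I)
    return [
        DeaminativeCluster(
            seq_id,
            Interval(seq_id or "?", group[0].gene_pos, group[-1].gene_pos + 1),
            len(group),
            n_c,
            n_a,
        )
    ]


def stop_created_by_editing(
    aln: EditingAlignment, code: int = 4, frame_start: int = 0
) -> bool:
    """Was the first in-frame stop codon of the edited mRNA created by editing?

    Translates the mRNA in the given frame under NCBI translation table
    ``code`` (default 4, where TGA reads as Trp, as in kinetoplastid
    mitochondria).  True iff the first in-frame stop overlaps at least one
    inserted-U position, or a U deletion falls inside the codon.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[code]
    except KeyError as exc:
        raise ValueError(f"unknown genetic code id {code}") from exc
    mrna = aln.mrna_seq
    if len(mrna) < frame_start + 3:
        raise ValueError("mRNA shorter than one codon in the given frame")
    stop_codons = set(table.stop_codons)
    stop_at = None
    for s in range(frame_start, len(mrna) - 2, 3):
        if mrna[s : s + 3] in stop_codons:
            stop_at = s
            break
    if stop_at is None:
        logger.warning(
            "stop_created_by_editing(%s/%s): no in-frame stop under code %d",
            aln.gene_id, aln.mrna_id, code,
        )
        return False
    inserted: set[int] = set()
    del_bounds: set[int] = set()  # mRNA boundary indices carrying a deletion
    for e in aln.events:
        if e.kind == U_INS:
            inserted.update(range(e.mrna_pos, e.mrna_pos + e.run_len))
        elif e.kind == U_DEL:
            del_bounds.add(e.mrna_pos)
    codon = range(stop_at, stop_at + 3)
    if any(pos in inserted for pos in codon):
        return True
    return any(stop_at < b < stop_at + 3 for b in del_bounds)


def aggregate(stats: Sequence[EditingStats]) -> SpeciesSummary:
    """Arithmetic means and ranges over a set of per-gene statistics."""
    if not stats:
        raise ValueError("aggregate: empty stats list")
    ins = [s.n_ins for s in stats]
    dels = [s.n_del for s in stats]
    pct = [s.pct_expansion for s in stats]
    n = len(stats)
    return SpeciesSummary(
        n_genes=n,
        mean_ins=sum(ins) / n, min_ins=min(ins), max_ins=max(ins),
        mean_del=sum(dels) / n, min_del=min(dels), max_del=max(dels),
        mean_pct_expansion=sum(pct) / n,
        min_pct_expansion=min(pct), max_pct_expansion=max(pct),
    )
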