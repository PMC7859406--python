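"""Seeded generator of prokinetoplastid-like synthetic data with ground truth.

Emulates the statistical structure the analysis modules assume: maxicircle
contigs carrying cryptogenes whose mature mRNAs are expanded by extensive
U-insertion (and some U-deletion) editing, minicircles built from a shared
backbone plus ~85 bp gRNA cassettes antisense (with G:U wobble) to edited
mRNA blocks, nuclear contigs with same-strand gene clusters and short
intergenic gaps, spliced-leader-bearing transcripts at a configured
fraction, and prey-like contaminant segments at controlled identity.

Ground truth is recorded for every simulated feature, enabling exact
parameter-recovery tests: applying a gene's truth events to its cryptogene
reproduces its mature mRNA byte for byte, and indel events are placed so
that the optimal constrained alignment cannot trade an insertion/deletion
pair away (no insertion run is allowed inside or immediately adjacent to
the gene T-run containing a deletion, gene termini are non-T and
event-free).  Identical parameters and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .core_io import Interval, SeqRecord, revcomp, write_fasta, write_table
from .editing import A_TO_I, C_TO_U, U_DEL, U_INS, EditEvent, apply_events
from .editing_stats import FIVE_AND_THREE_PRIME, FIVE_PRIME, PAN, UNEDITED

__all__ = [
    "SimParams",
    "SimBundle",
    "simulate_mt",
    "simulate_nuclear",
    "simulate_contamination",
    "simulate_all",
    "ankaliazontas_like",
    "spiralis_like",
]

#: the prokinetoplastid-specific spliced-leader region sequence
SL_DEFAULT = "TTACAGTTTCTGTACTT"


@dataclass(frozen=True)
class SimParams:
    """Generator knobs; presets mirror the two study species.

    ``ins_per_gene`` / ``del_per_gene`` are (mean, min, max) per-transcript
    totals; per-gene insertion totals are derived from a target length
    expansion consistent with the means, then clipped to [min, max].
    """

    n_genes: int = 14
    gene_len_range: tuple[int, int] = (380, 570)
    ins_per_gene: tuple[float, int, int] = (389.0, 166, 885)
    del_per_gene: tuple[float, int, int] = (29.0, 13, 49)
    ins_run_geom_p: float = 0.5
    deam_cluster: Optional[tuple[int, int, int]] = (8, 4, 30)  # (C->U, A->I, span)
    pattern_mix: tuple[tuple[str, float], ...] = ((PAN, 0.85), (FIVE_AND_THREE_PRIME, 0.15))
    n_minicircles: int = 10
    minicircle_len_range: tuple[int, int] = (550, 650)
    cassette_len: int = 85
    wobble_frac: float = 0.05
    maxi_backbone_len: int = 400
    spacer_len: int = 150
    circular_overlap: int = 120
    n_nuclear_contigs: int = 2
    genes_per_contig: int = 15
    nuclear_gene_len_range: tuple[int, int] = (300, 800)
    intergenic_mean: int = 76
    intergenic_jitter: bool = False
    sl_fraction: float = 0.70
    sl_seq: str = SL_DEFAULT
    prey: tuple[int, float, int] = (5, 0.95, 120)  # (n_contigs, identity, seg_len)
    gc: float = 0.5
    seed: int = 42


@dataclass
class SimBundle:
    """Simulated sequences plus ground-truth tables."""

    params: SimParams
    maxicircles: list[SeqRecord] = field(default_factory=list)
    minicircles: list[SeqRecord] = field(default_factory=list)
    nuclear_contigs: list[SeqRecord] = field(default_factory=list)
    mt_mrnas: list[SeqRecord] = field(default_factory=list)
    rrna_transcripts: list[SeqRecord] = field(default_factory=list)
    nuclear_transcripts: list[SeqRecord] = field(default_factory=list)
    prey_contigs: list[SeqRecord] = field(default_factory=list)
    contaminated_contigs: list[SeqRecord] = field(default_factory=list)
    # truth
    edit_events: dict[str, list[EditEvent]] = field(default_factory=dict)
    gene_seqs: dict[str, str] = field(default_factory=dict)
    gene_regions: dict[str, tuple[str, Interval]] = field(default_factory=dict)
    gene_patterns: dict[str, str] = field(default_factory=dict)
    cassettes: list[dict] = field(default_factory=list)
    sl_ids: set[str] = field(default_factory=set)
    contaminant_ids: set[str] = field(default_factory=set)
    nuclear_genes: dict[str, list[tuple[str, Interval, str]]] = field(default_factory=dict)

    def truth_n_ins(self, gene_id: str) -> int:
        return sum(e.run_len for e in self.edit_events[gene_id] if e.kind == U_INS)

    def truth_n_del(self, gene_id: str) -> int:
        return sum(e.run_len for e in self.edit_events[gene_id] if e.kind == U_DEL)

    def merge(self, other: "SimBundle") -> "SimBundle":
        for name in (
            "maxicircles", "minicircles", "nuclear_contigs", "mt_mrnas",
            "rrna_transcripts", "nuclear_transcripts", "prey_contigs",
            "contaminated_contigs", "cassettes",
        ):
            getattr(self, name).extend(getattr(other, name))
        for name in ("edit_events", "gene_seqs", "gene_regions", "gene_patterns", "nuclear_genes"):
            getattr(self, name).update(getattr(other, name))
        self.sl_ids |= other.sl_ids
        self.contaminant_ids |= other.contaminant_ids
        return self

    def write(self, outdir: str | Path) -> None:
        """Write FASTA sets, truth TSVs and a params echo to a directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fasta_sets = {
            "maxicircles": self.maxicircles,
            "minicircles": self.minicircles,
            "nuclear_contigs": self.nuclear_contigs,
            "mt_mrnas": self.mt_mrnas,
            "rrna_transcripts": self.rrna_transcripts,
            "nuclear_transcripts": self.nuclear_transcripts,
            "prey_contigs": self.prey_contigs,
            "contaminated_contigs": self.contaminated_contigs,
        }
        for name, recs in fasta_sets.items():
            if recs:
                write_fasta(recs, out / f"{name}.fasta")
        rows = []
        for gid, events in sorted(self.edit_events.items()):
            for e in events:
                rows.append(
                    {"gene_id": gid, "kind": e.kind, "gene_pos": e.gene_pos,
                     "mrna_pos": e.mrna_pos, "run_len": e.run_len}
                )
        write_table(rows, out / "truth_edit_events.tsv",
                    ["gene_id", "kind", "gene_pos", "mrna_pos", "run_len"])
        write_table(
            [
                {"gene_id": gid, "contig_id": cid, "start": iv.start, "end": iv.end,
                 "strand": iv.strand, "pattern": self.gene_patterns.get(gid, "")}
                for gid, (cid, iv) in sorted(self.gene_regions.items())
            ],
            out / "truth_gene_regions.tsv",
            ["gene_id", "contig_id", "start", "end", "strand", "pattern"],
        )
        write_table(
            [
                {"minicircle_id": c["minicircle_id"], "start": c["ival"].start,
                 "end": c["ival"].end, "strand": c["ival"].strand,
                 "mrna_id": c["mrna_id"], "mrna_start": c["mrna_ival"].start,
                 "mrna_end": c["mrna_ival"].end, "n_wobble": c["n_wobble"]}
                for c in self.cassettes
            ],
            out / "truth_cassettes.tsv",
            ["minicircle_id", "start", "end", "strand", "mrna_id",
             "mrna_start", "mrna_end", "n_wobble"],
        )
        write_table(
            [{"transcript_id": t} for t in sorted(self.sl_ids)],
            out / "truth_sl_ids.tsv", ["transcript_id"],
        )
        write_table(
            [{"contig_id": c} for c in sorted(self.contaminant_ids)],
            out / "truth_contaminants.tsv", ["contig_id"],
        )
        nrows = []
        for cid, genes in sorted(self.nuclear_genes.items()):
            for gid, iv, strand in genes:
                nrows.append({"contig_id": cid, "gene_id": gid, "start": iv.start,
                              "end": iv.end, "strand": strand})
        write_table(nrows, out / "truth_nuclear_genes.tsv",
                    ["contig_id", "gene_id", "start", "end", "strand"])
        with open(out / "params.txt", "w") as fh:
            for k, v in vars(self.params).items():
                fh.write(f"{k} = {v!r}\n")


def ankaliazontas_like(seed: int = 42, **overrides) -> SimParams:
    """Pan-editing-dominant preset (large U-insertion load, ~1.3-2.2 kb
    minicircles are also seen in this species; the default compact size is
    kept for desk-scale runs unless overridden)."""
    return replace(SimParams(seed=seed), **overrides)


def spiralis_like(seed: int = 42, **overrides) -> SimParams:
    """Terminal-editing-dominant preset with ~600 bp minicircles."""
    base = SimParams(
        ins_per_gene=(166.0, 19, 331),
        del_per_gene=(43.0, 17, 80),
        gene_len_range=(380, 570),
        pattern_mix=((FIVE_PRIME, 0.3), (FIVE_AND_THREE_PRIME, 0.4), (PAN, 0.3)),
        deam_cluster=None,
        minicircle_len_range=(550, 650),
        sl_fraction=0.58,
        circular_overlap=0,
        seed=seed,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# helpers

_BASES = np.array(list("ACGT"))


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=p))


def _spacer(rng: np.random.Generator, n: int, gc: float, guard: int = 60) -> str:
    """Intergenic spacer whose ``guard`` terminal bases are T-free.

    The guard bands prevent a chance run of spacer T's adjacent to a gene
    from absorbing a terminal insertion run during alignment, which would
    make truth counts unrecoverable for reasons unrelated to the aligner.
    """
    g = min(guard, n // 2)
    p3 = [(1 - gc) / 2, gc / 2, gc / 2]
    ends1 = "".join(rng.choice(_BASES[:3], size=g, p=np.array(p3) / sum(p3)))
    ends2 = "".join(rng.choice(_BASES[:3], size=g, p=np.array(p3) / sum(p3)))
    mid = _rand_seq(rng, n - 2 * g, gc)
    return ends1 + mid + ends2


def _clipped_int(rng: np.random.Generator, mean: float, lo: int, hi: int) -> int:
    """Integer draw on [lo, hi] whose expectation tracks ``mean`` (scaled
    Beta with matched first moment)."""
    if hi <= lo:
        return lo
    frac = min(1.0, max(0.0, (mean - lo) / (hi - lo)))
    k = 4.0
    a = max(1e-3, k * frac)
    b = max(1e-3, k * (1 - frac))
    return int(round(lo + (hi - lo) * rng.beta(a, b)))


def _pattern_pool(pattern: str, L: int) -> list[int]:
    """Interior gene positions eligible for edit events under a pattern."""
    lo, hi = 2, L - 1  # insertion anchors; deletions additionally need a T
    head = range(lo, max(lo + 1, L // 4))
    tail = range(max(lo, 3 * L // 4), hi + 1)
    if pattern == FIVE_PRIME:
        return list(head)
    if pattern == FIVE_AND_THREE_PRIME:
        return sorted(set(head) | set(tail))
    if pattern == UNEDITED:
        return []
    return list(range(lo, hi + 1))


def _trun(gene: str, d: int) -> tuple[int, int]:
    """Bounds [t0, t1] of the maximal T-run containing position d."""
    t0 = t1 = d
    while t0 > 0 and gene[t0 - 1] == "T":
        t0 -= 1
    while t1 < len(gene) - 1 and gene[t1 + 1] == "T":
        t1 += 1
    return t0, t1


def _make_gene(
    rng: np.random.Generator, p: SimParams, pattern: str, gene_id: str
) -> tuple[str, list[EditEvent]]:
    """One cryptogene and its truth event list (recovery-safe placement)."""
    L = int(rng.integers(p.gene_len_range[0], p.gene_len_range[1] + 1))
    seq = list(_rand_seq(rng, L, p.gc))
    non_t = "ACG"
    for i in (0, 1, L - 2, L - 1):  # non-T, event-free termini anchor the DP
        if seq[i] == "T":
            seq[i] = non_t[int(rng.integers(3))]
    gene = "".join(seq)

    if pattern == UNEDITED:
        return gene, []

    ins_mean, ins_lo, ins_hi = p.ins_per_gene
    del_mean, del_lo, del_hi = p.del_per_gene
    mean_len = (p.gene_len_range[0] + p.gene_len_range[1]) / 2
    exp_mean = max(0.05, (ins_mean - del_mean) / mean_len)
    expansion = exp_mean * (0.6 + 0.8 * rng.random())  # ±40% around the mean
    n_del = _clipped_int(rng, del_mean, del_lo, del_hi)
    n_ins = int(round(expansion * L)) + n_del
    n_ins = min(max(n_ins, ins_lo), ins_hi)

    pool = _pattern_pool(pattern, L)
    del_pool = [i for i in pool if gene[i] == "T" and 2 <= i <= L - 3]
    if len(del_pool) < n_del:  # fall back to any interior T
        del_pool = sorted(set(del_pool) | {
            i for i in range(2, L - 2) if gene[i] == "T"
        })
    if len(del_pool) < n_del:
        raise ValueError(
            f"gene {gene_id}: cannot place {n_del} deletions "
            f"({len(del_pool)} eligible T positions)"
        )
    del_pos = sorted(int(x) for x in rng.choice(del_pool, size=n_del, replace=False))

    forbidden: set[int] = set()
    for d in del_pos:
        t0, t1 = _trun(gene, d)
        # anchors in or adjacent to the deletion's T-run could absorb the
        # deleted U; a ±2 margin also blocks compound restructurings where
        # the optimum trades an interleaved del/ins pair for a substitution
        forbidden.update(range(t0 - 2, t1 + 3))
    anchor_pool = [a for a in pool if a not in forbidden]
    if not anchor_pool:
        raise ValueError(f"gene {gene_id}: no insertion anchors available")
    mean_run = 1.0 / p.ins_run_geom_p
    want = int(max(1, round(n_ins / mean_run)))
    # anchors at least 2 apart: a single aligned gene character between two
    # runs can be re-attributed by the DP, merging the runs and changing
    # the run/count bookkeeping; two characters cannot
    order = rng.permutation(len(anchor_pool))
    anchors = []
    for idx in order:
        a = anchor_pool[int(idx)]
        if all(abs(a - b) >= 2 for b in anchors):
            anchors.append(a)
            if len(anchors) >= want:
                break
    anchors.sort()
    n_runs = len(anchors)
    run_len = [1] * n_runs
    for _ in range(n_ins - n_runs):
        run_len[int(rng.integers(n_runs))] += 1

    events = [EditEvent(U_DEL, d, 0, 1) for d in del_pos]
    events += [EditEvent(U_INS, a, 0, rl) for a, rl in zip(anchors, run_len)]
    events.sort(key=lambda e: e.gene_pos)
    return gene, _fix_mrna_pos(gene, events)


def _fix_mrna_pos(gene: str, events: list[EditEvent]) -> list[EditEvent]:
    """Recompute mRNA coordinates of truth events by replaying them."""
    out: list[EditEvent] = []
    j = 0  # mrna cursor
    i = 0
    by_pos: dict[int, list[EditEvent]] = {}
    for e in events:
        by_pos.setdefault(e.gene_pos, []).append(e)
    for i in range(len(gene) + 1):
        here = by_pos.get(i, [])
        for e in here:
            if e.kind == U_INS:
                out.append(EditEvent(U_INS, i, j, e.run_len))
                j += e.run_len
        deleted = any(e.kind == U_DEL for e in here)
        subbed = [e for e in here if e.kind in (C_TO_U, A_TO_I)]
        if i < len(gene):
            if deleted:
                out.append(EditEvent(U_DEL, i, j, 1))
            else:
                for e in subbed:
                    out.append(EditEvent(e.kind, i, j))
                j += 1
    out.sort(key=lambda e: (e.gene_pos, e.mrna_pos))
    return out


# ---------------------------------------------------------------------------
# mitochondrial simulation


def simulate_mt(params: SimParams) -> SimBundle:
    """Maxicircle with cryptogenes + edited mRNAs + minicircles with cassettes."""
    rng = np.random.default_rng(params.seed)
    b = SimBundle(params=params)
    patterns = [k for k, _ in params.pattern_mix]
    probs = np.array([w for _, w in params.pattern_mix], dtype=float)
    probs /= probs.sum()

    segments = [_rand_seq(rng, params.maxi_backbone_len, params.gc)]
    pos = params.maxi_backbone_len
    for gi in range(params.n_genes):
        gene_id = f"mt_gene_{gi:02d}"
        pattern = str(rng.choice(patterns, p=probs))
        gene, events = _make_gene(rng, params, pattern, gene_id)
        spacer = _spacer(rng, params.spacer_len, params.gc)
        segments.append(spacer)
        pos += params.spacer_len
        segments.append(gene)
        iv = Interval("maxicircle_00", pos, pos + len(gene))
        pos += len(gene)
        mrna = apply_events(gene, events)
        b.gene_seqs[gene_id] = gene
        b.edit_events[gene_id] = events
        b.gene_regions[gene_id] = ("maxicircle_00", iv)
        b.gene_patterns[gene_id] = pattern
        b.mt_mrnas.append(SeqRecord(f"mRNA_{gene_id}", mrna))
    segments.append(_spacer(rng, params.spacer_len, params.gc))
    pos += params.spacer_len

    if params.deam_cluster is not None:
        n_c, n_a, span = params.deam_cluster
        gene_id = "mt_rrna_12S"
        L = 300
        seq = list(_rand_seq(rng, L, params.gc))
        start = int(rng.integers(20, L - span - 20))
        sites = sorted(int(x) for x in rng.choice(span, size=n_c + n_a, replace=False))
        kinds = [C_TO_U] * n_c + [A_TO_I] * n_a
        kind_order = list(rng.permutation(len(kinds)))
        events = []
        for site, ki in zip(sites, kind_order):
            kind = kinds[ki]
            gpos = start + site
            seq[gpos] = "C" if kind == C_TO_U else "A"
            events.append(EditEvent(kind, gpos, 0))
        gene = "".join(seq)
        events = _fix_mrna_pos(gene, sorted(events, key=lambda e: e.gene_pos))
        spacer = _spacer(rng, params.spacer_len, params.gc)
        segments.append(gene)
        iv = Interval("maxicircle_00", pos, pos + L)
        pos += L
        segments.append(spacer)
        pos += params.spacer_len
        b.gene_seqs[gene_id] = gene
        b.edit_events[gene_id] = events
        b.gene_regions[gene_id] = ("maxicircle_00", iv)
        b.gene_patterns[gene_id] = "DEAMINATIVE"
        b.rrna_transcripts.append(SeqRecord(f"mRNA_{gene_id}", apply_events(gene, events)))

    maxi = "".join(segments)
    if params.circular_overlap > 0:
        maxi = maxi + maxi[: params.circular_overlap]
    b.maxicircles.append(SeqRecord("maxicircle_00", maxi))

    # minicircles: shared backbone + one cassette each
    lo, hi = params.minicircle_len_range
    bb_len = max(100, (lo + hi) // 2 - params.cassette_len)
    backbone = _rand_seq(rng, bb_len, params.gc)
    for mi in range(params.n_minicircles):
        mid = f"minicircle_{mi:02d}"
        mrna = b.mt_mrnas[int(rng.integers(len(b.mt_mrnas)))]
        w0 = int(rng.integers(0, len(mrna.seq) - params.cassette_len + 1))
        block = mrna.seq[w0 : w0 + params.cassette_len]
        grna = list(revcomp(block))
        # introduce G:U wobble pairs: gRNA position t pairs mRNA position
        # w0 + (cassette_len - 1 - t)
        eligible = [
            t for t in range(len(grna))
            if block[params.cassette_len - 1 - t] in ("T", "G")
        ]
        n_wob = min(len(eligible), int(round(params.wobble_frac * params.cassette_len)))
        wob_sites = sorted(int(x) for x in rng.choice(eligible, size=n_wob, replace=False))
        for t in wob_sites:
            m_char = block[params.cassette_len - 1 - t]
            grna[t] = "G" if m_char == "T" else "T"  # G:U or U:G pair
        cassette = "".join(grna)
        cut = int(rng.integers(50, bb_len - 50))
        mini = backbone[:cut] + cassette + backbone[cut:]
        b.minicircles.append(SeqRecord(mid, mini))
        b.cassettes.append(
            {
                "minicircle_id": mid,
                "ival": Interval(mid, cut, cut + params.cassette_len, "+"),
                "mrna_id": mrna.id,
                "mrna_ival": Interval(mrna.id, w0, w0 + params.cassette_len),
                "n_wobble": n_wob,
            }
        )
    return b


# ---------------------------------------------------------------------------
# nuclear simulation


def simulate_nuclear(params: SimParams) -> SimBundle:
    """Same-strand gene clusters with short intergenic gaps + SL transcripts."""
    rng = np.random.default_rng(params.seed + 1)
    b = SimBundle(params=params)
    for ci in range(params.n_nuclear_contigs):
        cid = f"nuclear_{ci:02d}"
        strand = "+" if ci % 2 == 0 else "-"
        segments = [_rand_seq(rng, 200, params.gc)]
        pos = 200
        genes: list[tuple[str, Interval, str]] = []
        for gi in range(params.genes_per_contig):
            if gi > 0:
                gap = (
                    int(rng.geometric(1.0 / max(1, params.intergenic_mean)))
                    if params.intergenic_jitter
                    else params.intergenic_mean
                )
                segments.append(_rand_seq(rng, gap, params.gc))
                pos += gap
            L = int(rng.integers(*params.nuclear_gene_len_range))
            gene = _rand_seq(rng, L, params.gc)
            gid = f"nuc_gene_{ci:02d}_{gi:02d}"
            segments.append(gene)
            iv = Interval(cid, pos, pos + L, strand)
            pos += L
            genes.append((gid, iv, strand))
            t_seq = gene if strand == "+" else revcomp(gene)
            has_sl = rng.random() < params.sl_fraction
            tid = f"tx_{gid}"
            if has_sl:
                t_seq = params.sl_seq + t_seq
                b.sl_ids.add(tid)
            b.nuclear_transcripts.append(SeqRecord(tid, t_seq))
        segments.append(_rand_seq(rng, 200, params.gc))
        b.nuclear_contigs.append(SeqRecord(cid, "".join(segments)))
        b.nuclear_genes[cid] = genes
    return b


# ---------------------------------------------------------------------------
# contamination


def simulate_contamination(params: SimParams) -> SimBundle:
    """Prey contigs plus target contigs carrying mutated prey segments."""
    n_prey, identity, seg_len = params.prey
    if not (0 < identity <= 1):
        raise ValueError("prey identity must be in (0, 1]")
    rng = np.random.default_rng(params.seed + 2)
    b = SimBundle(params=params)
    for pi in range(n_prey):
        prey = SeqRecord(f"prey_{pi:02d}", _rand_seq(rng, 500, params.gc))
        b.prey_contigs.append(prey)
        seg_start = int(rng.integers(0, 500 - seg_len + 1))
        seg = list(prey.seq[seg_start : seg_start + seg_len])
        # exact mutation count, stratified over the segment: every window of
        # the segment then carries close to its expected divergence, so the
        # realized identity of any sub-alignment tracks the configured value
        n_mut = int(round((1 - identity) * seg_len))
        if n_mut > 0:
            cell = seg_len / n_mut
            for k in range(n_mut):
                lo = int(k * cell)
                hi = max(lo + 1, int((k + 1) * cell))
                t = int(rng.integers(lo, hi))
                alts = [c for c in "ACGT" if c != seg[t]]
                seg[t] = alts[int(rng.integers(3))]
        host = _rand_seq(rng, 1000, params.gc)
        cut = int(rng.integers(100, 900 - seg_len))
        cid = f"contam_{pi:02d}"
        b.contaminated_contigs.append(
            SeqRecord(cid, host[:cut] + "".join(seg) + host[cut:])
        )
        b.contaminant_ids.add(cid)
    return b


def simulate_all(params: SimParams) -> SimBundle:
    """Full bundle: mitochondrial + nuclear + contamination parts."""
    b = simulate_mt(params)
    b.merge(simulate_nuclear(params))
    b.merge(simulate_contamination(params))
    return b
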