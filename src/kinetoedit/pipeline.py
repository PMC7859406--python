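"""End-to-end orchestration: decontaminate → classify mt contigs → locate
cryptogenes → reconstruct editing → stats → gRNA → SL → polarity.

A single plain-text (YAML) config drives the run; every stage writes TSV
artifacts into the output directory and a manifest records the package
version, all effective parameters and input checksums, so a run is
self-documenting.  Re-running with identical inputs and config reproduces
identical outputs (the pipeline itself draws no random numbers).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .core_io import SeqRecord, logger, read_fasta, write_table
from .depletion import SearchParams, tdepleted_search, local_search
from .editing import EditAlignParams, align_editing
from .editing_stats import (
    aggregate,
    detect_deaminative_clusters,
    summarize_editing,
)
from .genome_features import DecontamParams, flag_prey_contigs, map_transcripts, polarity_report
from .grna import GRnaParams, MtClassifyParams, MAXICIRCLE_LIKE, MINICIRCLE_LIKE, classify_contigs, find_grnas
from .sl_motifs import PREY, SLRef, TARGET, sl_fraction, trim_sl

__all__ = ["PipelineConfig", "PipelineError", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated run configuration (paths may be None to skip stages)."""

    output_dir: Path
    mt_contigs: Optional[Path] = None
    mt_transcripts: Optional[Path] = None
    rrna_transcripts: Optional[Path] = None
    nuclear_contigs: Optional[Path] = None
    nuclear_transcripts: Optional[Path] = None
    prey: Optional[Path] = None
    sl_refs: Optional[Path] = None
    seed: int = 0
    verbosity: int = 1
    region_pad: int = 30
    genetic_code: int = 4
    search: SearchParams = field(default_factory=SearchParams)
    align: EditAlignParams = field(default_factory=EditAlignParams)
    classify: MtClassifyParams = field(default_factory=MtClassifyParams)
    grna: GRnaParams = field(default_factory=GRnaParams)
    decontam: DecontamParams = field(default_factory=DecontamParams)
    sl_max_mismatch: int = 1
    sl_min_suffix: int = 10
    sl_search_window: int = 40
    map_min_identity: float = 0.90

    def validate(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Path) and f.name != "output_dir" and not v.exists():
                raise FileNotFoundError(f"input file missing: {f.name} = {v}")


_PARAM_BLOCKS = {
    "search": SearchParams,
    "align": EditAlignParams,
    "classify": MtClassifyParams,
    "grna": GRnaParams,
    "decontam": DecontamParams,
}

_INPUT_KEYS = (
    "mt_contigs", "mt_transcripts", "rrna_transcripts", "nuclear_contigs",
    "nuclear_transcripts", "prey", "sl_refs",
)
_SCALAR_KEYS = (
    "seed", "verbosity", "region_pad", "genetic_code", "sl_max_mismatch",
    "sl_min_suffix", "sl_search_window", "map_min_identity",
)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config file; unknown keys are rejected."""
    with open(path) as fh:
        raw: dict[str, Any] = yaml.safe_load(fh) or {}
    if "output_dir" not in raw:
        raise ValueError("config: output_dir is required")
    cfg = PipelineConfig(output_dir=Path(raw.pop("output_dir")))
    inputs = raw.pop("inputs", {})
    for key in list(inputs):
        if key not in _INPUT_KEYS:
            raise ValueError(f"config: unknown input key {key!r}")
        setattr(cfg, key, Path(inputs.pop(key)))
    params = raw.pop("params", {})
    for block, cls in _PARAM_BLOCKS.items():
        if block in params:
            kw = params.pop(block)
            valid = {f.name for f in dc_fields(cls)}
            bad = set(kw) - valid
            if bad:
                raise ValueError(f"config: unknown {block} parameter(s) {sorted(bad)}")
            if block == "classify" and "minicircle_len_range" in kw:
                kw["minicircle_len_range"] = tuple(kw["minicircle_len_range"])
            setattr(cfg, block, cls(**kw))
    if params:
        raise ValueError(f"config: unknown params block(s) {sorted(params)}")
    for key in _SCALAR_KEYS:
        if key in raw:
            setattr(cfg, key, raw.pop(key))
    if raw:
        raise ValueError(f"config: unknown key(s) {sorted(raw)}")
    cfg.validate()
    return cfg


def _md5(path: Path) -> str:
    h = hashlib.md5()
    h.update(path.read_bytes())
    return h.hexdigest()


def _hit_row(h) -> dict:
    return {
        "query_id": h.query_id, "subject_id": h.subject_id,
        "q_start": h.q_ival.start, "q_end": h.q_ival.end,
        "s_start": h.s_ival.start, "s_end": h.s_ival.end,
        "strand": h.strand, "identity": h.identity, "score": h.score,
    }


_HIT_COLS = ["query_id", "subject_id", "q_start", "q_end", "s_start", "s_end",
             "strand", "identity", "score"]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all configured stages; returns the report directory.

    Stages whose inputs are not configured are skipped with a log line.
    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts written before the failure are retained.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        inputs: dict[str, list[SeqRecord]] = {}
        for key in _INPUT_KEYS:
            p = getattr(config, key)
            if p is not None:
                inputs[key] = read_fasta(p)
        _write_manifest(config, out)

        # 1. decontamination
        retained_nuclear = inputs.get("nuclear_contigs", [])
        if "prey" in inputs and retained_nuclear:
            stage = "decontam"
            logger.info("stage decontam: %d contigs", len(retained_nuclear))
            flags = flag_prey_contigs(retained_nuclear, inputs["prey"], config.decontam)
            write_table(
                [
                    {"contig_id": f.contig_id, "flagged": f.flagged,
                     "prey_id": f.evidence.query_id if f.evidence else "",
                     "identity": f.evidence.identity if f.evidence else 0.0,
                     "aligned_cols": f.evidence.n_cols if f.evidence else 0}
                    for f in flags
                ],
                out / "decontam.tsv",
                ["contig_id", "flagged", "prey_id", "identity", "aligned_cols"],
            )
            flagged = {f.contig_id for f in flags if f.flagged}
            retained_nuclear = [c for c in retained_nuclear if c.id not in flagged]

        # 2. mitochondrial contig classification
        maxicircles: list[SeqRecord] = []
        minicircles: list[SeqRecord] = []
        if "mt_contigs" in inputs and "mt_transcripts" in inputs:
            stage = "mt-classify"
            logger.info("stage mt-classify: %d contigs", len(inputs["mt_contigs"]))
            classes = classify_contigs(
                inputs["mt_contigs"], inputs["mt_transcripts"],
                inputs.get("rrna_transcripts", []), config.classify,
            )
            write_table(
                [
                    {"contig_id": c.contig_id, "label": c.label,
                     "n_evidence": len(c.evidence), "circular": c.circular,
                     "backbone": ";".join(f"{i.start}-{i.end}" for i in c.backbone_ivals)}
                    for c in classes
                ],
                out / "mt_classes.tsv",
                ["contig_id", "label", "n_evidence", "circular", "backbone"],
            )
            by_id = {c.id: c for c in inputs["mt_contigs"]}
            maxicircles = [by_id[c.contig_id] for c in classes if c.label == MAXICIRCLE_LIKE]
            minicircles = [by_id[c.contig_id] for c in classes if c.label == MINICIRCLE_LIKE]

        # 3-5. cryptogene location, editing reconstruction, statistics
        if maxicircles and "mt_transcripts" in inputs:
            stage = "editing"
            logger.info("stage editing: %d transcripts", len(inputs["mt_transcripts"]))
            hit_rows, event_rows, stats = [], [], []
            cluster_rows = []
            rrna_ids = {r.id for r in inputs.get("rrna_transcripts", [])}
            mt_like = inputs["mt_transcripts"] + inputs.get("rrna_transcripts", [])
            for mrna in mt_like:
                hits = tdepleted_search(mrna, maxicircles, config.search)
                if not hits:
                    hits = local_search(mrna, maxicircles, config.search)
            # best contig hit defines the gene region, padded on both sides
                if not hits:
                    logger.warning("editing: no cryptogene hit for %s", mrna.id)
                    continue
                h = hits[0]
                hit_rows.append(_hit_row(h))
                contig = next(c for c in maxicircles if c.id == h.subject_id)
                s0 = max(0, h.s_ival.start - config.region_pad)
                s1 = min(len(contig.seq), h.s_ival.end + config.region_pad)
                region_seq = contig.seq[s0:s1]
                if h.strand == "-":
                    from .core_io import revcomp
                    region_seq = revcomp(region_seq)
                region = SeqRecord(f"{mrna.id}_region", region_seq)
                aln = align_editing(region, mrna, config.align)
                if aln is None:
                    logger.warning("editing: unalignable pair %s", mrna.id)
                    continue
                for e in aln.events:
                    event_rows.append(
                        {"gene_id": aln.gene_id, "mrna_id": aln.mrna_id,
                         "kind": e.kind, "gene_pos": e.gene_pos,
                         "mrna_pos": e.mrna_pos, "run_len": e.run_len}
                    )
                st = summarize_editing(aln, config.genetic_code)
                stats.append(st)
                for cl in detect_deaminative_clusters(aln.events, seq_id=aln.gene_id):
                    cluster_rows.append(
                        {"seq_id": cl.seq_id, "start": cl.span.start,
                         "end": cl.span.end, "n_edits": cl.n_edits,
                         "n_c_to_u": cl.n_c_to_u, "n_a_to_i": cl.n_a_to_i}
                    )
            write_table(hit_rows, out / "cryptogene_hits.tsv", _HIT_COLS)
            write_table(event_rows, out / "edit_events.tsv",
                        ["gene_id", "mrna_id", "kind", "gene_pos", "mrna_pos", "run_len"])
            write_table(
                [
                    {"gene_id": s.gene_id, "gene_len": s.gene_len,
                     "n_ins": s.n_ins, "n_del": s.n_del,
                     "pct_expansion": s.pct_expansion,
                     "n_c_to_u": s.n_c_to_u, "n_a_to_i": s.n_a_to_i,
                     "pattern": s.pattern,
                     "stop_created_by_editing": s.stop_created_by_editing}
                    for s in stats
                ],
                out / "editing_stats.tsv",
                ["gene_id", "gene_len", "n_ins", "n_del", "pct_expansion",
                 "n_c_to_u", "n_a_to_i", "pattern", "stop_created_by_editing"],
            )
            write_table(cluster_rows, out / "deaminative_clusters.tsv",
                        ["seq_id", "start", "end", "n_edits", "n_c_to_u", "n_a_to_i"])
            mrna_stats = [s for s in stats if s.gene_id.removesuffix("_region") not in rrna_ids]
            if mrna_stats:
                # species summary covers mRNAs only (rRNAs are reported
                # per-gene but are not part of the U-indel load statistics)
                s = aggregate(mrna_stats)
                write_table([vars(s)], out / "species_summary.tsv", list(vars(s)))

        # 6. gRNA detection
        if minicircles and "mt_transcripts" in inputs:
            stage = "grna"
            logger.info("stage grna: %d minicircles", len(minicircles))
            rows = []
            for mini in minicircles:
                for h in find_grnas(mini, inputs["mt_transcripts"], config.grna):
                    rows.append(
                        {"minicircle_id": h.minicircle_id,
                         "c_start": h.cassette_ival.start, "c_end": h.cassette_ival.end,
                         "strand": h.cassette_ival.strand,
                         "mrna_id": h.mrna_id,
                         "m_start": h.mrna_ival.start, "m_end": h.mrna_ival.end,
                         "n_wc": h.n_wc, "n_wobble": h.n_wobble,
                         "n_mismatch": h.n_mismatch, "anchor_len": h.anchor_len,
                         "score": h.score}
                    )
            write_table(rows, out / "grna_hits.tsv",
                        ["minicircle_id", "c_start", "c_end", "strand", "mrna_id",
                         "m_start", "m_end", "n_wc", "n_wobble", "n_mismatch",
                         "anchor_len", "score"])

        # 7. spliced leaders
        sl_calls_by_id: dict[str, Any] = {}
        if "sl_refs" in inputs and "nuclear_transcripts" in inputs:
            stage = "sl"
            logger.info("stage sl: %d transcripts", len(inputs["nuclear_transcripts"]))
            refs = []
            for rec in inputs["sl_refs"]:
                source = PREY if "PREY" in rec.description.upper() else TARGET
                refs.append(SLRef(rec.id, rec.seq, source))
            table, calls = sl_fraction(
                inputs["nuclear_transcripts"], refs,
                config.sl_max_mismatch, config.sl_min_suffix, config.sl_search_window,
            )
            write_table(
                [{"transcript_id": c.transcript_id, "ref_name": c.ref_name,
                  "offset": c.offset, "matched_len": c.matched_len,
                  "mismatches": c.mismatches, "source": c.source} for c in calls],
                out / "sl_calls.tsv",
                ["transcript_id", "ref_name", "offset", "matched_len", "mismatches", "source"],
            )
            write_table(
                [{"source": k, "count": v[0], "fraction": v[1]} for k, v in table.items()],
                out / "sl_fractions.tsv", ["source", "count", "fraction"],
            )
            sl_calls_by_id = {c.transcript_id: c for c in calls}

        # 8. mapping and polarity (SLs are trans-spliced, so trim them
        # before genome mapping)
        if retained_nuclear and "nuclear_transcripts" in inputs:
            stage = "polarity"
            logger.info("stage polarity: mapping %d transcripts",
                        len(inputs["nuclear_transcripts"]))
            to_map = [
                trim_sl(t, sl_calls_by_id.get(t.id))
                for t in inputs["nuclear_transcripts"]
            ]
            mappings, frac = map_transcripts(
                to_map, retained_nuclear, config.map_min_identity
            )
            write_table(
                [
                    {"transcript_id": m.transcript_id, "contig_id": m.contig_id,
                     "t_start": m.t_ival.start, "t_end": m.t_ival.end,
                     "c_start": m.c_ival.start, "c_end": m.c_ival.end,
                     "strand": m.strand, "identity": m.identity,
                     "coverage": m.coverage}
                    for m in mappings
                ],
                out / "mappings.tsv",
                ["transcript_id", "contig_id", "t_start", "t_end", "c_start",
                 "c_end", "strand", "identity", "coverage"],
            )
            write_table([{"mapped_fraction": frac}], out / "mapping_summary.tsv",
                        ["mapped_fraction"])
            if mappings:
                write_table(
                    [
                        {"contig_id": r.contig_id, "n_genes": len(r.genes),
                         "same_strand_fraction": r.same_strand_fraction,
                         "mean_intergenic": r.mean_intergenic,
                         "n_overlapping": r.n_overlapping,
                         "strand_runs": ";".join(map(str, r.strand_runs))}
                        for r in polarity_report(mappings)
                    ],
                    out / "polarity.tsv",
                    ["contig_id", "n_genes", "same_strand_fraction",
                     "mean_intergenic", "n_overlapping", "strand_runs"],
                )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap with stage context
        logger.error("pipeline failed in stage %s: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    logger.info("pipeline complete: %s", out)
    return out


def _write_manifest(config: PipelineConfig, out: Path) -> None:
    lines = [f"kinetoedit {__version__}", ""]
    lines.append("[inputs]")
    for key in _INPUT_KEYS:
        p = getattr(config, key)
        if p is not None:
            lines.append(f"{key} = {p} md5={_md5(Path(p))}")
    lines.append("")
    lines.append("[params]")
    for key in _SCALAR_KEYS:
        lines.append(f"{key} = {getattr(config, key)}")
    for block in _PARAM_BLOCKS:
        for k, v in asdict(getattr(config, block)).items():
            lines.append(f"{block}.{k} = {v}")
    (out / "manifest.txt").write_text("\n".join(lines) + "\n")
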