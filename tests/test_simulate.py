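"""Generator contracts: determinism, truth round trips, moment recovery."""

from dataclasses import replace

import numpy as np
import pytest

from kinetoedit.core_io import SeqRecord
from kinetoedit.editing import U_DEL, U_INS, align_editing, apply_events
from kinetoedit.editing_stats import FIVE_PRIME, PAN
from kinetoedit.genome_features import flag_prey_contigs
from kinetoedit.simulate import (
    SimParams,
    ankaliazontas_like,
    simulate_all,
    simulate_contamination,
    simulate_mt,
    simulate_nuclear,
    spiralis_like,
)


def test_truth_events_reproduce_mrnas(ank_bundle):
    """Applying each gene's truth events to its cryptogene yields its mRNA."""
    b = ank_bundle
    all_tx = {r.id: r for r in b.mt_mrnas + b.rrna_transcripts}
    for gid, gene in b.gene_seqs.items():
        assert apply_events(gene, b.edit_events[gid]) == all_tx[f"mRNA_{gid}"].seq


def test_gene_regions_match_maxicircle(ank_bundle):
    b = ank_bundle
    maxi = {c.id: c.seq for c in b.maxicircles}
    for gid, (cid, iv) in b.gene_regions.items():
        assert maxi[cid][iv.start : iv.end] == b.gene_seqs[gid]


def test_cassettes_are_wobbled_reverse_complements(ank_bundle):
    """Every truth cassette pairs its mRNA block with WC or G:U only."""
    from kinetoedit.core_io import revcomp

    b = ank_bundle
    mrnas = {r.id: r.seq for r in b.mt_mrnas}
    wob = {("C", "T"), ("A", "G")}
    for c in b.cassettes:
        mini = next(m for m in b.minicircles if m.id == c["minicircle_id"])
        grna = mini.seq[c["ival"].start : c["ival"].end]
        block = mrnas[c["mrna_id"]][c["mrna_ival"].start : c["mrna_ival"].end]
        rc = revcomp(grna)
        n_wob = sum(1 for a, b2 in zip(rc, block) if a != b2)
        assert all(a == b2 or (a, b2) in wob for a, b2 in zip(rc, block))
        assert n_wob == c["n_wobble"]


def test_same_params_byte_identical(tmp_path):
    p = spiralis_like(seed=9, n_genes=3, n_minicircles=2)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_all(p).write(d1)
    simulate_all(p).write(d2)
    for f in sorted(d1.iterdir()):
        assert (d2 / f.name).read_bytes() == f.read_bytes(), f.name


def test_different_seed_different_output():
    a = simulate_mt(spiralis_like(seed=1, n_genes=2, n_minicircles=1))
    b = simulate_mt(spiralis_like(seed=2, n_genes=2, n_minicircles=1))
    assert a.maxicircles[0].seq != b.maxicircles[0].seq


def test_end_to_end_recovery_on_truth_regions(small_mt_bundle):
    """align_editing on each truth gene region recovers exact indel counts."""
    b = small_mt_bundle
    maxi = b.maxicircles[0]
    for gid in b.gene_seqs:
        cid, iv = b.gene_regions[gid]
        pad = 30
        region = SeqRecord("r", maxi.seq[max(0, iv.start - pad) : iv.end + pad])
        mrna = next(r for r in b.mt_mrnas + b.rrna_transcripts if r.id == f"mRNA_{gid}")
        aln = align_editing(region, mrna)
        assert aln.n_ins == b.truth_n_ins(gid)
        assert aln.n_del == b.truth_n_del(gid)


def test_sampled_mean_insertions_converges():
    """Over many genes the realized mean U-insertion count tracks the target."""
    p = SimParams(
        n_genes=500, gene_len_range=(100, 160),
        ins_per_gene=(50.0, 10, 120), del_per_gene=(4.0, 1, 8),
        deam_cluster=None, n_minicircles=0, seed=3,
        pattern_mix=((PAN, 1.0),),
    )
    b = simulate_mt(p)
    mean_ins = np.mean([b.truth_n_ins(g) for g in b.gene_seqs])
    assert abs(mean_ins - 50.0) / 50.0 < 0.05


def test_deam_cluster_counts_match_configuration(ank_bundle):
    events = ank_bundle.edit_events["mt_rrna_12S"]
    from kinetoedit.editing import A_TO_I, C_TO_U

    assert sum(1 for e in events if e.kind == C_TO_U) == 8
    assert sum(1 for e in events if e.kind == A_TO_I) == 4
    pos = [e.gene_pos for e in events]
    assert max(pos) - min(pos) < 30
    assert not any(e.kind in (U_INS, U_DEL) for e in events)


def test_infeasible_deletions_raise_named_error():
    p = SimParams(
        n_genes=1, gene_len_range=(40, 40), ins_per_gene=(5.0, 0, 10),
        del_per_gene=(30.0, 30, 30), deam_cluster=None, seed=1,
        pattern_mix=((PAN, 1.0),),
    )
    with pytest.raises(ValueError, match="mt_gene_00"):
        simulate_mt(p)


def test_nuclear_truth_polarity():
    p = spiralis_like(seed=4)
    b = simulate_nuclear(p)
    for cid, genes in b.nuclear_genes.items():
        strands = {s for _, _, s in genes}
        assert len(strands) == 1  # same-strand clusters by construction
        gaps = [n.start - p0.end for (_, p0, _), (_, n, _) in zip(genes, genes[1:])]
        assert all(g == 76 for g in gaps)


def test_sl_count_within_binomial_bound():
    from scipy.stats import binom

    p = replace(spiralis_like(seed=7), sl_fraction=0.58,
                n_nuclear_contigs=10, genes_per_contig=100,
                nuclear_gene_len_range=(60, 120))
    b = simulate_nuclear(p)
    n = len(b.nuclear_transcripts)
    lo, hi = binom.ppf([0.005, 0.995], n, 0.58)
    assert lo <= len(b.sl_ids) <= hi


def test_sl_fraction_zero_means_no_leaders():
    p = replace(spiralis_like(seed=8), sl_fraction=0.0)
    b = simulate_nuclear(p)
    assert b.sl_ids == set()
    assert not any(t.seq.startswith(p.sl_seq) for t in b.nuclear_transcripts)


@pytest.mark.parametrize(
    "identity,seg_len,expect_flagged",
    [
        (0.95, 120, True),   # above both thresholds
        (0.90, 120, False),  # expected identity below the 93% rule
        (0.99, 80, False),   # below the 100 bp length rule
    ],
)
def test_contamination_flagging_matrix(identity, seg_len, expect_flagged):
    p = replace(spiralis_like(seed=6), prey=(5, identity, seg_len))
    b = simulate_contamination(p)
    flags = flag_prey_contigs(b.contaminated_contigs, b.prey_contigs)
    n_flagged = sum(f.flagged for f in flags)
    if expect_flagged:
        assert n_flagged == len(flags)
    else:
        assert n_flagged == 0
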