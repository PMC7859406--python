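"""The constrained editing aligner against its exhaustive oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinetoedit.core_io import SeqRecord
from kinetoedit.editing import (
    A_TO_I,
    C_TO_U,
    U_DEL,
    U_INS,
    EditAlignParams,
    EditEvent,
    align_editing,
    apply_events,
    canonicalize,
    oracle_align,
)

GLOBAL = EditAlignParams(end_free_gene=False)


def _align(g, m, p=GLOBAL):
    return align_editing(SeqRecord("g", g), SeqRecord("m", m), p)


@pytest.mark.parametrize(
    "gene,mrna,kinds,n_ins,n_del",
    [
        ("ACG", "ACG", (), 0, 0),
        ("AG", "ATTG", (U_INS,), 2, 0),
        ("ATG", "AG", (U_DEL,), 0, 1),
        ("ACA", "ATA", (C_TO_U,), 0, 0),
        ("AAA", "AGA", (A_TO_I,), 0, 0),
    ],
)
def test_small_alignments(gene, mrna, kinds, n_ins, n_del):
    aln = _align(gene, mrna)
    assert tuple(e.kind for e in aln.events) == kinds
    assert (aln.n_ins, aln.n_del) == (n_ins, n_del)


def test_insertion_run_event_coordinates():
    aln = _align("AG", "ATTG")
    (e,) = aln.events
    assert (e.gene_pos, e.mrna_pos, e.run_len) == (1, 1, 2)


def test_oracle_examples():
    p = GLOBAL
    assert oracle_align(SeqRecord("g", "ACG"), SeqRecord("m", "ACG"), p) == 3 * p.match
    assert (
        oracle_align(SeqRecord("g", "AG"), SeqRecord("m", "ATTG"), p)
        == 2 * p.match + p.ins_open + p.ins_ext
    )


def test_oracle_size_limit():
    with pytest.raises(ValueError, match="size limit"):
        oracle_align(SeqRecord("g", "A" * 11), SeqRecord("m", "ACG"), GLOBAL)


def _random_pair(rng, max_gene=8, max_ops=4):
    n = int(rng.integers(1, max_gene + 1))
    gene = "".join(rng.choice(list("ACGT"), n))
    mrna = list(gene)
    for _ in range(int(rng.integers(0, max_ops + 1))):
        op = int(rng.integers(0, 3))
        if op == 0:
            mrna.insert(int(rng.integers(0, len(mrna) + 1)), "T")
        elif op == 1:
            ts = [i for i, c in enumerate(mrna) if c == "T"]
            if ts:
                mrna.pop(ts[int(rng.integers(len(ts)))])
        elif mrna:
            i = int(rng.integers(len(mrna)))
            mrna[i] = "ACGT"[int(rng.integers(4))]
    return gene, "".join(mrna)


@pytest.mark.parametrize("end_free", [False, True])
@pytest.mark.parametrize("allow_other", [True, False])
def test_oracle_equivalence_random_pairs(end_free, allow_other):
    """DP optimum equals the exhaustively enumerated optimum."""
    p = EditAlignParams(end_free_gene=end_free, allow_other_mismatch=allow_other)
    rng = np.random.default_rng(12345)
    checked = 0
    while checked < 60:
        gene, mrna = _random_pair(rng)
        if not mrna or len(mrna) > 12:
            continue
        checked += 1
        aln = _align(gene, mrna, p)
        orc = oracle_align(SeqRecord("g", gene), SeqRecord("m", mrna), p)
        if orc is None:
            assert aln is None
        else:
            assert aln is not None and aln.score == pytest.approx(orc)


@settings(derandomize=True, max_examples=60)
@given(st.integers(0, 10_000))
def test_length_conservation_and_round_trip(seed):
    """len(mrna) == len(gene span) + n_ins − n_del, and replaying the event
    list on the gene reproduces the mRNA (no generic mismatches present)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 30))
    gene = "".join(rng.choice(list("ACGT"), n))
    mrna = apply_events(gene, [EditEvent(U_INS, int(rng.integers(1, n)), 0, int(rng.integers(1, 4)))])
    aln = _align(gene, mrna)
    assert len(aln.mrna_seq) == len(aln.gene_ival) + aln.n_ins - aln.n_del
    if not aln.other_mismatches:
        span = aln.gene_seq[aln.gene_ival.start : aln.gene_ival.end]
        assert apply_events(span, [
            EditEvent(e.kind, e.gene_pos - aln.gene_ival.start, e.mrna_pos, e.run_len)
            for e in aln.events
        ]) == mrna


def test_monotonicity_one_more_forced_insertion():
    """Appending one more U to an insertion run raises n_ins by exactly 1."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(8, 20))
        gene = "".join(rng.choice(list("ACG"), n))  # T-free so runs are unambiguous
        pos = int(rng.integers(1, n))
        run = int(rng.integers(1, 4))
        m1 = apply_events(gene, [EditEvent(U_INS, pos, 0, run)])
        m2 = apply_events(gene, [EditEvent(U_INS, pos, 0, run + 1)])
        a1, a2 = _align(gene, m1), _align(gene, m2)
        assert a2.n_ins == a1.n_ins + 1


def test_canonical_left_shift_of_deletion():
    aln = _align("TT", "T")
    (e,) = aln.events
    assert e.kind == U_DEL and e.gene_pos == 0


def test_canonical_left_shift_of_insertion_in_t_context():
    # gene A|G with mRNA A T T G: both placements score equally; the run is
    # emitted at the leftmost admissible gene position
    aln = _align("ATG", "ATTTG")
    ins = [e for e in aln.events if e.kind == U_INS]
    assert sum(e.run_len for e in ins) == 2
    assert min(e.gene_pos for e in ins) == 1


def test_canonicalize_idempotent():
    rng = np.random.default_rng(3)
    for _ in range(30):
        gene, mrna = _random_pair(rng, max_gene=8, max_ops=4)
        if not mrna:
            continue
        aln = _align(gene, mrna)
        if aln is None:
            continue
        c1 = canonicalize(aln)
        c2 = canonicalize(c1)
        assert c1.events == c2.events == aln.events
        assert (c1.n_ins, c1.n_del) == (aln.n_ins, aln.n_del)


def test_unalignable_returns_none_not_exception():
    p = EditAlignParams(allow_other_mismatch=False, end_free_gene=False)
    assert _align("G", "C", p) is None


def test_param_validation():
    with pytest.raises(ValueError):
        EditAlignParams(match=-1)
    with pytest.raises(ValueError):
        EditAlignParams(ins_open=1.0)
    with pytest.raises(ValueError):
        EditEvent(C_TO_U, 0, 0, 2)
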