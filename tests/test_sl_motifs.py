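"""Spliced-leader detection/attribution and the stem-loop motif language."""

import itertools

import numpy as np
import pytest

from kinetoedit.core_io import SeqRecord, revcomp
from kinetoedit.sl_motifs import (
    AMBIGUOUS,
    PREY,
    TARGET,
    Gap,
    Literal,
    MotifPattern,
    SLRef,
    StemClose,
    StemOpen,
    compare_to_reference,
    detect_sl,
    parse_pattern,
    scan_motif,
    sl_fraction,
    trim_sl,
)

SL = "TTACAGTTTCTGTACTT"  # the prokinetoplastid-specific SL-region sequence


@pytest.fixture
def refs():
    return [SLRef("SL_target", SL, TARGET)]


def test_detect_full_sl_at_offset_zero(refs):
    rng = np.random.default_rng(0)
    payload = "".join(rng.choice(list("ACGT"), 120))
    call = detect_sl(SeqRecord("t", SL + payload), refs)
    assert (call.offset, call.matched_len, call.mismatches) == (0, 17, 0)
    assert call.source == TARGET


def test_detect_truncated_sl_suffix_with_one_mismatch(refs):
    rng = np.random.default_rng(1)
    suffix = list(SL[-12:])
    suffix[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[suffix[5]]
    payload = "".join(rng.choice(list("ACG"), 120))  # T-free payload, no chance SL
    call = detect_sl(
        SeqRecord("t", "".join(suffix) + payload), refs, max_mismatch=1, min_suffix=10
    )
    assert call.matched_len == 12 and call.mismatches == 1


def test_detect_none_without_sl(refs):
    rng = np.random.default_rng(2)
    t = SeqRecord("t", "".join(rng.choice(list("ACG"), 150)))
    assert detect_sl(t, refs) is None


def test_target_prey_tie_is_ambiguous():
    refs = [SLRef("a", SL, TARGET), SLRef("b", SL, PREY)]
    call = detect_sl(SeqRecord("t", SL + "CCCGGGCCC"), refs)
    assert call.source == AMBIGUOUS


def test_prey_attribution_wins_on_longer_match():
    prey_sl = SL[:-4] + "GGAC"  # diverged 3' end
    refs = [SLRef("t_ref", SL, TARGET), SLRef("p_ref", prey_sl, PREY)]
    call = detect_sl(SeqRecord("t", prey_sl + "CACACACACA"), refs, max_mismatch=0)
    assert call.source == PREY


def test_trim_sl_removes_leader(refs):
    t = SeqRecord("t", SL + "ACGACGACG")
    call = detect_sl(t, refs)
    assert trim_sl(t, call).seq == "ACGACGACG"
    assert trim_sl(t, None).seq == t.seq


def test_sl_fraction_partitions_transcripts(refs):
    rng = np.random.default_rng(3)
    transcripts = []
    for i in range(40):
        payload = "".join(rng.choice(list("ACG"), 100))
        transcripts.append(SeqRecord(f"t{i}", (SL + payload) if i < 28 else payload))
    table, calls = sl_fraction(transcripts, refs, max_mismatch=0)
    assert table[TARGET] == (28, 0.70)
    assert sum(v[0] for v in table.values()) == 40
    assert len(calls) == 28


# ---------------------------------------------------------------------------
# motif language


def test_stem_loop_hit_with_perfect_pairing():
    pat = MotifPattern((StemOpen("s", 4, 4), Literal("GAAA"), StemClose("s", 0)))
    hits = scan_motif(SeqRecord("x", "GGCGGAAACGCC"), pat)
    plus = [h for h in hits if h.strand == "+"]
    assert plus and plus[0].start == 0 and plus[0].end == 12
    # pairs from the stem base: G:C, G:C, C:G, G:C
    assert plus[0].stem_pairs[0] == (("G", "C"), ("G", "C"), ("C", "G"), ("G", "C"))


def test_stem_fails_without_pairing():
    pat = MotifPattern((StemOpen("s", 4, 4), Literal("GAAA"), StemClose("s", 0)))
    assert scan_motif(SeqRecord("x", "GGCGGAAAGGGG"), pat) == []


def test_literal_with_mismatch_budget():
    pat = MotifPattern((Literal("ACGT", 1),))
    hits = scan_motif(SeqRecord("x", "ACGA"), pat)
    assert any(h.strand == "+" and h.start == 0 for h in hits)
    assert scan_motif(SeqRecord("x", "AGGA"), pat) == [] or all(
        h.strand == "-" for h in scan_motif(SeqRecord("x", "AGGA"), pat)
    )


def test_gu_wobble_in_stems_togglable():
    # stem GGGG / TTTT pairs only via G:U wobble
    seq = SeqRecord("x", "GGGGAAATTTT")
    pat_gu = MotifPattern((StemOpen("s", 4, 4), Literal("AAA"), StemClose("s", 0, True)))
    pat_wc = MotifPattern((StemOpen("s", 4, 4), Literal("AAA"), StemClose("s", 0, False)))
    assert scan_motif(seq, pat_gu) != []
    assert scan_motif(seq, pat_wc) == []


def test_pattern_compile_errors():
    with pytest.raises(ValueError, match="no prior STEM_OPEN"):
        MotifPattern((StemClose("s", 0),))
    with pytest.raises(ValueError, match="unclosed"):
        MotifPattern((StemOpen("s", 3, 5),))
    with pytest.raises(ValueError):
        Literal("ACQT")


def _brute_force_hits(seq: str, stem_range, loop: str):
    """Independent enumeration of stem-loop occurrences on one strand."""
    wc = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}
    found = []
    for start in range(len(seq)):
        for L in range(stem_range[0], stem_range[1] + 1):
            end = start + 2 * L + len(loop)
            if end > len(seq):
                continue
            stem1 = seq[start : start + L]
            mid = seq[start + L : start + L + len(loop)]
            stem2 = seq[start + L + len(loop) : end]
            if mid != loop:
                continue
            if all((stem1[t], stem2[L - 1 - t]) in wc for t in range(L)):
                found.append((start, end))
    return found


def test_scan_motif_matches_brute_force_enumeration():
    """Leftmost-shortest non-overlapping scan agrees with a sliding-window
    oracle on short random sequences."""
    rng = np.random.default_rng(11)
    pat = MotifPattern((StemOpen("s", 3, 5), Literal("GAAA"), StemClose("s", 0)))
    for _ in range(60):
        seq = "".join(rng.choice(list("ACGT"), int(rng.integers(20, 120))))
        hits = [h for h in scan_motif(SeqRecord("x", seq), pat) if h.strand == "+"]
        brute = _brute_force_hits(seq, (3, 5), "GAAA")
        # greedy non-overlapping selection over the oracle's occurrences
        expect, cursor = [], 0
        for s, e in sorted(brute):
            if s >= cursor:
                # shortest match at this start
                cands = [x for x in brute if x[0] == s]
                e = min(x[1] for x in cands)
                expect.append((s, e))
                cursor = e
        assert [(h.start, h.end) for h in hits] == expect


def test_compare_to_reference_identical_and_compensatory():
    pat = MotifPattern((StemOpen("s", 4, 4), Literal("GAAA"), StemClose("s", 0)))
    (hit,) = [h for h in scan_motif(SeqRecord("x", "GGCGGAAACGCC"), pat) if h.strand == "+"]
    same = compare_to_reference(hit, [("G", "C"), ("G", "C"), ("C", "G"), ("G", "C")])
    assert (same.n_identical, same.n_compensatory) == (4, 0)
    swapped = compare_to_reference(hit, [("A", "T"), ("G", "C"), ("C", "G"), ("G", "C")])
    assert (swapped.n_identical, swapped.n_compensatory) == (3, 1)
    with pytest.raises(ValueError, match="length mismatch"):
        compare_to_reference(hit, [("G", "C")])


def test_compare_to_reference_mispair_counts_as_neither():
    pat = MotifPattern((StemOpen("s", 2, 2), Literal("AAA"), StemClose("s", 1)))
    # stem GA / TA: G:A at the base is a tolerated mispair, A:T pairs
    (hit,) = [h for h in scan_motif(SeqRecord("x", "GAAAATA"), pat) if h.strand == "+"]
    rep = compare_to_reference(hit, [("G", "C"), ("A", "T")])
    assert rep.n_identical + rep.n_compensatory <= 1


def test_parse_pattern_round_trip():
    text = """
    # 530-loop-like toy pattern
    STEM_OPEN s1 4 6
    LITERAL GAAA 1
    STEM_CLOSE s1 1 GU
    """
    pat = parse_pattern(text)
    assert isinstance(pat.elements[0], StemOpen)
    assert pat.elements[1].max_mismatch == 1
    with pytest.raises(ValueError, match="line"):
        parse_pattern("WIBBLE 3")
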