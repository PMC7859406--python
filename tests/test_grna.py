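"""Minicircle architecture: classification, backbones, gRNA duplexes, circularity."""

import numpy as np
import pytest

from kinetoedit.core_io import SeqRecord, revcomp
from kinetoedit.grna import (
    MAXICIRCLE_LIKE,
    MINICIRCLE_LIKE,
    UNCLASSIFIED,
    GRnaParams,
    classify_contigs,
    detect_circularity,
    find_backbone,
    find_grnas,
)

_WOBBLE_RC = {("C", "T"), ("A", "G")}


def _rewalk(minicircle, mrna, hit, allow_wobble=True):
    """Independent column-by-column tally of a reported duplex."""
    L = len(minicircle.seq)
    iv = hit.cassette_ival
    if iv.strand == "+":
        c = revcomp(minicircle.seq)[L - iv.end : L - iv.start]
    else:
        c = minicircle.seq[iv.start : iv.end]
    m = mrna.seq[hit.mrna_ival.start : hit.mrna_ival.end]
    wc = sum(1 for a, b in zip(c, m) if a == b and a != "N")
    wob = sum(1 for a, b in zip(c, m) if a != b and (a, b) in _WOBBLE_RC and allow_wobble)
    return wc, wob, len(c) - wc - wob


def test_grna_hit_tallies_match_independent_rewalk(small_mt_bundle):
    b = small_mt_bundle
    n_checked = 0
    for mini in b.minicircles:
        for h in find_grnas(mini, b.mt_mrnas):
            mrna = next(r for r in b.mt_mrnas if r.id == h.mrna_id)
            assert _rewalk(mini, mrna, h) == (h.n_wc, h.n_wobble, h.n_mismatch)
            n_checked += 1
    assert n_checked >= len(b.minicircles)


def test_exact_cassette_with_two_wobbles():
    rng = np.random.default_rng(8)
    block = "".join(rng.choice(list("ACGT"), 40))
    grna = list(revcomp(block))
    # convert two eligible pairs to G:U wobble
    elig = [t for t in range(40) if block[39 - t] in "TG"][:2]
    for t in elig:
        grna[t] = "G" if block[39 - t] == "T" else "T"
    mini = SeqRecord("mini", "".join(grna))
    hits = find_grnas(mini, [SeqRecord("m", block)])
    top = hits[0]
    assert (top.n_wc, top.n_wobble, top.n_mismatch) == (38, 2, 0)


def test_cassette_embedded_in_backbone_located():
    rng = np.random.default_rng(9)
    block = "".join(rng.choice(list("ACGT"), 40))
    backbone = "".join(rng.choice(list("ACGT"), 560))
    mini = SeqRecord("mini", backbone[:450] + revcomp(block) + backbone[450:])
    hits = find_grnas(mini, [SeqRecord("m", block)])
    top = hits[0]
    assert abs(top.cassette_ival.start - 450) <= 3
    assert abs(top.cassette_ival.end - 490) <= 3


def test_shuffled_minicircle_gives_no_hits(small_mt_bundle):
    b = small_mt_bundle
    rng = np.random.default_rng(13)
    for mini in b.minicircles:
        shuffled = "".join(rng.permutation(list(mini.seq)))
        assert find_grnas(SeqRecord(mini.id, shuffled), b.mt_mrnas) == []


def test_grna_params_validation():
    with pytest.raises(ValueError):
        GRnaParams(min_duplex=5, min_anchor=10)


def test_backbone_shared_interval_recovered():
    rng = np.random.default_rng(21)
    backbone = "".join(rng.choice(list("ACGT"), 400))
    contigs = []
    for i in range(10):
        flank1 = "".join(rng.choice(list("ACGT"), 100))
        flank2 = "".join(rng.choice(list("ACGT"), 100))
        contigs.append(SeqRecord(f"m{i}", flank1 + backbone + flank2))
    bb = find_backbone(contigs, 0.90, 100, 2)
    for c in contigs:
        ivals = bb[c.id]
        assert len(ivals) == 1
        assert abs(len(ivals[0]) - 400) <= 10


def test_backbone_absent_when_nothing_shared():
    rng = np.random.default_rng(22)
    contigs = [SeqRecord(f"r{i}", "".join(rng.choice(list("ACGT"), 500))) for i in range(4)]
    bb = find_backbone(contigs, 0.90, 100, 2)
    assert all(v == [] for v in bb.values())


def test_backbone_identity_threshold_boundary():
    """A backbone shared at ~92% pairwise identity passes min_identity 0.90
    but not 0.95 (each contig carries ~4% private mutations)."""
    rng = np.random.default_rng(23)
    backbone = "".join(rng.choice(list("ACGT"), 400))
    contigs = []
    for i in range(6):
        mutated = list(backbone)
        for p in rng.choice(400, 16, replace=False):  # 4% per contig
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        flank = "".join(rng.choice(list("ACGT"), 80))
        contigs.append(SeqRecord(f"m{i}", flank + "".join(mutated) + flank[::-1]))
    detected = find_backbone(contigs, 0.90, 100, 2)
    assert all(len(v) >= 1 for v in detected.values())
    strict = find_backbone(contigs, 0.95, 100, 2)
    assert sum(len(v) for v in strict.values()) < sum(len(v) for v in detected.values())


def test_classify_contigs_on_bundle(small_mt_bundle):
    b = small_mt_bundle
    rng = np.random.default_rng(31)
    noise = SeqRecord("noise", "".join(rng.choice(list("ACGT"), 1000)))
    contigs = b.maxicircles + b.minicircles + [noise]
    classes = {c.contig_id: c for c in classify_contigs(contigs, b.mt_mrnas, b.rrna_transcripts)}
    maxi = classes[b.maxicircles[0].id]
    assert maxi.label == MAXICIRCLE_LIKE
    assert len(maxi.evidence) >= len(b.mt_mrnas)
    for mini in b.minicircles:
        assert classes[mini.id].label == MINICIRCLE_LIKE
    assert classes["noise"].label == UNCLASSIFIED


def test_circularity_duplicated_terminus():
    rng = np.random.default_rng(41)
    circle = "".join(rng.choice(list("ACGT"), 900))
    linearized = circle + circle[:120]
    assert detect_circularity(SeqRecord("c", linearized), 50, 2) == (True, 120)


def test_circularity_with_one_substitution():
    rng = np.random.default_rng(42)
    circle = "".join(rng.choice(list("ACGT"), 900))
    lin = list(circle + circle[:120])
    lin[910] = {"A": "C", "C": "G", "G": "T", "T": "A"}[lin[910]]
    assert detect_circularity(SeqRecord("c", "".join(lin)), 50, 1) == (True, 120)


def test_circularity_negative_on_random_contig():
    rng = np.random.default_rng(43)
    contig = "".join(rng.choice(list("ACGT"), 1000))
    assert detect_circularity(SeqRecord("c", contig), 50, 2) == (False, 0)


def test_circularity_invariant_under_rotation():
    rng = np.random.default_rng(44)
    circle = "".join(rng.choice(list("ACGT"), 600))
    for k in (0, 100, 350, 599):
        rot = circle[k:] + circle[:k]
        lin = rot + rot[:90]
        circ, ov = detect_circularity(SeqRecord("c", lin), 50, 0)
        assert circ and ov == 90


def test_circularity_short_contig_rejected():
    with pytest.raises(ValueError):
        detect_circularity(SeqRecord("c", "ACGT" * 10), 50, 0)
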