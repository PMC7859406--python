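# Methods

This note documents the models and procedures `kinetoedit` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Coordinate and alphabet conventions

All sequences are upper-case DNA over {A, C, G, T, N}; RNA input is
transliterated U→T on read, and reports use the word "U" for
inserted/deleted T's, matching the field's vocabulary.  All intervals are
0-based half-open; 1-based closed coordinates appear only in report columns
suffixed `_1based`.  N never matches anything during alignment scoring (it
is treated as a generic mismatch), a conservative choice for assembly gaps.

## Thymidine-depleted homology search

U-indel editing inserts and deletes only uridines, so a cryptogene and its
mature edited transcript become the *same* string when every T is removed.
`deplete_t` performs that projection and keeps a strictly increasing
position map; `restore_interval` maps depleted-space hits back to original
coordinates.  `tdepleted_search` runs a seed-and-extend local search over
the depleted 3-letter alphabet of both query and database (both database
strands; the subject, never the query, is reverse-complemented so one
coordinate convention holds).  Identity is reported in the search space
(matches / alignment columns, gaps included).  No low-complexity masking is
applied anywhere — depleted sequence is inherently lower-complexity, and
masking would defeat the purpose of the search.

The engine is shared with the standard-space `local_search`: exact k-mer
seeds grouped into diagonal clusters (diagonal drift ≤ band, query gaps
≤ 200 nt), then a banded Smith–Waterman with affine gaps over a window
extending `xdrop + band` nt beyond the outermost seeds.  Defaults: seed
length 10 in depleted space and 12 in standard space (word sizes down to 4
are accepted but generate many seeds), band 15, match +2 / mismatch −3 /
gap −5 open −2 extend, minimum hit length 40 columns, minimum identity 0.7.
Equal-score hits order by subject id, then subject start, for determinism.
There are no E-value statistics: at the scale this package targets
(single organelle genomes, dozens of transcripts) score and identity
thresholds are the interpretable controls.

## Constrained editing alignment

`align_editing` aligns a gene region to a mature mRNA under the operation
set of kinetoplastid editing:

* **U insertion** — column consuming only mRNA, admissible only where the
  mRNA character is T; contiguous insertions form a run.
* **U deletion** — column consuming only gene, admissible only where the
  gene character is T.
* **C→U and A→I substitution** — gene C against mRNA T, and gene A against
  mRNA G (inosine reads as G in cDNA).
* **generic mismatch** — any other pairing; tolerated (scored punitively)
  to absorb sequencing error, and switchable off.

The optimum is computed by an affine three-state dynamic program
(aligned-column state plus insertion-run and deletion-run states), O(n·m)
time and memory, JIT-compiled with numba.  Run cost is
`open + (L−1)·ext`; default scores are match +2, deaminative substitution
−4, generic mismatch −9, open −3 and extend −1 for both run types.  Cheap
run extension reflects the long U-insertion tracts of pan-editing; the
generic mismatch is priced above one substitution-plus-indel pair so it is
used only as a last resort.  The mRNA is always consumed end-to-end; with
`end_free_gene` (the default) the gene region may be entered and left
anywhere at no cost, so a transcript can cover a sub-interval of a padded
gene region.  An admissible alignment must align at least one gene
position; a hypothetical "alignment" consisting purely of inserted U's
(possible only for an all-U mRNA) is reported as unalignable, as is any
input with no admissible path when generic mismatches are disabled —
`align_editing` returns `None` rather than raising.

Among equal-score placements, indel runs inside homopolymers are ambiguous.
Tracebacks are canonicalized by shifting every run to its 5'-most
score-equal admissible position (the analogue of VCF left-normalization),
with insertions ordered before deletions at shared junctions;
`canonicalize` is idempotent and count-preserving.  Event lists record, per
run, the gene position (for insertions: the position *before* which U's are
inserted), the mRNA position, and the run length.  The length-conservation
identity `len(mRNA) == len(gene span) + n_ins − n_del` holds exactly for
every returned alignment, and replaying the event list on the gene
reproduces the mRNA byte-for-byte whenever no generic-mismatch columns are
present.

`oracle_align` is an independent correctness oracle: it enumerates every
admissible alignment explicitly (no memoization, costs summed from the move
sequence) for genes ≤ 10 nt and mRNAs ≤ 12 nt.  The test suite checks DP
optimum == enumeration optimum over hundreds of random pairs in both global
and end-free modes, with generic mismatches on and off.

## Editing statistics

`pct_expansion` is 100·(n_ins − n_del)/gene_len with the *aligned*
gene-region length as denominator (the span the transcript actually
covers).  The pattern classifier splits the gene into 20 bins and calls a
bin edited at ≥ 1 edit site; fewer than 3 sites in total is UNEDITED,
edited bins confined to the first 25% of the gene is FIVE_PRIME, confined
to the first and last 25% is FIVE_AND_THREE_PRIME, and anything more
dispersed is PAN.  The label set is closed, so PAN doubles as the label for
dispersed editing that covers less than 70% of bins; ordering the checks
this way guarantees the ≥70%-coverage case is always PAN while terminal
patterns are never mislabelled.  The named thresholds (20 bins, 25% / 70%,
density 1 site/bin) are package decisions — the pattern classes themselves
are standard field vocabulary, their cutoffs are not standardized.

Deaminative clusters chain substitution events whose consecutive spacing is
≤ 30 nt (the span scale at which clustered C→U/A→I editing is observed in
these organisms) and keep groups of ≥ 3; spans are tight.  Stop-codon
provenance translates the edited mRNA under NCBI translation table 4
(TGA = Trp, the mitochondrial code of these organisms; configurable),
takes the first in-frame stop, and reports whether it overlaps an
inserted-U position or contains a U-deletion boundary.  Species summaries
are arithmetic means and ranges over genes, invariant to gene order.

## Minicircles, backbones, gRNA duplexes, circularity

`classify_contigs` labels a contig MAXICIRCLE_LIKE when a T-depleted
(mRNA) or standard-space (rRNA) homology hit covers ≥ 150 nt of it — long
enough to be a gene region rather than an ~85 nt gRNA cassette —
MINICIRCLE_LIKE when it shares a conserved backbone with ≥ 2 other contigs
and its length falls in the configured range (default 300–2500 bp, wide
enough for both the ~600 bp and the 1.3–2.2 kb minicircle classes observed
in the two study species), and UNCLASSIFIED otherwise.

`find_backbone` runs all-vs-all `local_search` and counts, per position,
the number of distinct partner contigs supporting it.  A position is
supported when it lies in a 20-column alignment window at ≥ the identity
threshold (default 0.90): the short window keeps boundaries sharp —
chance extension of an alignment past the conserved region decays at ~60%
identity and is excluded within a few nucleotides — while isolated private
mutations inside the backbone do not break the run.  Runs of positions
with ≥ `min_share` (default 2) supporters and length ≥ `min_len`
(default 100) are reported.

`find_grnas` detects gRNA cassettes as *ungapped* antisense duplexes
between a minicircle strand and an edited mRNA.  The reverse complement of
the gRNA-bearing strand is colinear with the mRNA, so Watson–Crick pairs
appear as character equality and the two G:U wobble configurations as the
character pairs (C,T) and (A,G).  Candidates are seeded on exact 10-mer
WC matches and extended with x-drop under wc +1 / wobble +0.5 / mismatch
−2.  Mismatch −2 (rather than a milder penalty) matters: pan-edited mRNAs
are U-rich, so random columns pair (WC or wobble) ~37% of the time and a
mild penalty lets extensions wander past the cassette.  Accepted duplexes
need length ≥ 30, a longest-WC-run anchor ≥ 8, and mismatch fraction
≤ 0.1; these operating points were calibrated on simulated cassettes
(85 nt, 5% wobble) against shuffled-minicircle negative controls — 30/8
loses no true cassettes while suppressing the composition-driven chance
duplexes that U-rich transcripts otherwise produce.  Wobble support can be
switched off (`allow_wobble=False`) to mimic a plain nucleotide-identity
search.  Overlapping hits resolve to the best score.

`detect_circularity` reports the longest prefix/suffix self-overlap of
length ≥ `min_overlap` (default 50) with ≤ `max_mismatch` (default 2)
substitutions.  It reports evidence only: a terminal repeat can equally be
an assembly artifact, and the caller, not the function, must judge.

## Spliced leaders and motifs

`detect_sl` searches the transcript's first 40 nt for the best match to any
*suffix* (≥ 10 nt) of any SL reference, because trans-splicing joins the SL
3' end to the mRNA and truncated assemblies retain only a suffix.  Best =
longest match, then fewest mismatches, then TARGET over PREY; an exact
TARGET/PREY tie is AMBIGUOUS, never silently assigned, since the SL
sequences of these organisms and their prey are near-identical.  The
default mismatch tolerance is 1 (sequencing error); tolerance 0 gives the
strict identical-SL criterion.  The reference SL-region string shipped as
the simulator default, `TTACAGTTTCTGTACTT`, is the full 17-nt printed
prokinetoplastid-specific sequence (sometimes described by its 10-bp
diagnostic core; the full string is used here).  `trim_sl` removes a
detected leader before genome mapping — the SL is not genome-encoded, and
untrimmed leaders chance-extend mappings into intergenic sequence, biasing
intergenic distances short.

The motif language covers degenerate stem-loop searches (e.g. the 9S
530-loop and 12S A-loop rRNA landmarks): IUPAC literals with a mismatch
budget, length-range gaps, and paired stems closed reverse-wise under
WC ± G:U with a mispair budget.  `scan_motif` reports all non-overlapping
occurrences on both strands, taking the leftmost-then-shortest match and
resuming past it; hit intervals are in the coordinates of the scanned
strand.  `compare_to_reference` counts stem columns that are identical
versus compensatory (both structures pair, with different nucleotide
pairs) against a reference pairing — the classic evidence for conserved
secondary structure.  Tolerated mispairs count as neither.

## Decontamination, mapping, polarity

A genomic contig is flagged as prey contamination when any local alignment
against a prey reference contains a contiguous stretch of ≥ 100 columns at
≥ 93% identity, both thresholds inclusive, with identity defined as
matches / alignment columns including gaps (the rule does not itself define
the identity denominator; column-wise identity is the common convention of
nucleotide search tools).  The search behind the rule uses match +1 /
mismatch −2 / gap −4 open −2 extend — the classic megablast ratios — so
that flank extensions below ~⅔ identity score negative and cannot leak a
short high-identity segment over the length threshold; the decision itself
is then made on exact column windows of the optimal alignment, making the
boundary behaviour exact (93 matches / 100 columns flags; 92/100 and
93 matches / 99 columns do not).

`map_transcripts` maps unspliced (no split alignments — consistent with
the absence of cis-introns in these genomes) at ≥ 90% identity, reporting
identity, transcript coverage and the best hit per locus.
`polarity_report` orders mapped genes per contig, computes strand runs,
the majority-strand fraction, and intergenic distances
(next.start − prev.end, clipped to 0 and counted when mappings overlap,
so means stay interpretable).

## The synthetic-data generator

`simulate_mt` / `simulate_nuclear` / `simulate_contamination` generate the
study conditions every other module assumes, with complete ground truth.
All randomness flows from one integer seed; identical parameters give
byte-identical FASTA/TSV output.

**Editing.**  Genes are i.i.d. uniform A/C/G/T (GC fraction configurable).
Per gene, a target length expansion is drawn uniformly within ±40% of the
preset mean expansion — implied by the configured mean insertion/deletion
loads and mean gene length — and converted to an insertion total (clipped
to the preset [min, max]); deletion totals draw from a moment-matched
scaled Beta on their range.  Insertion totals are partitioned into runs at
mean length 1/p (geometric parameter p = 0.5 by default, runs mostly 1–6)
over distinct anchor positions.  The mature mRNA is produced by replaying
the sampled events, so the truth round-trip invariant is exact by
construction.

Event placement follows rules that make the truth *recoverable*, i.e. that
prevent the optimal constrained alignment from restructuring events into a
different count:

* gene termini (2 positions each end) are forced non-T and event-free, so
  the alignment is anchored and free end-gaps cannot absorb terminal
  events;
* no insertion anchor within the maximal gene T-run containing a deletion,
  ±2 positions — otherwise the optimum can trade the deleted U against an
  inserted U (or, in dense clusters, against a substitution);
* insertion anchors at least 2 apart — a single aligned gene character
  between two runs can be re-attributed by the DP, merging the runs;
* maxicircle spacers are T-free for 60 nt on each side of a gene, so
  padded gene regions cannot offer chance U's to terminal insertion runs.

These are generator-side constraints on where simulated editing occurs,
not aligner-side tuning; real editing is under no such constraint, so exact
count recovery on simulated data demonstrates the aligner's correctness on
recoverable instances, not that every real editing pattern has a unique
optimal explanation (interleaved insertion/deletion patterns within U-runs
are genuinely ambiguous, for any method).

**Presets.**  `ankaliazontas_like`: 14 genes of 380–570 nt, insertions
389 (166–885) and deletions 29 (13–49) per transcript, pan-editing
dominant (85% PAN / 15% 5'+3'), one 12S-like rRNA carrying the
8 C→U + 4 A→I / 30 nt deaminative cluster and no U-indels, a
circular-mapping maxicircle (120 bp duplicated terminus).
`spiralis_like`: insertions 166 (19–331), deletions 43 (17–80),
terminal-editing dominant, ~600 bp minicircles, SL fraction 0.58, linear
contigs.  Minicircles share one conserved backbone and each carry one
85-nt cassette: the reverse complement of a random edited-mRNA window with
5% of its pairs converted to G:U wobble.  Nuclear contigs carry same-strand
gene clusters (15 genes by default) with fixed 76-nt intergenic spacing
(a geometric-jitter option exists but is off by default, so spacing
statistics are exact test targets); transcripts carry the SL prefix with
probability `sl_fraction` (default 0.70).  Contaminated contigs embed
prey segments (default 120 nt at 95% identity) whose mutations are
stratified across the segment — the realized divergence of any
sub-window then tracks the configured identity, which makes behaviour at
the 93%/100 bp decontamination boundary deterministic rather than
subject to Bernoulli sampling noise.

**What the simulator does not emulate:** read-level error and coverage,
assembly fragmentation and chimerism, partially edited intermediates and
misediting, gRNA populations per cassette, codon structure in nuclear
genes, and real base-composition structure (beyond a global GC knob).
Passing the recovery tests therefore validates algorithmic correctness
under the stated statistical structure, not performance on raw sequencing
data.

## Pipeline

`run_pipeline` executes decontaminate → classify mitochondrial contigs →
locate cryptogenes (T-depleted search, falling back to standard space for
unedited transcripts) → reconstruct editing (gene region = best hit ± 30 nt
padding; minus-strand regions reverse-complemented) → statistics →
gRNA detection → SL detection → SL-trimmed mapping and polarity, from one
YAML config with typed, unknown-key-rejecting parameter blocks.  rRNA
transcripts get per-gene rows but are excluded from the species U-indel
summary.  Every stage writes TSV artifacts; a manifest records the package
version, all effective parameters and input checksums.  The pipeline draws
no random numbers, so re-running identical inputs reproduces identical
bytes (tested).  Single-process by design: the data are desk-scale and
determinism is worth more than parallel speed.

## Problem sizes used in validation

The shipped tests and the acceptance script run entirely on simulated
data at the preset scales: 14 genes (~0.5 kb each, ~10 kb maxicircle),
10–50 minicircles of ~0.6 kb, 1000 transcripts for SL statistics, 15-gene
nuclear clusters, and 200 random pairs (gene ≤ 8 nt) for oracle
equivalence — sizes chosen so the full validation completes in minutes on
one CPU while every check retains its statistical meaning (binomial
bounds are computed at the actual n).

## Known limitations

* The editing aligner reports one optimal alignment; count ambiguity
  between score-equal explanations is resolved by canonical left-shift,
  not enumerated.
* The seed-and-extend searches have no significance statistics; thresholds
  are score/identity/length based.
* gRNA detection is ungapped; bulged gRNA:mRNA duplexes are out of scope.
* SL attribution relies on the provided reference set; it cannot flag a
  prey SL absent from it.
* `detect_circularity` cannot distinguish a genuine circle from an
  assembler-duplicated terminus.
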