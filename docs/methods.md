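# Methods

## Gene model and coordinates

All internal coordinates are 0-based half-open; GTF (1-based inclusive) and
UCSC rmsk / BED (0-based) dialects are converted at the file boundary so no
off-by-one arithmetic leaks into the analysis.  A gene model is an ordered
list of labelled exons with rational gene-order positions: canonical exons
take integers 1…n, a novel exon written `kN j` takes a position strictly
inside (k, k+1) and increasing in j, and the alternative terminal exons
`13a`/`13b` both sit at position 13 (they are alternative 13th exons, not
extra gene-order positions).  Intron *i* is the gap between canonical exons
*i* and *i+1*; a model with n canonical exons has exactly n−1 introns, and
intron statistics are computed over canonical introns only.  Minus-strand
genes are supported by mirroring gene order against genomic order.

The bundled 19-exon locus model (`anril_19exon_model.synthetic.gtf`) anchors
every exon boundary that appears in the published skipped-exon event
coordinates; the eight boundaries never printed (exon 1, exon 2 start,
exon 4 end, exon 5, exon 6 start, exon 13 end, exon 17 end, exon 19 end)
are synthetic fill-ins chosen to respect the anchored sites, and the file
says so per exon.  Every computation that feeds a reported number depends
only on anchored boundaries.

## Circle catalogues

A catalogue entry is the exon path seen from one outward-facing primer,
wrapping around the circle (`4-5-6-9-10-4 (10-4)`).  The junction derived
from the written path is (second-to-last label, first label).  When a
bracketed junction is also printed it is trusted as the junction call
whenever it is a feasible wrap point of the written cycle (the cycle is
rotated to it and the disagreement logged) — this handles entries whose
written rotation starts elsewhere, e.g. `14-5-6-14 (14-5)`.  A bracket
that cannot be a wrap point (a label absent from the path) is logged and
the derived junction kept.  Both bracket dialects are supported:
donor-acceptor (tables) and acceptor-donor (prose).

Canonical form rotates the cycle so the acceptor exon is first and the
donor last; isoform identity is the pair (canonical cycle, junction), so
circles with the same exon set but different junctions stay distinct, and
the same circle detected from different primer rows compares equal.
Deduplication within a cell line merges identical identities; the rule is
exposed as an option because the published total isoform count is not
recoverable from the printed catalogue under any single obvious rule
(canonical dedup yields 35 + 15 distinct circles and five shared ones).

The precursor span of a circle runs from its acceptor-side-most to its
donor-side-most exon: the included introns are
{i : ⌊min ordinal⌋ ≤ i < ⌈max ordinal⌉}, clipped to canonical introns.
Inclusion counts and intron lengths are each scaled by their maximum into
[0, 1]; exon abundance is the per-exon isoform count scaled by the most
abundant exon per cell line.  For "junctions involving an intron" no
published definition exists, so both site conventions are implemented
explicitly (a junction's donor site feeds intron ⌊ordinal(donor)⌋, its
acceptor site drains intron ⌈ordinal(acceptor)⌉−1) and the caller picks
donor / acceptor / either.

## Alignment and inverted-pair detection

Repeat elements are read from UCSC rmsk (16/17 column) or BED6 tracks,
filtered by a class/family/name regex (default `Alu`), and assigned to the
intron or exon containing at least `min_overlap_frac` of their length
(default 1.0 — full containment; boundary straddlers are reported but not
counted, which cannot distort counts because Alu elements are an order of
magnitude shorter than typical introns).

Inverted-pair detection aligns, for every intron pair i &lt; j and repeat
pair (a ∈ i, b ∈ j), the forward genomic sequence of a against the reverse
complement of b, using global (end-gap penalized) affine-gap alignment via
the three-state Gotoh recurrence (numba-compiled; `N` scores as a
mismatch).  A gap of length L costs `gap_open + L·gap_extend`.  A pair is
accepted when the score reaches `min_score` (default −200).  Same-intron
pairs are never tested — they cannot bracket a back-splice.

The substitution/gap scale behind the published −200 threshold is not
recorded anywhere, so the defaults are declared, not inferred: match +2,
mismatch −6, gap open −10, gap extend −4.  This scale was chosen so the
threshold is meaningful for Alu-length sequences: a perfect 300 bp
reverse-complement pair scores +600, the −200 acceptance boundary sits near
one-third divergence (comfortably containing the 10–20 % divergence typical
between Alu family members), and two unrelated random 300-mers score around
−800, far below threshold — detection is sharp rather than vacuous.  With
cheap-gap scales (e.g. match +1, extend −0.5) random 300-mers align with
*positive* expected score and a −200 floor would accept everything, which
is why such defaults were rejected.  All five scoring parameters are
configurable on every API and CLI entry point.

A detected pair across introns (i, j) predicts donor exon j and acceptor
exon i+1 (i+1 = j is a single-exon circle); one supporting pair suffices,
and predictions never involve novel exons (repeat data has no sub-exon
resolution).  Observed junctions are partitioned exactly into explained
(junction equality with a prediction) and unexplained; comparison is at
junction level, matching how candidate mechanisms are confirmed.

Repeat-count–vs–intron-length association uses Spearman and Pearson
correlations from scipy with two-sided p-values; no multiple-testing
correction is applied (a single pair of tests per run).

## Exon skipping

SE events use the SUPPA-style identifier `GENE;SE:chrom:e1-s2:e2-s3:strand`
with e1 = upstream flank end, (s2, e2) = skipped exon, s3 = downstream
flank start, strictly ordered.  The candidate circle exon set is every
canonical exon with start ≥ e1 and end ≤ s3 — always a contiguous run, and
monotone in the flanks.  A candidate matches an observed circle only when
the exon sets are equal ("completely matched"); junction agreement is
implied because a skipping-derived circle of exons a…b forces junction
(b, a).  Generating SE events from an annotation is out of scope: events
are consumed as text, with the published locus events bundled (two printed
events share one candidate set and are kept as separate events).

## Synthetic data

The simulator emulates the analysed locus rather than a realistic genome:
19 exons (log-normal lengths, median 150 bp, σ_log 0.5, floor 60 bp) and
introns with log-normal lengths (median 1.5 kb, σ_log 1.15, floor 700 bp)
whose central mass spans roughly two orders of magnitude, so the
"long intron, many repeats" regime exists.  Repeats are 300 bp (Alu
length).  A planted inverted pair (i, j, d) inserts a random 300-mer into
intron i and its reverse complement, with a fraction d of positions
substituted, into intron j; background repeats are independent random
300-mers.  Placement partitions each intron into equal slots with a 10 bp
pad; a configuration whose repeats cannot fit raises rather than silently
reshaping the locus.  Circles are generated with ground-truth mechanism
labels: *alu* circles are the contiguous runs bracketed by planted pairs,
*skipping* circles equal the candidate set of a generated SE event (flanked
by real model exons), *random* circles are exon subsets re-sampled until
their junction collides with neither mechanism.  One seeded generator
drives everything; identical seed and config give byte-identical files, and
every emitted file re-parses through the package's own readers.

What passing the simulation tests does **not** show: real intron sequence
composition (planted repeats are exact or uniformly mutated copies, not
diverged Alu consensus families), detection sensitivity under indel-rich
divergence, or behaviour on overlapping/nested gene annotation.  The
fixtures-based results stand on the printed catalogue and coordinates, not
on the simulator.

## Problem sizes and numerics

Simulation-based checks use 20 seeds with the default locus dimensions
(~50–100 kb of sequence, ≤ 6 cross-intron alignments per locus); the
alignment kernel is O(|a|·|b|) per pair and exact, with scores reproduced
against exhaustive enumeration for short sequences and against an
independent global aligner for longer ones.  Correlation helpers refuse
constant input (undefined coefficients) and fewer than three introns.
Degenerate circles (single-exon paths like `7-7`) are legal everywhere;
empty catalogues and empty sequences raise explicit errors rather than
returning silent zeros.

## Known limitations

* The bundled locus model is a reconstruction: coordinates not printed in
  the published event table are synthetic fill-ins, so absolute intron
  lengths (e.g. scaled-length plots) for unanchored introns are indicative
  only.
* Real-data per-intron Alu counts require a user-supplied UCSC rmsk extract
  and annotation (see the optional integration test); they are not
  redistributable here.
* Alignment is score-only (no traceback); the analysis needs scores, not
  alignments.
* Junction explanation is necessary-condition reasoning: a predicted
  junction shows an inverted pair *could* bracket the circle, not that it
  did.
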