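# circanril

Structural analysis of circular RNA isoform catalogues at the ANRIL
(*CDKN2B-AS1*) locus: back-splice junction bookkeeping, inverted intronic
Alu-pair detection, and exon-skipping compatibility testing.

## The problem

ANRIL is a long non-coding RNA antisense to the *CDKN2A/B* tumour-suppressor
locus on chromosome 9p21, with 19 canonical exons.  Besides linear
transcripts it produces covalently closed circles (circANRIL) whose
non-canonical, head-to-tail **back-splice junctions** — written here as
(donor exon, acceptor exon), e.g. 14-5 — vary widely between cell lines.
Two mechanisms are commonly invoked to explain where back-splices form:

1. **Inverted Alu repeats** — two ~300 bp Alu elements in *different*
   introns, one the (approximate) reverse complement of the other, can
   base-pair in the pre-mRNA and bracket a circle.  An inverted pair across
   introns *(i, j)*, *i < j*, brackets exons *i+1 … j* and therefore
   predicts the junction *(j, i+1)*.
2. **Exon skipping** — a skipped-exon (SE) event whose flanking splice
   sites span a run of exons could release that run from a lariat as a
   circle; a circle of exons *a … b* produced this way must carry exactly
   that exon set (and junction *(b, a)*).

This package implements the desk side of testing both hypotheses against an
observed circle catalogue:

* parse circle catalogues written as exon paths
  (`4-5-6-9-10-4 (10-4)`), canonicalize rotations, deduplicate
  primer-route detections, and compute exon-abundance, intron-inclusion and
  junction tallies per cell line;
* build an exon/intron gene model from GTF/GFF3 or BED12, assign
  Alu-class repeats (UCSC rmsk or BED6 tracks) to introns and exons, detect
  cross-intron reverse-complement repeat pairs by affine-gap global
  alignment (Gotoh DP, acceptance threshold on the score), and classify
  observed junctions as Alu-explained or not;
* parse SE events in the SUPPA-style dialect
  (`GENE;SE:chr9:22029593-22032673:22032985-22046316:+`), derive each
  event's candidate circle exon set, and match candidates against the
  catalogue;
* simulate seeded loci, genomes, repeat tracks and mechanism-labelled
  circle catalogues so the whole pipeline is testable against planted
  ground truth without downloads.

Bundled fixtures: the published NZM7/NZM37 melanoma circANRIL catalogue,
the SE events reported at the locus, and a 19-exon locus model whose splice
boundaries are anchored to the printed SE coordinates (unprinted boundaries
are synthetic fill-ins and flagged as such in the file).

## Worked example

```python
>>> import circanril as ca
>>> model = ca.anril_gene_model()
>>> cat = ca.nzm_catalogue().deduplicated()
>>> sorted(len(cat.line(c)) for c in cat.cell_lines)
[15, 35]
>>> shared = ca.common_isoforms(cat.line("NZM7"), cat.line("NZM37"))
>>> shared
[CircIsoform(4-5-6 (6-4)), CircIsoform(4-5-6-7 (7-4)), CircIsoform(4-5-6-7-14 (14-4)), CircIsoform(5-6-14 (14-5)), CircIsoform(5-6-7-13-14 (14-5))]
```

After deduplication the two cell lines keep 35 and 15 distinct circles and
share only five — the two catalogues are almost completely different.
Testing the inverted-Alu hypothesis against the reported intron pairs with
reverse-complement Alu elements:

```python
>>> from circanril.repeat_analysis import junction_for_intron_pair
>>> pairs = [(1,14), (1,12), (1,11), (6,11), (7,11), (1,6), (6,7), (5,7), (1,5)]
>>> predicted = [junction_for_intron_pair(i, j) for i, j in pairs]
>>> observed = {iso.junction for iso in cat.all_isoforms()}
>>> explained, unexplained = ca.classify_observed_junctions(observed, predicted)
>>> sorted(explained), len(unexplained)
([('6', '2'), ('7', '6')], 20)
```

Only 2 of the 22 observed junctions (6-2 and 7-6) coincide with a junction
an intronic inverted Alu pair could bracket.  The exon-skipping route fares
no better:

```python
>>> events = ca.anril_se_events()
>>> candidates = [(e, ca.potential_circ_exons(e, model)) for e in events]
>>> ca.match_skipping_to_catalogue(candidates, cat)
[]
```

None of the 12 SE events' candidate exon sets completely matches any
observed circle, so neither mechanism accounts for the observed back-splice
junctions.

The same analyses are available from the shell:

```bash
circanril catalogue --out reports/            # bundled catalogue statistics
circanril skipping  --out reports/            # SE candidates vs catalogue
circanril simulate  --seed 5 --out sim/       # synthetic dataset
circanril alu --annotation sim/model.gtf --gene-id SIMGENE \
    --genome sim/genome.fa --repeats sim/repeats.rmsk.tsv \
    --catalogue sim/catalogue.tsv --out reports/alu
```

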