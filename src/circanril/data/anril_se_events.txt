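# Skipped-exon (SE) events at the ANRIL / CDKN2B-AS1 locus, in the
# SUPPA-style event-identifier dialect GENE;SE:chrom:e1-s2:e2-s3:strand,
# where e1 = end of the upstream flanking exon, s2/e2 = bounds of the
# skipped exon, s3 = start of the downstream flanking exon.
# One event per line. Two published events share a candidate exon set and
# are kept as separate lines.
CDKN2B-AS1;SE:chr9:22029593-22032673:22032985-22046316:+
CDKN2B-AS1;SE:chr9:22049227-22056251:22056386-22077678:+
CDKN2B-AS1;SE:chr9:22049227-22056251:22056386-22112319:+
CDKN2B-AS1;SE:chr9:22049227-22097257:22097363-22112319:+
CDKN2B-AS1;SE:chr9:22049227-22056251:22056386-22120199:+
CDKN2B-AS1;SE:chr9:22049227-22120199:22120409-22120503:+
CDKN2B-AS1;SE:chr9:22056386-22058358:22059053-22061952:+
CDKN2B-AS1;SE:chr9:22056386-22061952:22062025-22063943:+
CDKN2B-AS1;SE:chr9:22056386-22063943:22064017-22077678:+
CDKN2B-AS1;SE:chr9:22064017-22065661:22065756-22066234:+
CDKN2B-AS1;SE:chr9:22064017-22066234:22066352-22077678:+
CDKN2B-AS1;SE:chr9:22112394-22113665:22113798-22118643:+
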