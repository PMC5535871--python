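# Circular ANRIL isoforms detected with outward-facing primers in the NZM7
# and NZM37 melanoma cell lines, transcribed from the published catalogue.
# primer_row names the exon the outward-facing primer pair targeted; the
# bracketed pair in isoform_path is the reported back-splice junction
# (donor-acceptor order). Duplicate rows are detection routes, not distinct
# molecules; deduplication happens downstream.
cell_line	primer_row	isoform_path
NZM7	Exon 2	2-5-6-2
NZM7	Exon 4	4-5-6-9-10-4 (10-4)
NZM7	Exon 4	4-5-6-7-10-12-4 (12-4)
NZM7	Exon 4	4-5-6-7-4 (7-4)
NZM7	Exon 4	4-5-6-13-14-4 (14-4)
NZM7	Exon 4	4-5-6-10-13-14-4 (14-4)
NZM7	Exon 4	4-5-13-14-4 (14-4)
NZM7	Exon 4	4-5-6-12-13-14-4 (14-4)
NZM7	Exon 4	4-5-6-13-14-4 (14-4)
NZM7	Exon 4	4-5-6-4 (6-4)
NZM7	Exon 4	4-5-6-10-11-12-4 (12-4)
NZM7	Exon 6	6-4-5-6 (6-4)
NZM7	Exon 6	6-14-5-6 (14-5)
NZM7	Exon 6	6-7-9-10-6 (10-6)
NZM7	Exon 6	6-9-10-5-6 (10-5)
NZM7	Exon 6	6-10-2-5-6 (10-2)
NZM7	Exon 6	6-9-6 (9-6)
NZM7	Exon 6	6-4(N1)-4(N2)-5-6 (6-4N1)
NZM7	Exon 6	6-4(N2)-4-5-6 (6-4N2)
NZM7	Exon 6	6-7-5-6 (7-5)
NZM7	Exon 6	6-7-6 (7-6)
NZM7	Exon 6	6-14-6 (14-6)
NZM7	Exon 6	6-10-5-6 (10-5)
NZM7	Exon 7	7-5-6-7 (7-5)
NZM7	Exon 8	8-5-6-8 (8-5)
NZM7	Exon 8	8-5-6-7-8 (8-5)
NZM7	Exon 8	8-9-10-5-6-7-8 (10-5)
NZM7	Exon 8	8-13-14-5-6-8 (14-5)
NZM7	Exon 8	8-10-13-14-5-6-8 (14-5)
NZM7	Exon 14	14-4-5-6-7-14 (14-4)
NZM7	Exon 14	14-4-5-6-14 (14-4)
NZM7	Exon 14	14-5-6-13N1-13-14 (14-5)
NZM7	Exon 14	14-5-6-7-13-14 (14-5)
NZM7	Exon 14	14-16-13N1-13-14 (16-13N1)
NZM7	Exon 16	16-15-16 (16-15)
NZM7	Exon 16	16-5-6-7-13-14-15-16 (16-5)
NZM7	Exon 16	16-6-7-13-14-15-16 (16-4)
NZM7	Exon 16	14-15-16-19-5-6-10-13-14 (19-5)
NZM7	Exon 16	16-5-6-7-13-14-15-16 (16-5)
NZM37	Exon 4	4-5-6-7-4 (7-4)
NZM37	Exon 4	4-5-6-7-13-14-4 (14-4)
NZM37	Exon 6	6-7-10-4-5-6 (10-4)
NZM37	Exon 6	6-7-10-5-6 (10-5)
NZM37	Exon 6	6-14-5-6 (14-5)
NZM37	Exon 6	6-7-9-10-5-6 (10-5)
NZM37	Exon 6	6-4-5-6 (6-4)
NZM37	Exon 14	14-5-6-14 (14-5)
NZM37	Exon 14	14-5-6-13-14 (14-5)
NZM37	Exon 14	14-4-5-6-7-14 (14-4)
NZM37	Exon 14	14-5-6-7-13-14 (14-5)
NZM37	Exon 14	14-4-5-6-7-9-14 (14-4)
NZM37	Exon 14	14-4-5-6-7-13-14 (14-4)
NZM37	Exon 14	14-5-6-7-10-13-14 (14-5)
NZM37	Exon 14	14-5-6-7-9-10-13-14 (14-5)
NZM37	Exon 14	14-4-5-6-7-10-13-14 (14-4)
NZM37	Exon 14	14-5-6-7-10-12-13-14 (14-5)
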