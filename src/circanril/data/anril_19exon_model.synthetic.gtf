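# 19-exon model of the ANRIL / CDKN2B-AS1 locus, hg19 chr9, + strand.
# SYNTHETIC RECONSTRUCTION: splice boundaries that appear in the published
# skipped-exon event coordinates for this locus are anchored verbatim
# (exon 2 end; exons 3, 7, 8, 9, 10, 11, 12, 14, 15, 16, 18 in full;
# exon 4 start; exon 6 end; exon 13 start; exon 17 start; exon 19 start).
# The remaining boundaries (exon 1 both ends, exon 2 start, exon 4 end,
# exon 5 both ends, exon 6 start, exon 13 end, exon 17 end, exon 19 end)
# are synthetic fill-ins consistent with the anchored sites and the known
# overall span of the locus; they are NOT measured values.
chr9	circanril	exon	21994791	21995300	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "1"; anchored "none";
chr9	circanril	exon	22029258	22029593	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "2"; anchored "end";
chr9	circanril	exon	22032674	22032985	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "3"; anchored "both";
chr9	circanril	exon	22046317	22046422	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "4"; anchored "start";
chr9	circanril	exon	22047005	22047134	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "5"; anchored "none";
chr9	circanril	exon	22048269	22049227	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "6"; anchored "end";
chr9	circanril	exon	22056252	22056386	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "7"; anchored "both";
chr9	circanril	exon	22058359	22059053	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "8"; anchored "both";
chr9	circanril	exon	22061953	22062025	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "9"; anchored "both";
chr9	circanril	exon	22063944	22064017	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "10"; anchored "both";
chr9	circanril	exon	22065662	22065756	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "11"; anchored "both";
chr9	circanril	exon	22066235	22066352	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "12"; anchored "both";
chr9	circanril	exon	22077679	22078432	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "13"; anchored "start";
chr9	circanril	exon	22097258	22097363	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "14"; anchored "both";
chr9	circanril	exon	22112320	22112394	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "15"; anchored "both";
chr9	circanril	exon	22113666	22113798	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "16"; anchored "both";
chr9	circanril	exon	22118644	22118892	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "17"; anchored "start";
chr9	circanril	exon	22120200	22120409	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "18"; anchored "both";
chr9	circanril	exon	22120504	22121097	.	+	.	gene_id "CDKN2B-AS1"; transcript_id "CDKN2B-AS1.1"; exon_label "19"; anchored "start";
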