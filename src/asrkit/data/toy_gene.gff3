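##gff-version 3
# Toy 33-bp gene with three mRNA isoforms (coding lengths 16, 9, 19 bp)
# sharing a 25-bp coding footprint: ASR = (16 + 9 + 19) / 25 = 1.76
chr1	asrkit	gene	1	33	.	+	.	ID=toy_gene;gene_biotype=protein_coding
chr1	asrkit	mRNA	1	16	.	+	.	ID=mRNA1;Parent=toy_gene
chr1	asrkit	CDS	1	16	.	+	0	ID=cds1;Parent=mRNA1
chr1	asrkit	mRNA	25	33	.	+	.	ID=mRNA2;Parent=toy_gene
chr1	asrkit	CDS	25	33	.	+	0	ID=cds2;Parent=mRNA2
chr1	asrkit	mRNA	1	33	.	+	.	ID=mRNA3;Parent=toy_gene
chr1	asrkit	CDS	1	10	.	+	0	ID=cds3;Parent=mRNA3
chr1	asrkit	CDS	25	33	.	+	2	ID=cds3;Parent=mRNA3
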