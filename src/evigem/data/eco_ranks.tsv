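# Evidence and Conclusion Ontology (ECO) accessions mapped to support ranks.
# rank: experimental | similarity | other
# Edit or extend this table to tune support classification; unknown codes
# are treated as "other" with a warning.
eco_code	rank	label
ECO:0000269	experimental	experimental evidence used in manual assertion
ECO:0000314	experimental	direct assay evidence
ECO:0000315	experimental	mutant phenotype evidence
ECO:0000316	experimental	genetic interaction evidence
ECO:0000270	experimental	expression pattern evidence
ECO:0000353	experimental	physical interaction evidence
ECO:0001055	experimental	enzyme activity assay
ECO:0000006	experimental	experimental evidence
ECO:0000250	similarity	sequence similarity evidence used in manual assertion
ECO:0000044	similarity	sequence similarity evidence
ECO:0000031	similarity	BLAST evidence used in manual assertion
ECO:0000266	similarity	sequence orthology evidence
ECO:0000247	similarity	sequence alignment evidence
ECO:0000255	other	match to sequence model evidence
ECO:0000259	other	match to InterPro member signature
ECO:0000303	other	non-traceable author statement
ECO:0000305	other	curator inference
ECO:0000501	other	inferred from electronic annotation
ECO:0000053	other	computational combinatorial evidence
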