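# Published study inputs (not distributed)

The study-scale reproduction test
(`tests/test_acceptance.py::test_published_study_reproduction`) consumes
the supplementary data files of the published analysis this package
reimplements. They are distributed by the journal and cannot be shipped
here. To run the test, download them and place them in this directory as:

- `study_proteins.fasta` — the 727 homolog protein sequences.
- `study_cds_alignment.fasta` — the codon alignment of the 727 CDS
  sequences (951 retained sites after trimming at gap threshold 0.3).
- `study_gene_tree.nwk` — the 727-leaf maximum-likelihood gene tree with
  ultrafast-bootstrap supports, leaves labelled `<gene>_<species>`.
- `clades.tsv` — species → clade table (columns `species`, `clade`;
  labels A/B/D/F) following the published species phylogeny.
- `loci.bed`, `pairs.tsv` — gene coordinates (BED6) and BLAST tabular
  homolog pairs for the eight representative genomes.

Without these files the test fails with a pointer to this document; every
other test in the suite is self-contained.
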