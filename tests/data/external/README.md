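Place here, to enable the accession-dependent conservation comparison:

- `rbs1.fa`    — S. cerevisiae Rbs1 protein sequence (FASTA)
- `r3hdm2.fa`  — human R3H domain-containing protein 2, accession XP_011536342.1 (FASTA)

These are real database sequences and are not bundled; fetch them by
accession (e.g. NCBI efetch). Without them the corresponding test fails
with an explanatory message.
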