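# Supplementary alignment files (not bundled)

Place the four journal supplementary alignment files here to enable the
deterministic reproduction tests and the full acceptance report:

    Supp1_Krill_COI_fasta.txt     mitochondrial cox-1 (both species)
    Supp2_Krill_Hsp70A_fasta.txt  hsp70 paralog A
    Supp3_Krill_Hsp70B_fasta.txt  hsp70 paralog B
    Supp4_Krill_Hsp70C_fasta.txt  hsp70 paralog C

Alternatively set the environment variable `POLYDIV_DATA` to a directory
containing them. The per-allele GenBank accessions are KT586430-KT586614
(gene accessions KM067139-KM067147); the label parser accepts
`EC##_All#` / `ES##_All#` style names (see `polydiv.alignment`,
`DEFAULT_LABEL_SCHEMA`).
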