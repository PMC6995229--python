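# Published inputs (not redistributed)

The published-data acceptance checks in `tests/test_acceptance.py` expect
the original 12-line dataset here. The sequence data are deposited in
GenBank (accessions MK862365–MK862404; reference gene AJ228921); the
delta-Ct expression table is distributed with the original study's
supplementary material. None of these files ship with this package, so
those checks fail until you provide:

| file                  | content                                                         |
|-----------------------|-----------------------------------------------------------------|
| `five_prime_A.fasta`  | alignment of the 12 hsp70A proximal promoters                   |
| `five_prime_B.fasta`  | alignment of the 12 hsp70B proximal promoters                   |
| `three_prime_A.fasta` | alignment of the 12 hsp70A 3'UTRs                               |
| `three_prime_B.fasta` | alignment of the 12 hsp70B 3'UTRs                               |
| `metadata.csv`        | columns `id,line,arrangement,gene_copy`; line ids `OST_1..6`, `O347_1..6` |
| `delta_ct.csv`        | columns `line,arrangement,sex,bio_rep,delta_ct` (67 rows)       |
| `rp49_gene.fasta`     | the rp49 reference-gene genomic sequence (AJ228921)             |

The mapping from accession to (line, gene copy) is not encoded in the
deposited ids and must be supplied in `metadata.csv` by the user.
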