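# External reference inputs (not redistributed)

Three acceptance checks in `tests/test_acceptance.py` compare against
published reference data that cannot ship with this package. To run them,
place the following files here:

| file | content |
| --- | --- |
| `fh_cds.fasta` | the 3639 nt human complement factor H construct CDS (single FASTA record) |
| `fh_isoform_protein.fasta` | the truncated factor H isoform protein sequence (single FASTA record) |
| `ppatens_v3.3.gff3` | *Physcomitrium patens* v3.3 genome annotation (Phytozome) |
| `ppatens_v3.3.fa` | *P. patens* v3.3 genome assembly FASTA (Phytozome) |

Without these files the corresponding tests fail with a message pointing
here; every other test runs on packaged tables and generated fixtures.
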