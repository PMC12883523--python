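# Optional reference sequences

The printed-value acceptance targets compare against published subunit
sequences that must be downloaded once (they are not redistributed here).
Drop plain single-record FASTA files at the paths below and both
`tests/test_acceptance.py` and `scripts/acceptance.py` will pick them up;
without them those targets are skipped/omitted.

```
data/uniprot/A8ZMJ4.fasta     # A. marina PC alpha-1
data/uniprot/A8ZMJ6.fasta     # A. marina PC alpha-2
data/uniprot/A8ZMJ5.fasta     # A. marina PC beta-1
data/uniprot/A8ZMJ7.fasta     # A. marina PC beta-2
data/platensis/cpcA.fasta     # A. platensis PC alpha (mature chain)
data/platensis/cpcB.fasta     # A. platensis PC beta (mature chain)
data/platensis/apcA.fasta     # A. platensis APC alpha (mature chain)
data/platensis/apcB.fasta     # A. platensis APC beta (mature chain)
```

UniProt entries can be fetched with e.g.

```
curl -o data/uniprot/A8ZMJ4.fasta https://rest.uniprot.org/uniprotkb/A8ZMJ4.fasta
```
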