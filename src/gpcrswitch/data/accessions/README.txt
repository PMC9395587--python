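Drop externally fetched inputs here (or run `gpcrswitch fetch-data`):

  5TGZ.pdb  5XRA.pdb        crystal structures (https://files.rcsb.org/download/<ID>.pdb)
  P21554.fasta P20272.fasta F1MAK4.fasta Q08BG4.fasta Q9Y2T6.fasta
                            UniProt canonical sequences
                            (https://rest.uniprot.org/uniprotkb/<ACC>.fasta)

These files are required only by the crystal/sequence worked examples
(tests marked `requires_accessions` and acceptance targets t1-t7); the
rest of the package and test suite is fully offline.
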