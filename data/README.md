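# External data

Place the deposited nucleosome crystal structure here to enable the
CSA validation path:

* `1KX5.pdb` — download from the PDB (https://www.rcsb.org/structure/1KX5)
  and save in legacy PDB format. The file is not redistributed with this
  repository.

With the file present, `tests/test_acceptance.py` runs the chain A / E
contact-surface-area validation and `scripts/acceptance.py` reports
targets t1/t2. Alternatively set the environment variable
`TAILENSEMBLE_1KX5` to the file's path.
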