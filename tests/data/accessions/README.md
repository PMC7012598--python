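# Deposited structures for the integration tests

The crystal-structure integration tests in `tests/test_acceptance.py`
read local copies of the deposited CK1δ entries from this directory:

- `1ckj.pdb` — wild-type CK1δ ΔC, activation loop "up" in chain A and
  "down" in chain B
- `6pxn.pdb` — tau (R178C) CK1δ ΔC, same chain assignment

Fetch them on a machine with network access:

```python
from ck1switch.accessions import fetch_pdb
fetch_pdb("1CKJ", "tests/data/accessions")
fetch_pdb("6PXN", "tests/data/accessions")
```

Without these files the two tests fail with a message pointing here; no
other test touches the network or this directory.
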