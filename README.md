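# musekit

**DNA communication: keyboard ciphers, secret sharing across strands, and
multiplexed Sanger chromatogram patterning.**

musekit is a toolkit for writing short messages into synthetic DNA,
splitting them across several molecules, and reading them back from a
single multiplexed sequencing reaction.  It is aimed at researchers in DNA
data storage and biosecurity-adjacent steganography who want a complete,
testable in-silico model of the pipeline.

It implements three pieces:

* **iKey-64** — a 64-button keyboard ↔ codon bijection used as a
  substitution cipher.  The 4³ = 64 codons split into three structural
  categories — all bases distinct (24), first = third (12), adjacent repeat
  (28) — and frequent characters get the repeat-free codons, so encoded
  text never contains a homopolymer run longer than 4 bases (digits: 2).
  Shuffling codons within categories gives 24!·12!·28! ≈ 9.1×10⁶¹ personal
  keyboard variants.
* **MuSE** (Multiplexed Sequence Encoding) — a secret-sharing composer that
  fragments a message *m* and a decoy *d* across N strands.  Consecutive
  pairs (n1+n2, n3+n4, …) share the message fragments; the circularly
  shifted pairs (n2+n3, …, nN+n1) share the decoy.  A Pascal's-triangle
  combination key names the correct pairs; watermark codons identify
  strands; even strands are reverse-complemented as camouflage.
* **Chromatogram patterning** — an in-silico Sanger co-sequencing simulator
  and decoder.  Templates mixed in one reaction contribute
  concentration-weighted peak intensities; positions where pair partners
  agree form large homogeneous peaks, the 3-nt spacer codons (space1 = AGT
  vs space2 = CTA) form heterogeneous troughs at word boundaries, and the
  decoder recovers the embedded words from that pattern alone.

The wet-lab-validated construct sequences (the 212-nt keyboard record, the
two-strand message pair DNA-1/DNA-2, the six WWII communication strands
n1–n6, and the four sequencing primers) ship as checksum-verified fixtures.

## Worked example

```python
from musekit import (
    Communication, TemplateMix, build_reference_ikey, build_strands,
    decode_pattern, encode_chars, load_fixture, simulate_cosequencing,
)

ikey = build_reference_ikey()
print(encode_chars("VK", ikey, shift_policy=False))   # GTTTTC   (run of 4 Ts)
print(encode_chars("110011", ikey))                   # AGCAGCCTGCTGAGCAGC

comm = Communication(message="Bletchley Park: GC&CS Codebreakers",
                     decoy="Captain Ridley's Shooting Party", ikey=ikey)
strands = build_strands(comm, filler_seed=2)

pooled = TemplateMix([(s, 1.0) for s in strands])
key_trace = simulate_cosequencing(pooled, load_fixture("Primer_Key"))
print(" ".join(decode_pattern(key_trace, ikey).decoded_words))
# Pascal's triangle: d2r6-reverse
```

The same workflow is available from the shell; `musekit demo-wwii --seed 2`
prints:

```
combination key (pooled, Primer_Key): Pascal's triangle: d2r6-reverse
message pair n1+n2: Bletchley Park:
message pair n3+n4: GC&CS
message pair n5+n6: Codebreakers
message: Bletchley Park: GC&CS Codebreakers
decoy pair n2+n3: Captain Ridley's
decoy pair n4+n5: Shooting
decoy pair n6+n1: Party
decoy: Captain Ridley's Shooting Party
...
```

Reading the pooled strands with the key primer reveals only the combination
key (the message regions stay heterogeneous); resolving it names the pairs
n1+n2, n3+n4, n5+n6, whose co-sequencing reveals the message fragment by
fragment, while the circularly permuted pairing reveals the decoy.  Other
CLI commands: `keygen`, `encode`, `decode`, `compose`, `cosequence`,
`detect` (see `musekit --help`).

## Documentation

The model, its assumptions, parameter defaults, and the reconstruction
decisions behind the reference keyboard layout are documented in
[docs/methods.md](docs/methods.md).
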